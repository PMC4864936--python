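"""Exact search for a minimal-repeat optimal scaffold of one subgraph.

The search enumerates signed sequences of contig instances, extending
only to the right of an active region, and finds a scaffold minimizing
the number of discordant edges by iterative deepening on the allowed
discordance p.  Equivalent partial scaffolds -- equal active region
(with relative geometry), pending-edge set and placed unique set -- are
pruned through a prefix-tree memo table with dominance on the running
discordant count.  Repeat contigs may be placed multiple times but are
never used to propose extensions; instances drifting out of pairing
reach of the scaffold tail are confirmed if essential (their removal
would create a discordant edge) and silently dropped otherwise, which
guarantees the minimal-repeat property of the result.

Placement geometry: each appended instance is anchored on the best
in-reach, orientation-matching edge from a placed instance (support,
then precision, then recency); where no anchor exists the instance
starts a new piece beyond pairing reach ("break").  Gaps between placed
instances are therefore taken at their edge estimates until the final
maximum-likelihood gap sizing.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .graph import Contig, ScaffoldEdge, ScaffoldGraph
from .io import Config

log = logging.getLogger("jumpscaf")

UNTOUCHED, PENDING, SAT, DISC = 0, 1, 2, 3


class CapExceeded(Exception):
    """Explored-state counter hit the configured cap."""


# ---------------------------------------------------------------------------
# pure geometry primitives (shared with the brute-force oracle)
# ---------------------------------------------------------------------------

def pair_satisfies(edge: ScaffoldEdge, a: tuple, b: tuple, m: float) -> bool:
    """Do placed instances a (of edge.c1) and b (of edge.c2) satisfy the edge?

    Instances are (orient, start, end) tuples.  Either left-to-right
    reading of the edge may match (the constraint is reversal-symmetric).
    """
    qa, sa, ea = a
    qb, sb, eb = b
    w = m * edge.sd
    if qa == edge.o1 and qb == edge.o2 and abs((sb - ea) - edge.gap) <= w:
        return True
    if qb == -edge.o2 and qa == -edge.o1 and abs((sa - eb) - edge.gap) <= w:
        return True
    return False


def is_concordant(edge: ScaffoldEdge, placements_c1: Iterable[tuple],
                  placements_c2: Iterable[tuple], m: float = 6.0) -> bool:
    """True iff any placed instance pair satisfies the edge's constraints."""
    for a in placements_c1:
        for b in placements_c2:
            if pair_satisfies(edge, a, b, m):
                return True
    return False


class GraphView:
    """Indexed, immutable view of one subgraph for the search."""

    def __init__(self, contigs: Dict[str, Contig],
                 edges: Sequence[ScaffoldEdge], config: Config):
        self.contigs = contigs
        # concordance of edges between repeats is ignored throughout
        self.edges = [e for e in edges
                      if not (contigs[e.c1].is_repeat
                              and contigs[e.c2].is_repeat)]
        self.m = config.sd_multiplier
        self.delta_min = config.delta_min
        self.adj: Dict[str, List[int]] = {c: [] for c in contigs}
        for i, e in enumerate(self.edges):
            self.adj[e.c1].append(i)
            if e.c2 != e.c1:
                self.adj[e.c2].append(i)
        self.is_repeat = {c: ctg.is_repeat for c, ctg in contigs.items()}
        self.length = {c: ctg.length for c, ctg in contigs.items()}
        self.uniques = frozenset(c for c in contigs if not self.is_repeat[c])
        self.max_reach = max((e.gap + self.m * e.sd for e in self.edges),
                             default=0.0)
        # beyond this tail distance no window can pair, even overlapping
        self.confirm_dist = self.max_reach - self.delta_min
        self.break_gap = self.confirm_dist + 1.0


def _anchor_candidates(view: GraphView, live, contig: str, orient: int,
                       tail_end: float):
    """In-reach, orientation-matching anchors for appending (contig, orient).

    ``live`` maps contig id -> list of (orient, start, end) placed
    instances.  Yields (edge_index, anchor_end, target_start).
    """
    lim = tail_end + view.delta_min
    for ei in view.adj[contig]:
        e = view.edges[ei]
        reach = e.gap + view.m * e.sd
        if contig == e.c2 and orient == e.o2:
            for (qa, sa, ea) in live.get(e.c1, ()):
                if qa == e.o1 and ea + reach >= lim:
                    yield ei, ea, ea + e.gap
        if contig == e.c1 and orient == -e.o1:
            for (qb, sb, eb) in live.get(e.c2, ()):
                if qb == -e.o2 and eb + reach >= lim:
                    yield ei, eb, eb + e.gap


def best_anchor(view: GraphView, live, contig: str, orient: int,
                tail_end: float):
    """Deterministic anchor choice: support desc, sd asc, rightmost, edge id."""
    best = None
    best_key = None
    for ei, aend, target in _anchor_candidates(view, live, contig, orient,
                                               tail_end):
        e = view.edges[ei]
        key = (-e.support, e.sd, -aend, ei)
        if best_key is None or key < best_key:
            best_key = key
            best = (ei, aend, target)
    return best


def place_sequence(view: GraphView, seq: Sequence[Tuple[str, int]]):
    """Place a signed instance sequence under the anchored-placement rule.

    Returns (instances, tail_end) where instances are
    (contig, orient, start, end) in sequence order.  Used by the
    brute-force oracle and by memoization-soundness checks; the search
    engine reproduces exactly this geometry incrementally.
    """
    live: Dict[str, List[tuple]] = {}
    out: List[tuple] = []
    tail = 0.0
    for contig, orient in seq:
        if not out:
            start = 0.0
        else:
            hit = best_anchor(view, live, contig, orient, tail)
            if hit is None:
                start = tail + view.break_gap
            else:
                start = max(hit[2], tail + view.delta_min)
        end = start + view.length[contig]
        out.append((contig, orient, start, end))
        live.setdefault(contig, []).append((orient, start, end))
        tail = max(tail, end)
    return out, tail


def score_placement(view: GraphView, instances: Sequence[tuple]):
    """Count unsatisfied edges for a full placement; returns (k, sat_set)."""
    live: Dict[str, List[tuple]] = {}
    for contig, orient, start, end in instances:
        live.setdefault(contig, []).append((orient, start, end))
    sat = set()
    for i, e in enumerate(view.edges):
        if is_concordant(e, live.get(e.c1, ()), live.get(e.c2, ()), view.m):
            sat.add(i)
    return len(view.edges) - len(sat), sat


def order_extensions(view: GraphView, tail_contig: str) -> Dict[str, float]:
    """Estimated distances from the scaffold tail by breadth-first search.

    Each edge is visited once; contigs reachable along several paths get
    the weighted mean of the path estimates, down-weighted by path edge
    count.
    """
    acc: Dict[str, List[tuple]] = {tail_contig: [(0.0, 1)]}
    seen_edges: Set[int] = set()
    queued = {tail_contig}
    q = deque([tail_contig])
    while q:
        c = q.popleft()
        ests = acc[c]
        wsum = sum(1.0 / pl for _, pl in ests)
        d0 = sum(d / pl for d, pl in ests) / wsum
        l0 = min(pl for _, pl in ests)
        base = 0 if c == tail_contig else l0
        for ei in sorted(view.adj[c]):
            if ei in seen_edges:
                continue
            seen_edges.add(ei)
            e = view.edges[ei]
            o = e.other(c)
            acc.setdefault(o, []).append(
                (d0 + e.gap + view.length[o], base + 1))
            if o not in queued:
                queued.add(o)
                q.append(o)
    out = {}
    for c, ests in acc.items():
        wsum = sum(1.0 / pl for _, pl in ests)
        out[c] = sum(d / pl for d, pl in ests) / wsum
    out[tail_contig] = 0.0
    return out


# ---------------------------------------------------------------------------
# memo table
# ---------------------------------------------------------------------------

_VAL = ("#",)     # sentinel key for the value slot in trie nodes


class MemoTable:
    """Prefix tree over canonical state encodings with per-key best k.

    Keys are flattened token lists (active-region entries, then pending
    edges, then placed uniques); lookup and insertion cost is
    proportional to the key length.  A state is pruned iff an equal key
    was recorded with k' <= k.
    """

    def __init__(self):
        self.root: dict = {}
        self.insertions = 0

    def admit(self, tokens: Sequence, k: int) -> bool:
        node = self.root
        for t in tokens:
            nxt = node.get(t)
            if nxt is None:
                nxt = node[t] = {}
            node = nxt
        best = node.get(_VAL)
        if best is not None and best <= k:
            return False
        node[_VAL] = k
        self.insertions += 1
        return True


# ---------------------------------------------------------------------------
# search engine
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    instances: List[tuple]          # (contig, orient, start, end), by position
    k: int                          # discordant edges in the returned scaffold
    satisfied: Set[int]             # edge indices satisfied by the placement
    flags: Tuple[str, ...] = ()
    stats: dict = field(default_factory=dict)


class _Engine:
    def __init__(self, view: GraphView, config: Config,
                 node_budget: Optional[int] = None):
        self.view = view
        self.config = config
        self.memo_enabled = config.memo_enabled
        self.node_budget = node_budget
        self.nodes = 0           # accepted (explored) states, all depths
        self.p = 0
        self.reset()

    # -- state ------------------------------------------------------------

    def reset(self):
        self.inst: List[list] = []      # [contig, orient, start, end, removed, confirmed]
        self.by_contig: Dict[str, List[int]] = {}
        self.unique_placed: Set[str] = set()
        self.tail = 0.0
        self.status = [UNTOUCHED] * len(self.view.edges)
        self.pending: Set[int] = set()
        self.k = 0
        self.memo = MemoTable()
        self.best = None                # (k, -span, seq, instances)

    def live(self, contig: str):
        return [(self.inst[i][1], self.inst[i][2], self.inst[i][3])
                for i in self.by_contig.get(contig, ()) if not self.inst[i][4]]

    def live_map(self):
        return {c: self.live(c) for c in self.by_contig}

    # -- edge status helpers ----------------------------------------------

    def _edge_satisfied(self, ei: int) -> bool:
        e = self.view.edges[ei]
        return is_concordant(e, self.live(e.c1), self.live(e.c2), self.view.m)

    def _can_gain(self, contig: str) -> bool:
        if self.view.is_repeat[contig]:
            n_live = sum(not self.inst[i][4]
                         for i in self.by_contig.get(contig, ()))
            return n_live < self.config.max_repeat_copies
        return contig not in self.unique_placed

    def _edge_alive(self, ei: int) -> bool:
        """Can a future (right-extension) placement still satisfy the edge?"""
        e = self.view.edges[ei]
        g1, g2 = self._can_gain(e.c1), self._can_gain(e.c2)
        if g1 and g2:
            return True
        lim = self.tail + self.view.delta_min
        reach = e.gap + self.view.m * e.sd
        if g2:
            for (qa, sa, ea) in self.live(e.c1):
                if qa == e.o1 and ea + reach >= lim:
                    return True
        if g1:
            for (qb, sb, eb) in self.live(e.c2):
                if qb == -e.o2 and eb + reach >= lim:
                    return True
        return False

    def _set_status(self, ei: int, st: int, journal: list):
        old = self.status[ei]
        if old == st:
            return
        journal.append(("status", ei, old))
        self.status[ei] = st
        if old == PENDING:
            self.pending.discard(ei)
        if st == PENDING:
            self.pending.add(ei)
        if old == DISC:
            self.k -= 1
        if st == DISC:
            self.k += 1

    # -- extension ---------------------------------------------------------

    def _append(self, contig: str, orient: int, start: float, journal: list):
        end = start + self.view.length[contig]
        idx = len(self.inst)
        self.inst.append([contig, orient, start, end, False, False])
        self.by_contig.setdefault(contig, []).append(idx)
        newly_unique = False
        if not self.view.is_repeat[contig]:
            self.unique_placed.add(contig)
            newly_unique = True
        journal.append(("inst", idx, newly_unique, self.tail))
        self.tail = max(self.tail, end)
        return idx

    def extend(self, contig: str, orient: int, force_break: bool = False):
        """Append an instance; returns (journal, sat_new) or None on k > p.

        The caller is responsible for memo admission and repeat-utility
        pruning; ``revert`` undoes everything on rejection.
        """
        journal: list = []
        if force_break or not self.inst:
            anchor = None
        else:
            anchor = best_anchor(self.view, self.live_map(), contig, orient,
                                 self.tail)
        if anchor is None:
            start = (self.tail + self.view.break_gap) if self.inst else 0.0
        else:
            start = max(anchor[2], self.tail + self.view.delta_min)
        idx = self._append(contig, orient, start, journal)
        sat_new = []
        for ei in self.view.adj[contig]:
            st = self.status[ei]
            if st in (SAT, DISC):
                continue
            if self._edge_satisfied(ei):
                if st == PENDING or st == UNTOUCHED:
                    sat_new.append(ei)
                self._set_status(ei, SAT, journal)
            elif self._edge_alive(ei):
                self._set_status(ei, PENDING, journal)
            else:
                self._set_status(ei, DISC, journal)
        # the tail moved: pending edges may have drifted out of reach
        for ei in list(self.pending):
            if not self._edge_alive(ei):
                self._set_status(ei, DISC, journal)
        if self.k > self.p:
            self.revert(journal)
            return None
        self._confirm_repeats(journal)
        if self.k > self.p:
            self.revert(journal)
            return None
        return journal, sat_new, idx

    def _confirm_repeats(self, journal: list):
        """Confirm or drop repeat instances beyond pairing reach of the tail.

        An instance is essential iff marking it removed turns some
        currently satisfied edge discordant; essential instances are
        confirmed (kept forever), the rest are removed with the
        geometry of all other instances preserved.
        """
        for idx, rec in enumerate(self.inst):
            contig, orient, start, end, removed, confirmed = rec
            if removed or confirmed or not self.view.is_repeat[contig]:
                continue
            if self.tail - end <= self.view.confirm_dist:
                continue
            rec[4] = True            # tentative removal
            broken = []
            for ei in self.view.adj[contig]:
                if self.status[ei] == SAT and not self._edge_satisfied(ei):
                    broken.append(ei)
            essential = False
            for ei in broken:
                if not self._edge_alive(ei):
                    essential = True
                    break
            if essential:
                rec[4] = False
                rec[5] = True
                journal.append(("confirm", idx))
            else:
                journal.append(("removed", idx))
                for ei in broken:
                    self._set_status(ei, PENDING, journal)

    def revert(self, journal: list):
        for entry in reversed(journal):
            tag = entry[0]
            if tag == "status":
                _, ei, old = entry
                st = self.status[ei]
                self.status[ei] = old
                if st == PENDING:
                    self.pending.discard(ei)
                if old == PENDING:
                    self.pending.add(ei)
                if st == DISC:
                    self.k -= 1
                if old == DISC:
                    self.k += 1
            elif tag == "inst":
                _, idx, newly_unique, old_tail = entry
                contig = self.inst[idx][0]
                self.by_contig[contig].pop()
                if not self.by_contig[contig]:
                    del self.by_contig[contig]
                if newly_unique:
                    self.unique_placed.discard(contig)
                self.inst.pop()
                self.tail = old_tail
            elif tag == "confirm":
                self.inst[entry[1]][5] = False
            elif tag == "removed":
                self.inst[entry[1]][4] = False

    # -- state encoding / memo ---------------------------------------------

    def _relevant_instances(self) -> List[int]:
        rel: Set[int] = set()
        for idx, rec in enumerate(self.inst):
            if not rec[4] and not rec[5] and self.view.is_repeat[rec[0]]:
                rel.add(idx)
        lim = self.tail + self.view.delta_min
        for ei in self.pending:
            e = self.view.edges[ei]
            reach = e.gap + self.view.m * e.sd
            if self._can_gain(e.c2):
                for idx in self.by_contig.get(e.c1, ()):
                    rec = self.inst[idx]
                    if not rec[4] and rec[1] == e.o1 and rec[3] + reach >= lim:
                        rel.add(idx)
            if self._can_gain(e.c1):
                for idx in self.by_contig.get(e.c2, ()):
                    rec = self.inst[idx]
                    if not rec[4] and rec[1] == -e.o2 and rec[3] + reach >= lim:
                        rel.add(idx)
        return sorted(rel, key=lambda i: (self.inst[i][2], i))

    def state_tokens(self) -> list:
        tokens: list = []
        for idx in self._relevant_instances():
            contig, orient, start, end, removed, confirmed = self.inst[idx]
            tokens.append((contig, orient, int(round(self.tail - end)),
                           confirmed))
        tokens.append(("|",))
        tokens.extend(sorted(self.pending))
        tokens.append(("|",))
        tokens.extend(sorted(self.unique_placed))
        return tokens

    # -- proposals -----------------------------------------------------------

    def proposals(self):
        """Candidate extensions, dangling-proposed first (nearest first)."""
        dangling: Set[str] = set()
        for ei in self.pending:
            e = self.view.edges[ei]
            c1_live = any(not self.inst[i][4]
                          for i in self.by_contig.get(e.c1, ()))
            c2_live = any(not self.inst[i][4]
                          for i in self.by_contig.get(e.c2, ()))
            if c1_live and not self.view.is_repeat[e.c1] and self._can_gain(e.c2):
                dangling.add(e.c2)
            if c2_live and not self.view.is_repeat[e.c2] and self._can_gain(e.c1):
                dangling.add(e.c1)
        props: List[tuple] = []
        if dangling:
            tail_contig = None
            for rec in reversed(self.inst):
                if not rec[4]:
                    tail_contig = rec[0]
                    break
            dist = order_extensions(self.view, tail_contig) if tail_contig else {}
            for c in sorted(dangling, key=lambda c: (dist.get(c, float("inf")), c)):
                for orient in (1, -1):
                    props.append(("ext", c, orient))
        # breaks: start a fresh piece with a unique contig, optionally led
        # by one repeat (covers scaffolds that begin with a repeat)
        for c in sorted(self.view.uniques - self.unique_placed):
            for orient in (1, -1):
                props.append(("break", c, orient))
        seen_pairs = set()
        for ei, e in enumerate(self.view.edges):
            r, u = None, None
            if self.view.is_repeat[e.c1] and not self.view.is_repeat[e.c2]:
                r, u, ro, uo = e.c1, e.c2, e.o1, e.o2
            elif self.view.is_repeat[e.c2] and not self.view.is_repeat[e.c1]:
                r, u, ro, uo = e.c2, e.c1, -e.o2, -e.o1
            if r is None or u in self.unique_placed or not self._can_gain(r):
                continue
            combo = (r, ro, u, uo)
            if combo not in seen_pairs:
                seen_pairs.add(combo)
                props.append(("break_pair",) + combo)
        return props

    # -- DFS -----------------------------------------------------------------

    def _tick(self):
        self.nodes += 1
        if self.node_budget is not None and self.nodes > self.node_budget:
            raise CapExceeded()

    def _admit(self) -> bool:
        if not self.memo_enabled:
            return True
        return self.memo.admit(self.state_tokens(), self.k)

    def _record_solution(self) -> bool:
        """The first completion at the current deepening level is returned.

        Iterative deepening guarantees its discordance is the minimum;
        the deterministic exploration order (nearest dangling candidates
        first, + before -, breaks last) breaks ties between optima, and
        the same scaffold is found with memoization on or off (a pruned
        prefix's completions were already produced from the earlier
        equal state).
        """
        final_k = self.k + len(self.pending)
        if final_k > self.p:
            return False
        instances = [(rec[0], rec[1], rec[2], rec[3])
                     for rec in self.inst if not rec[4]]
        instances.sort(key=lambda t: (t[2], t[0], t[1]))
        self.best = (final_k, instances)
        return True

    def _dfs(self) -> bool:
        if self.unique_placed == self.view.uniques:
            if self._record_solution():
                return True
        for prop in self.proposals():
            kind = prop[0]
            if kind == "break_pair":
                _, r, ro, u, uo = prop
                out1 = self.extend(r, ro, force_break=True)
                if out1 is None:
                    continue
                j1, sat1, idx1 = out1
                ok = self._useful_repeat(idx1)
                out2 = self.extend(u, uo) if ok else None
                if out2 is None:
                    self.revert(j1)
                    continue
                j2, _, _ = out2
                done = False
                if self._admit():
                    self._tick()
                    done = self._dfs()
                if not done:
                    self.revert(j2)
                    self.revert(j1)
                    continue
                return True
            _, c, orient = prop
            out = self.extend(c, orient, force_break=(kind == "break"))
            if out is None:
                continue
            journal, sat_new, idx = out
            keep = True
            if self.view.is_repeat[c]:
                keep = bool(sat_new) or self._useful_repeat(idx)
            done = False
            if keep and self._admit():
                self._tick()
                done = self._dfs()
            if done:
                return True
            self.revert(journal)
        return False

    def _useful_repeat(self, idx: int) -> bool:
        """A repeat instance must offer a reachable window for a pending edge."""
        rec = self.inst[idx]
        if rec[4]:
            return False
        contig, orient, start, end = rec[0], rec[1], rec[2], rec[3]
        lim = self.tail + self.view.delta_min
        for ei in self.view.adj[contig]:
            if self.status[ei] != PENDING:
                continue
            e = self.view.edges[ei]
            reach = e.gap + self.view.m * e.sd
            if contig == e.c1 and orient == e.o1 and self._can_gain(e.c2) \
                    and end + reach >= lim:
                return True
            if contig == e.c2 and orient == -e.o2 and self._can_gain(e.c1) \
                    and end + reach >= lim:
                return True
        return False

    # -- top level ------------------------------------------------------------

    def run(self, max_p: Optional[int] = None):
        """Iterative deepening; returns (k, instances) of the first optimum."""
        limit = len(self.view.edges) if max_p is None else max_p
        for p in range(limit + 1):
            self.reset()
            self.p = p
            if self._dfs():
                return self.best
        return self.best


def _minimal_repeat_sweep(view: GraphView, instances: List[tuple]):
    """Drop non-essential repeat instances from a final placement.

    Removal preserves the geometry of the remaining instances (the
    vacated span becomes gap), so only edges incident to the removed
    contig can change status.  Iterates until stable.
    """
    instances = list(instances)
    changed = True
    while changed:
        changed = False
        base_k, _ = score_placement(view, instances)
        for i, (contig, orient, start, end) in enumerate(instances):
            if not view.is_repeat[contig]:
                continue
            trial = instances[:i] + instances[i + 1:]
            k, _ = score_placement(view, trial)
            if k <= base_k:
                instances = trial
                changed = True
                break
    return instances


def repeat_instance_essential(view: GraphView, instances: Sequence[tuple],
                              idx: int) -> bool:
    """Does deleting instance ``idx`` strictly increase the discordant count?"""
    base_k, _ = score_placement(view, instances)
    trial = list(instances[:idx]) + list(instances[idx + 1:])
    k, _ = score_placement(view, trial)
    return k > base_k


def scaffold_subgraph(contigs: Dict[str, Contig],
                      edges: Sequence[ScaffoldEdge], config: Config,
                      max_p: Optional[int] = None) -> SearchResult:
    """Minimal-repeat optimal scaffold of one fenced subgraph.

    Runs the memoized iterative-deepening search; if the explored-state
    counter exceeds the configured cap the edge-support threshold is
    raised by the configured step, the subgraph rebuilt, and the search
    restarted with the result flagged (hybrid-exact fallback).
    """
    uniques = [c for c, ctg in contigs.items() if not ctg.is_repeat]
    if not uniques:
        # nothing anchors a search: each repeat goes out as a singleton
        instances = []
        pos = 0.0
        view = GraphView(contigs, [], config)
        for c in sorted(contigs):
            instances.append((c, 1, pos, pos + contigs[c].length))
            pos += contigs[c].length + view.break_gap
        return SearchResult(instances=instances, k=len(edges),
                            satisfied=set(),
                            flags=("repeat-only subgraph",),
                            stats={"states": 0, "p": 0})
    threshold = config.edge_support
    flags: List[str] = []
    while True:
        kept = [e for e in edges if e.support >= threshold]
        view = GraphView(contigs, kept, config)
        engine = _Engine(view, config, node_budget=config.state_cap)
        try:
            best = engine.run(max_p=max_p)
            break
        except CapExceeded:
            threshold += config.support_step
            flags = [f"hybrid: edge support threshold raised to {threshold}"]
            log.info("state cap %d hit; retrying with support >= %d",
                     config.state_cap, threshold)
    assert best is not None
    instances = _minimal_repeat_sweep(view, best[1])
    k, sat = score_placement(view, instances)
    return SearchResult(
        instances=instances, k=k, satisfied=sat, flags=tuple(flags),
        stats={"states": engine.nodes,
               "memo_insertions": engine.memo.insertions,
               "p": best[0], "support_threshold": threshold})
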