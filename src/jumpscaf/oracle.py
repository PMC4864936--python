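"""Brute-force scaffolding oracle for small graphs.

Exhaustively enumerates signed sequences of contig instances (repeats up
to a copy bound), places every sequence under the same anchored-
placement geometry the scaffolder uses, and scores discordance with the
shared concordance primitive.  Unlike the scaffolder it applies no
equivalence-class memoization and no proposal restrictions: every
unplaced contig is tried at every position, which makes it an
independent check of the search's exactness.  Iterative deepening on
the allowed discordance plus a sound dead-edge bound keeps the
enumeration feasible for graphs of a dozen instances or so.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .graph import Contig, ScaffoldEdge
from .io import Config
from .search import (GraphView, best_anchor, is_concordant, pair_satisfies,
                     score_placement)


@dataclass
class BruteForceResult:
    min_k: int
    optima: List[List[tuple]]       # minimal-repeat optimal placements
    n_explored: int = 0


def _edge_dead(view: GraphView, e: ScaffoldEdge, live: dict, tail: float,
               can_gain) -> bool:
    """True iff no extension of the current placement can satisfy e."""
    if is_concordant(e, live.get(e.c1, ()), live.get(e.c2, ()), view.m):
        return False
    g1, g2 = can_gain(e.c1), can_gain(e.c2)
    if g1 and g2:
        return False
    lim = tail + view.delta_min
    reach = e.gap + view.m * e.sd
    if g2:
        for (q, s, en) in live.get(e.c1, ()):
            if q == e.o1 and en + reach >= lim:
                return False
    if g1:
        for (q, s, en) in live.get(e.c2, ()):
            if q == -e.o2 and en + reach >= lim:
                return False
    return True


def brute_force_scaffold(contigs: Dict[str, Contig],
                         edges: Sequence[ScaffoldEdge], config: Config,
                         repeat_cap: int = 2,
                         max_p: Optional[int] = None) -> BruteForceResult:
    """Exhaustive minimum-discordance scaffold over all signed sequences.

    Repeat contigs may occur up to ``repeat_cap`` times; sequences must
    cover every unique contig.  Returns the exact minimum discordant
    count and the subset of optimal placements from which no repeat
    instance can be removed without increasing discordance.
    """
    view = GraphView(contigs, edges, config)
    uniques = sorted(view.uniques)
    repeats = sorted(c for c in contigs if view.is_repeat[c])
    n_unique = len(uniques)
    max_depth = n_unique + repeat_cap * len(repeats)
    counters = {"explored": 0}

    limit = len(view.edges) if max_p is None else max_p
    for p in range(limit + 1):
        solutions: List[Tuple[int, List[tuple]]] = []
        seq: List[tuple] = []
        out: List[tuple] = []
        live: Dict[str, List[tuple]] = {}
        placed_u: Set[str] = set()
        copies = {r: 0 for r in repeats}

        def can_gain(c: str) -> bool:
            if view.is_repeat[c]:
                return copies[c] < repeat_cap
            return c not in placed_u

        def dfs(tail: float):
            counters["explored"] += 1
            dead = sum(_edge_dead(view, e, live, tail, can_gain)
                       for e in view.edges)
            if dead > p:
                return
            if len(placed_u) == n_unique:
                k, _ = score_placement(view, out)
                if k <= p:
                    solutions.append((k, list(out)))
            if len(out) >= max_depth:
                return
            cands = [c for c in uniques if c not in placed_u]
            cands += [r for r in repeats if copies[r] < repeat_cap]
            for c in cands:
                for orient in (1, -1):
                    if out:
                        hit = best_anchor(view, live, c, orient, tail)
                        start = (tail + view.break_gap) if hit is None \
                            else max(hit[2], tail + view.delta_min)
                    else:
                        start = 0.0
                    end = start + view.length[c]
                    inst = (c, orient, start, end)
                    out.append(inst)
                    live.setdefault(c, []).append((orient, start, end))
                    if view.is_repeat[c]:
                        copies[c] += 1
                    else:
                        placed_u.add(c)
                    dfs(max(tail, end))
                    out.pop()
                    live[c].pop()
                    if not live[c]:
                        del live[c]
                    if view.is_repeat[c]:
                        copies[c] -= 1
                    else:
                        placed_u.discard(c)

        dfs(0.0)
        if solutions:
            min_k = min(k for k, _ in solutions)
            if min_k <= p:
                optima = _minimal_repeat_optima(
                    view, [s for k, s in solutions if k == min_k])
                return BruteForceResult(min_k=min_k, optima=optima,
                                        n_explored=counters["explored"])
    raise RuntimeError("no complete scaffold found (unreachable)")


def _minimal_repeat_optima(view: GraphView,
                           placements: List[List[tuple]]) -> List[List[tuple]]:
    """Filter optima to those in which every repeat instance is essential.

    Removal is geometry-preserving: the vacated span becomes gap, so an
    instance is essential iff deleting it (coordinates of the others
    unchanged) increases the unsatisfied-edge count.
    """
    out = []
    seen = set()
    for inst in placements:
        base_k, _ = score_placement(view, inst)
        minimal = True
        for i, (c, _, _, _) in enumerate(inst):
            if not view.is_repeat[c]:
                continue
            k, _ = score_placement(view, inst[:i] + inst[i + 1:])
            if k <= base_k:
                minimal = False
                break
        if minimal:
            key = tuple((c, o, round(s)) for c, o, s, _ in inst)
            if key not in seen:
                seen.add(key)
                out.append(inst)
    return out
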