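"""Graph contraction: fenced subgraphs anchored at border contigs.

A border contig is a unique contig long enough that no concordant edge
can span it, so an optimal scaffold can be assembled per fenced
subgraph and stitched at shared borders without losing global
optimality.  Each border has two intrinsic ends; the edges incident to
it partition by end, and each end belongs to at most one subgraph, so a
border joins at most two subgraphs.  Repeat contigs are added back to
every subgraph holding a unique contig they link to (repeat-repeat
edges are ignored throughout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .graph import Contig, ScaffoldEdge, ScaffoldGraph
from .library import Library

log = logging.getLogger("jumpscaf")


class StitchError(RuntimeError):
    """A border contig turned up interior to a subgraph scaffold."""


@dataclass
class FencedSubgraph:
    contigs: Dict[str, Contig]
    edges: List[ScaffoldEdge]
    borders: Set[str] = field(default_factory=set)

    def min_id(self) -> str:
        return min(self.contigs)


def find_border_contigs(graph: ScaffoldGraph,
                        libraries: Sequence[Library] = (),
                        sd_multiplier: float = 6.0,
                        l_max: Optional[float] = None) -> Set[str]:
    """Unique contigs no concordant edge can span.

    The criterion is length >= the largest library upper bound L (or an
    explicit ``l_max``); as a defensive refinement a contig is not a
    border if some individual edge's concordance window (g + m*sd) could
    still span it.
    """
    if l_max is None:
        if not libraries:
            return set()
        l_max = max(lib.upper for lib in libraries)
    max_window = max((e.gap + sd_multiplier * e.sd for e in graph.edges),
                     default=0.0)
    borders = set()
    for c, ctg in graph.contigs.items():
        if ctg.is_repeat or ctg.length < l_max:
            continue
        if ctg.length <= max_window:
            continue
        borders.add(c)
    return borders


def _border_end(edge: ScaffoldEdge, border: str) -> str:
    """Which intrinsic end ('L'/'R') of the border the edge attaches to."""
    if border == edge.c1:
        return "R" if edge.o1 == 1 else "L"
    return "L" if edge.o2 == 1 else "R"


def decompose(graph: ScaffoldGraph, borders: Set[str]) -> List[FencedSubgraph]:
    """Partition the graph into fenced subgraphs with repeats added back.

    Connected components of the unique subgraph minus borders seed the
    subgraphs; components touching the same border end are merged (they
    compete for that end and must be searched jointly); every edge lands
    in exactly one subgraph.
    """
    contigs = graph.contigs
    is_rep = {c: ctg.is_repeat for c, ctg in contigs.items()}
    core = [c for c in contigs if not is_rep[c] and c not in borders]
    g_u = nx.Graph()
    g_u.add_nodes_from(core)
    for e in graph.edges:
        if (e.c1 in g_u and e.c2 in g_u):
            g_u.add_edge(e.c1, e.c2)
    comp_of: Dict[str, int] = {}
    for i, comp in enumerate(sorted(nx.connected_components(g_u), key=min)):
        for c in comp:
            comp_of[c] = i

    # union-find over components and border ends
    parent: Dict = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb, key=str)] = min(ra, rb, key=str)

    def element(contig: str, edge: ScaffoldEdge):
        if is_rep[contig]:
            return None
        if contig in borders:
            return ("end", contig, _border_end(edge, contig))
        return ("comp", comp_of[contig])

    for i in set(comp_of.values()):
        find(("comp", i))
    edge_owner: Dict[int, tuple] = {}
    for ei, e in enumerate(graph.edges):
        el1, el2 = element(e.c1, e), element(e.c2, e)
        if el1 is None and el2 is None:
            continue                      # repeat-repeat: ignored
        if el1 is not None and el2 is not None:
            union(el1, el2)
            owner = el1 if el1[0] == "comp" else el2
        else:
            owner = el1 if el1 is not None else el2
        edge_owner[ei] = owner

    groups: Dict[tuple, dict] = {}

    def group_for(el):
        root = find(el)
        return groups.setdefault(root, {"contigs": set(), "edges": [],
                                        "borders": set()})

    for c, i in comp_of.items():
        group_for(("comp", i))["contigs"].add(c)
    for el in list(parent):
        if el[0] == "end":
            g = group_for(el)
            g["contigs"].add(el[1])
            g["borders"].add(el[1])
    for ei, owner in edge_owner.items():
        e = graph.edges[ei]
        g = group_for(owner)
        g["edges"].append(e)
        g["contigs"].update((e.c1, e.c2))

    group_list = list(groups.values())
    group_list = _merge_cyclic_groups(group_list)
    subs = []
    covered: Set[str] = set()
    for g in group_list:
        sub_contigs = {c: contigs[c] for c in g["contigs"]}
        covered.update(c for c in g["contigs"] if not is_rep[c])
        subs.append(FencedSubgraph(contigs=sub_contigs, edges=g["edges"],
                                   borders=g["borders"]))
    # uniques (incl. borders) untouched by any edge become their own subgraph
    for c in sorted(contigs):
        if not is_rep[c] and c not in covered:
            subs.append(FencedSubgraph(
                contigs={c: contigs[c]}, edges=[],
                borders={c} if c in borders else set()))
    subs.sort(key=lambda s: s.min_id())
    return subs


def _merge_cyclic_groups(group_list: List[dict]) -> List[dict]:
    """Merge fenced subgraphs that form a cycle through shared borders.

    Stitching assumes the subgraph-sharing structure is a forest; a
    cycle (e.g. two subgraphs sharing both their borders) cannot be
    linearized by concatenation, so all subgraphs on the cycle are
    searched jointly instead.
    """
    holder: Dict[str, List[int]] = {}
    for gi, g in enumerate(group_list):
        for b in g["borders"]:
            holder.setdefault(b, []).append(gi)

    parent = list(range(len(group_list)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cyclic: Set[int] = set()
    for b, gids in sorted(holder.items()):
        if len(gids) != 2:
            continue
        r1, r2 = find(gids[0]), find(gids[1])
        if r1 == r2:
            cyclic.add(r1)
        else:
            parent[max(r1, r2)] = min(r1, r2)
    # a cluster flagged cyclic collapses into one jointly-searched subgraph
    cyclic = {find(r) for r in cyclic}
    if not cyclic:
        return group_list
    merged: Dict[int, dict] = {}
    out: List[dict] = []
    for gi, g in enumerate(group_list):
        root = find(gi)
        if root not in cyclic:
            out.append(g)
            continue
        m = merged.get(root)
        if m is None:
            m = merged[root] = {"contigs": set(), "edges": [], "borders": set()}
            out.append(m)
        m["contigs"] |= g["contigs"]
        m["edges"].extend(g["edges"])
        m["borders"] |= g["borders"]
    log.info("merged %d cyclically fenced subgraph cluster(s)", len(merged))
    return out


# ---------------------------------------------------------------------------
# stitching
# ---------------------------------------------------------------------------

def _normalize(piece: List[tuple]) -> List[tuple]:
    piece = sorted(piece, key=lambda t: (t[2], t[0]))
    shift = piece[0][2]
    return [(c, o, s - shift, e - shift) for c, o, s, e in piece]


def _reverse(piece: List[tuple]) -> List[tuple]:
    lo = min(s for _, _, s, _ in piece)
    hi = max(e for _, _, _, e in piece)
    m = lo + hi
    return _normalize([(c, -o, m - e, m - s) for c, o, s, e in piece])


def stitch(pieces: Sequence[List[tuple]], borders: Set[str]) -> List[List[tuple]]:
    """Concatenate subgraph scaffold pieces at shared border contigs.

    Each piece is a list of (contig, orient, start, end) instances.  A
    border shared by two pieces must be terminal in both; orientation is
    reconciled by flipping the later piece, and the earlier piece is
    reversed only when the border sits at its head.
    """
    pool: List[List[tuple]] = [_normalize(list(p)) for p in pieces]
    for border in sorted(borders):
        holding = [i for i, p in enumerate(pool)
                   if any(c == border for c, _, _, _ in p)]
        if len(holding) < 2:
            continue
        if len(holding) > 2:
            raise StitchError(f"border {border} appears in {len(holding)} pieces")
        i1, i2 = holding
        p1, p2 = pool[i1], pool[i2]
        for p in (p1, p2):
            if p[0][0] != border and p[-1][0] != border:
                raise StitchError(f"border {border} interior to a scaffold piece")
        if p1[0][0] == border and len(p1) > 1:
            p1 = _reverse(p1)
        if p2[-1][0] == border and len(p2) > 1:
            p2 = _reverse(p2)
        if len(p1) == 1:
            p1 = [(border, p2[0][1], p1[0][2], p1[0][3])]
        q1 = p1[-1][1]
        if p2[0][1] != q1:
            if len(p2) == 1:
                p2 = [(p2[0][0], q1, p2[0][2], p2[0][3])]
            else:
                raise StitchError(
                    f"border {border}: irreconcilable orientations")
        shift = p1[-1][2] - p2[0][2]
        merged = p1 + [(c, o, s + shift, e + shift) for c, o, s, e in p2[1:]]
        pool[i1] = _normalize(merged)
        del pool[i2]
    return pool
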