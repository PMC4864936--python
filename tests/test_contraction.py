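"""Graph contraction: border contigs, fenced decomposition, stitching."""

import pytest

from jumpscaf.contraction import (StitchError, decompose, find_border_contigs,
                                  stitch)
from jumpscaf.graph import Contig, ScaffoldEdge, ScaffoldGraph
from jumpscaf.library import INWARD, Library


def _edge(eid, c1, o1, c2, o2, gap=100.0, sd=30.0, support=10):
    return ScaffoldEdge(eid, c1, o1, c2, o2, gap, sd, support)


def _lib(mu, sigma):
    return Library(id="l", orientation=INWARD, mu=mu, sigma=sigma, q1=0, q3=1)


def test_border_criterion():
    contigs = {
        "long": Contig("long", 20000),
        "short": Contig("short", 15000),
        "bigrep": Contig("bigrep", 50000, is_repeat=True),
    }
    graph = ScaffoldGraph(contigs, [])
    borders = find_border_contigs(graph, [_lib(10000, 1000)])  # L = 16000
    assert borders == {"long"}            # repeats and short contigs excluded


def test_border_defensive_window_check():
    contigs = {"long": Contig("long", 20000), "x": Contig("x", 5000)}
    # an edge whose concordance window could span 20 kbp disqualifies it
    wide = _edge(0, "long", 1, "x", 1, gap=19000.0, sd=400.0)
    graph = ScaffoldGraph(contigs, [wide])
    assert find_border_contigs(graph, [_lib(10000, 1000)]) == set()


def test_decompose_chain_at_border():
    contigs = {c: Contig(c, 30000 if c == "X" else 5000) for c in "ABXCD"}
    edges = [_edge(0, "A", 1, "B", 1), _edge(1, "B", 1, "X", 1),
             _edge(2, "C", 1, "X", -1), _edge(3, "C", 1, "D", 1)]
    graph = ScaffoldGraph(contigs, edges)
    subs = decompose(graph, {"X"})
    members = sorted(tuple(sorted(s.contigs)) for s in subs)
    assert members == [("A", "B", "X"), ("C", "D", "X")]
    # every edge lands in exactly one subgraph
    counts = {}
    for s in subs:
        for e in s.edges:
            counts[e.id] = counts.get(e.id, 0) + 1
    assert counts == {0: 1, 1: 1, 2: 1, 3: 1}


def test_decompose_repeat_added_to_both_sides():
    contigs = {c: Contig(c, 30000 if c == "X" else 5000) for c in "ABXCD"}
    contigs["R"] = Contig("R", 2000, is_repeat=True)
    edges = [_edge(0, "A", 1, "B", 1), _edge(1, "B", 1, "X", 1),
             _edge(2, "C", 1, "X", -1), _edge(3, "C", 1, "D", 1),
             _edge(4, "B", 1, "R", 1), _edge(5, "D", 1, "R", 1)]
    subs = decompose(ScaffoldGraph(contigs, edges), {"X"})
    with_r = [s for s in subs if "R" in s.contigs]
    assert len(with_r) == 2
    # a border contig belongs to at most two subgraphs
    x_count = sum("X" in s.contigs for s in subs)
    assert x_count <= 2


def test_decompose_no_borders_single_subgraph():
    contigs = {c: Contig(c, 5000) for c in "ABC"}
    edges = [_edge(0, "A", 1, "B", 1), _edge(1, "B", 1, "C", 1)]
    subs = decompose(ScaffoldGraph(contigs, edges), set())
    assert len(subs) == 1 and sorted(subs[0].contigs) == ["A", "B", "C"]


# ---------------------------------------------------------------------------
# stitching
# ---------------------------------------------------------------------------

def _inst(c, o, s, length=1000):
    return (c, o, float(s), float(s + length))


def test_stitch_simple_concatenation():
    p1 = [_inst("A", 1, 0), _inst("B", 1, 1100), _inst("X", 1, 2200, 5000)]
    p2 = [_inst("X", 1, 0, 5000), _inst("C", 1, 5100), _inst("D", 1, 6200)]
    out = stitch([p1, p2], {"X"})
    assert len(out) == 1
    assert [c for c, _, _, _ in out[0]] == ["A", "B", "X", "C", "D"]
    assert all(o == 1 for _, o, _, _ in out[0])


def test_stitch_flips_reversed_piece():
    p1 = [_inst("A", 1, 0), _inst("B", 1, 1100), _inst("X", 1, 2200, 5000)]
    # second subgraph solved in the mirrored orientation: [D-, C-, X-]
    p2 = [_inst("D", -1, 0), _inst("C", -1, 1100), _inst("X", -1, 2200, 5000)]
    out = stitch([p1, p2], {"X"})
    assert len(out) == 1
    assert [c for c, _, _, _ in out[0]] == ["A", "B", "X", "C", "D"]
    assert [o for _, o, _, _ in out[0]] == [1, 1, 1, 1, 1]


def test_stitch_unshared_border_is_scaffold_end():
    p1 = [_inst("A", 1, 0), _inst("X", 1, 1100, 5000)]
    out = stitch([p1], {"X"})
    assert len(out) == 1 and out[0][-1][0] == "X"


def test_stitch_interior_border_raises():
    p1 = [_inst("A", 1, 0), _inst("X", 1, 1100, 5000), _inst("B", 1, 6200)]
    p2 = [_inst("X", 1, 0, 5000), _inst("C", 1, 5100)]
    with pytest.raises(StitchError):
        stitch([p1, p2], {"X"})
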