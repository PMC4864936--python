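"""Exact search: concordance windows, extension ordering, memoization,
reversal symmetry, repeat handling."""

import pytest

from jumpscaf.graph import Contig, ScaffoldEdge
from jumpscaf.io import Config
from jumpscaf.search import (GraphView, MemoTable, is_concordant,
                             order_extensions, pair_satisfies,
                             scaffold_subgraph, score_placement)
from jumpscaf.simulate import random_scaffold_graph


def _edge(eid, c1, o1, c2, o2, gap, sd=300.0, support=10):
    return ScaffoldEdge(eid, c1, o1, c2, o2, gap, sd, support)


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def test_concordance_window():
    e = _edge(0, "A", 1, "B", 1, gap=3000.0, sd=300.0)
    a = (1, 0.0, 5000.0)
    # implied gap 3500 inside the 6-sd window [1200, 4800]
    assert pair_satisfies(e, a, (1, 8500.0, 9500.0), 6.0)
    # implied gap 10000: discordant
    assert not pair_satisfies(e, a, (1, 15000.0, 16000.0), 6.0)
    # orientation mismatch at perfect distance: discordant
    assert not pair_satisfies(e, a, (-1, 8000.0, 9000.0), 6.0)
    # the mirror-image reading satisfies too
    assert pair_satisfies(e, (-1, 8000.0, 9000.0), (-1, 0.0, 5000.0), 6.0)


def test_is_concordant_any_instance_pair():
    e = _edge(0, "A", 1, "R", 1, gap=100.0, sd=30.0)
    a_placements = [(1, 0.0, 5000.0)]
    r_far = (1, 20000.0, 21000.0)
    r_near = (1, 5100.0, 6100.0)
    assert not is_concordant(e, a_placements, [r_far])
    assert is_concordant(e, a_placements, [r_far, r_near])


# ---------------------------------------------------------------------------
# extension ordering
# ---------------------------------------------------------------------------

def test_order_extensions_distance_and_weighting(cfg):
    contigs = {c: Contig(c, 1000) for c in "TXYZ"}
    edges = [
        _edge(0, "T", 1, "X", 1, gap=0.0),          # X at 0 + 1000 via 1 edge
        _edge(1, "T", 1, "Y", 1, gap=500.0),
        _edge(2, "X", 1, "Z", 1, gap=4000.0),
    ]
    view = GraphView(contigs, edges, cfg)
    dist = order_extensions(view, "T")
    assert dist["T"] == 0.0
    assert dist["X"] == pytest.approx(1000.0)
    assert dist["Y"] == pytest.approx(1500.0)
    assert dist["X"] < dist["Y"] < dist["Z"]


def test_order_extensions_multipath_weighted_mean(cfg):
    # candidate reachable at 1000 over 1 edge and 3000 over 2 edges (the
    # intermediate node is discovered first, so its edge relaxes M->C)
    contigs = {c: Contig(c, 500) for c in "TMC"}
    edges = [
        _edge(0, "M", -1, "T", -1, gap=1000.0),          # T->M: 1500
        _edge(1, "C", -1, "T", -1, gap=500.0),           # T->C direct: 1000
        _edge(2, "C", 1, "M", -1, gap=1000.0),           # M->C: +1500 = 3000
    ]
    view = GraphView(contigs, edges, cfg)
    dist = order_extensions(view, "T")
    assert dist["C"] == pytest.approx((1000 / 1 + 3000 / 2) / (1 / 1 + 1 / 2))


# ---------------------------------------------------------------------------
# scaffolding small graphs
# ---------------------------------------------------------------------------

def test_concordant_chain(cfg, chain_graph):
    contigs, edges = chain_graph
    res = scaffold_subgraph(contigs, edges, cfg)
    assert res.k == 0
    order = [c for c, _, _, _ in res.instances]
    assert order in (["A", "B", "C"], ["C", "B", "A"])


def test_triangle_with_contradiction(cfg):
    contigs = {c: Contig(c, 5000) for c in "ABC"}
    edges = [
        _edge(0, "A", 1, "B", 1, gap=100.0, sd=30.0),
        _edge(1, "B", 1, "C", 1, gap=100.0, sd=30.0),
        _edge(2, "A", -1, "C", -1, gap=100.0, sd=30.0, support=3),
    ]
    res = scaffold_subgraph(contigs, edges, cfg)
    assert res.k == 1


def test_repeat_placed_between_uniques(cfg):
    contigs = {"A": Contig("A", 5000), "C": Contig("C", 5000),
               "R": Contig("R", 2000, is_repeat=True)}
    edges = [
        _edge(0, "A", 1, "R", 1, gap=100.0, sd=30.0),
        _edge(1, "C", -1, "R", -1, gap=100.0, sd=30.0),   # R then C
        _edge(2, "A", 1, "C", 1, gap=2200.0, sd=50.0),
    ]
    res = scaffold_subgraph(contigs, edges, cfg)
    assert res.k == 0
    mids = [c for c, _, _, _ in res.instances]
    assert mids in (["A", "R", "C"], ["C", "R", "A"])
    # dropping the repeat instance breaks at least one edge
    view = GraphView(contigs, edges, cfg)
    without = [t for t in res.instances if t[0] != "R"]
    k_without, _ = score_placement(view, without)
    assert k_without > res.k


def test_speculative_repeat_not_kept(cfg):
    # repeat linked to A only loosely: a scaffold without it is optimal
    contigs = {"A": Contig("A", 5000), "B": Contig("B", 5000),
               "R": Contig("R", 2000, is_repeat=True)}
    edges = [
        _edge(0, "A", 1, "B", 1, gap=100.0, sd=30.0),
    ]
    res = scaffold_subgraph(contigs, edges, cfg)
    assert res.k == 0
    assert all(c != "R" for c, _, _, _ in res.instances)


def test_repeat_only_subgraph_singletons(cfg):
    contigs = {"R": Contig("R", 2000, is_repeat=True),
               "S": Contig("S", 2500, is_repeat=True)}
    res = scaffold_subgraph(contigs, [], cfg)
    assert sorted(c for c, _, _, _ in res.instances) == ["R", "S"]
    assert "repeat-only subgraph" in res.flags


def test_reversal_symmetry(cfg):
    """Reversing every edge constraint yields the mirrored optimum."""
    for seed in range(10):
        contigs, edges = random_scaffold_graph(seed)
        rev = [ScaffoldEdge(e.id, e.c1, -e.o1, e.c2, -e.o2, e.gap, e.sd,
                            e.support) for e in edges]
        k1 = scaffold_subgraph(contigs, edges, cfg).k
        k2 = scaffold_subgraph(contigs, rev, cfg).k
        assert k1 == k2


# ---------------------------------------------------------------------------
# memoization
# ---------------------------------------------------------------------------

def test_memo_table_dominance():
    t = MemoTable()
    key = [("A", 1, 0, False), ("|",), 3, ("|",), "A", "B"]
    assert t.admit(key, 2)
    assert not t.admit(key, 2)          # equal k: pruned
    assert not t.admit(key, 3)          # worse k: pruned
    assert t.admit(key, 1)              # better k: admitted, updates
    assert not t.admit(key, 1)
    assert t.insertions == 2


def test_memo_soundness_and_savings(cfg):
    strict = 0
    for seed in range(12):
        contigs, edges = random_scaffold_graph(seed)
        on = scaffold_subgraph(contigs, edges, Config(edge_support=1))
        off = scaffold_subgraph(contigs, edges,
                                Config(edge_support=1, memo_enabled=False))
        assert on.k == off.k
        assert on.instances == off.instances
        assert on.stats["states"] <= off.stats["states"]
        strict += on.stats["states"] < off.stats["states"]
    assert strict > 0                   # memo saves work where paths branch


def test_state_cap_triggers_support_escalation():
    import numpy as np
    rng = np.random.default_rng(5)
    contigs = {f"c{i}": Contig(f"c{i}", int(rng.integers(3000, 8000)))
               for i in range(6)}
    names = sorted(contigs)
    edges = []
    for i in range(6):
        for j in range(i + 1, 6):
            edges.append(ScaffoldEdge(
                len(edges), names[i], int(rng.choice([1, -1])), names[j],
                int(rng.choice([1, -1])), float(rng.integers(100, 4000)),
                float(rng.integers(30, 80)),
                int(rng.integers(5, 5 + len(edges) % 6 + 1))))
    res = scaffold_subgraph(contigs, edges, Config(edge_support=1, state_cap=100))
    assert res.flags and "hybrid" in res.flags[0]
    assert res.stats["support_threshold"] > 1
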