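"""Scaffold-graph construction: classification, bundling, edge length
estimation, multi-library merging, filters, staging."""

import math

import numpy as np
import pytest

from jumpscaf.graph import (Contig, RawEdge, ScaffoldEdge, ScaffoldGraph,
                            TruncatedInsertModel, apply_filters, bundle_pairs,
                            classify_contigs, compute_coverage,
                            drop_repeat_repeat_edges, estimate_edge_gap,
                            merge_libraries, pair_to_raw_key, stage_libraries)
from jumpscaf.io import Config, MappingRecord
from jumpscaf.library import INWARD, OUTWARD, SAME, Library


def _lib(mu=3000.0, sigma=300.0, dist=None, orientation=INWARD):
    if dist is None:
        dist = np.full(1000, mu)
    return Library(id="l", orientation=orientation, mu=mu, sigma=sigma,
                   q1=float(np.percentile(dist, 25)),
                   q3=float(np.percentile(dist, 75)), distances=np.asarray(dist))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_classify_repeat_thresholds():
    contigs = {
        "a": Contig("a", 1000, coverage=40.0),
        "b": Contig("b", 1000, coverage=40.0),
        "c": Contig("c", 1000, coverage=40.0),
        "r": Contig("r", 1000, coverage=70.0),
    }
    # force the genome mean to 40 by making unique contigs dominate
    for c in "abc":
        contigs[c].length = 100000
    mean = classify_contigs(contigs, repeat_factor=1.5)
    assert 39 < mean < 41
    assert contigs["r"].is_repeat and not contigs["a"].is_repeat
    # boundary: exactly factor x mean is a repeat (not strictly below)
    contigs["r"].coverage = 1.5 * mean
    classify_contigs(contigs, repeat_factor=1.5)
    assert contigs["r"].is_repeat
    # larger factor turns it unique again
    contigs["r"].coverage = 70.0
    classify_contigs(contigs, repeat_factor=2.0)
    assert not contigs["r"].is_repeat


def test_compute_coverage():
    contigs = {"a": Contig("a", 1000)}
    recs = [MappingRecord(f"q{i}", 1, "a", 0, "+", 100, "l") for i in range(20)]
    compute_coverage(contigs, recs)
    assert contigs["a"].coverage == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# bundling and orientation classes
# ---------------------------------------------------------------------------

def _cross_pair(c1, p1, s1, c2, p2, s2, rlen=100):
    return (MappingRecord("q", 1, c1, p1, s1, rlen, "l"),
            MappingRecord("q", 2, c2, p2, s2, rlen, "l"))


def test_pair_to_raw_inward_geometry():
    lengths = {"A": 1000, "B": 2000}
    # read1 forward near A's end, read2 reverse near B's start: A+ then B+
    key, s_hat = pair_to_raw_key(*_cross_pair("A", 800, "+", "B", 100, "-"),
                                 INWARD, lengths)
    assert key == ("A", 1, "B", 1)
    assert s_hat == (1000 - 800) + (100 + 100)   # overhangs on both sides


def test_pair_to_raw_canonicalizes_ids():
    lengths = {"A": 1000, "B": 2000}
    # same physical configuration reported with B's read first
    k1, s1 = pair_to_raw_key(*_cross_pair("A", 800, "+", "B", 100, "-"),
                             INWARD, lengths)
    k2, s2 = pair_to_raw_key(*_cross_pair("B", 100, "-", "A", 800, "+"),
                             INWARD, lengths)
    assert k1 == k2 and s1 == s2


def test_bundle_groups_by_orientation_class():
    lengths = {"A": 1000, "B": 2000}
    lib = _lib()
    pairs = [_cross_pair("A", 800, "+", "B", 100, "-") for _ in range(5)]
    pairs += [_cross_pair("A", 800, "+", "B", 1900, "+") for _ in range(3)]
    pairs += [_cross_pair("A", 500, "+", "A", 900, "-")]     # same contig
    raws = bundle_pairs(lib, pairs, lengths)
    assert len(raws) == 2
    assert sorted(len(r.s_obs) for r in raws) == [3, 5]


# ---------------------------------------------------------------------------
# truncation-corrected gap estimation
# ---------------------------------------------------------------------------

def test_lookup_point_mass_inversion():
    model = TruncatedInsertModel(_lib(3000, 1.0))
    raw = RawEdge("A", 1, "B", 1, "l", [2400.0])
    g, sd, clamped = estimate_edge_gap(raw, model, {"A": 2000, "B": 2000})
    assert g == 600 and not clamped
    assert sd == pytest.approx(model.library.sigma)   # single observation


def test_lookup_uniform_truncation():
    # I uniform on [2000, 4000]
    dist = np.repeat(np.arange(2000, 4001), 3).astype(float)
    lib = _lib(3000, 577.0, dist)
    model = TruncatedInsertModel(lib)
    # wide window: no truncation effect, E(S) = 3000 - g
    tab = model.table(100000)
    assert tab[1500] == pytest.approx(1500.0)
    # g=2500, C=3500: E(I | [2500,3500]) = 3000 so E(S) = 500
    tab2 = model.table(1000)
    assert tab2[2500] == pytest.approx(500.0)
    # monotone decreasing wherever defined; strictly so where the window
    # clips the support (interior windows leave E(S) flat for a uniform)
    valid = tab2[~np.isnan(tab2)]
    assert np.all(np.diff(valid) <= 0)
    assert np.all(np.diff(tab2[3100:3900]) < 0)


def test_lookup_bucket_rounding_ties_down():
    model = TruncatedInsertModel(_lib())
    assert model.bucket_for(250) == 0       # tie rounds down
    assert model.bucket_for(251) == 500
    assert model.bucket_for(749) == 500
    assert model.bucket_for(751) == 1000


def test_lookup_clamps_out_of_range_mean():
    model = TruncatedInsertModel(_lib(3000, 1.0))
    raw = RawEdge("A", 1, "B", 1, "l", [9999.0])
    g, _, clamped = estimate_edge_gap(raw, model, {"A": 2000, "B": 2000})
    assert clamped and g == 0


def test_edge_sd_scales_with_support():
    model = TruncatedInsertModel(_lib(3000, 300.0))
    raw = RawEdge("A", 1, "B", 1, "l", [2400.0] * 25)
    _, sd, _ = estimate_edge_gap(raw, model, {"A": 2000, "B": 2000})
    assert sd == pytest.approx(300.0 / 5)


def test_gap_recovery_through_simulator():
    """Estimator composed with truncated sampling recovers the true gap."""
    from scipy import stats
    rng = np.random.default_rng(3)
    sample = rng.normal(10000, 1000, 10000)
    model = TruncatedInsertModel(_lib(10000, 1000.0, sample))
    lengths = {"A": 6000, "B": 6000}
    hits = total = 0
    for g in range(2000, 12001, 1000):
        a, b = (g - 10000) / 1000, (g + 12000 - 10000) / 1000
        draws = stats.truncnorm.rvs(a, b, loc=10000, scale=1000, size=100,
                                    random_state=int(rng.integers(2**31)))
        raw = RawEdge("A", 1, "B", 1, "l", list(draws - g))
        ghat, _, _ = estimate_edge_gap(raw, model, lengths)
        total += 1
        hits += abs(ghat - g) <= 500 + 3 * 1000 / math.sqrt(100)
    assert hits / total >= 0.95


# ---------------------------------------------------------------------------
# merging, filters, staging
# ---------------------------------------------------------------------------

def _edge(eid, gap, sd, support, c1="A", c2="B", o1=1, o2=1, libs=("x",)):
    return ScaffoldEdge(eid, c1, o1, c2, o2, gap, sd, support, libs)


def test_merge_inverse_variance_example():
    contigs = {"A": Contig("A", 1000), "B": Contig("B", 1000)}
    merged = merge_libraries(
        [_edge(0, 5000.0, 300.0, 10, libs=("a",)),
         _edge(1, 5200.0, 400.0, 6, libs=("b",))], contigs)
    assert len(merged) == 1
    e = merged[0]
    assert e.gap == pytest.approx(5072.0, abs=0.5)
    assert e.sd == pytest.approx(240.0, abs=0.5)
    assert e.support == 16 and e.libs == ("a", "b")


def test_merge_single_edge_unchanged():
    contigs = {"A": Contig("A", 1000), "B": Contig("B", 1000)}
    merged = merge_libraries([_edge(0, 5000.0, 300.0, 10)], contigs)
    assert merged[0].gap == 5000.0 and merged[0].support == 10


def test_merge_conflicting_unique_edges_keep_max_support():
    contigs = {"A": Contig("A", 1000), "B": Contig("B", 1000)}
    merged = merge_libraries(
        [_edge(0, 3000.0, 100.0, 8), _edge(1, 20000.0, 100.0, 3)], contigs)
    assert len(merged) == 1 and merged[0].support == 8


def test_merge_repeat_pair_keeps_all_clusters():
    contigs = {"A": Contig("A", 1000), "R": Contig("R", 1000, is_repeat=True)}
    merged = merge_libraries(
        [_edge(0, 3000.0, 100.0, 8, c2="R"), _edge(1, 20000.0, 100.0, 3, c2="R")],
        contigs)
    assert len(merged) == 2


def test_apply_filters():
    contigs = {"A": Contig("A", 550), "B": Contig("B", 5000),
               "C": Contig("C", 5000)}
    edges = [_edge(0, 100.0, 30.0, 4, "B", "C"),
             _edge(1, 100.0, 30.0, 5, "B", "C", o2=-1)]
    g, singles = apply_filters(ScaffoldGraph(contigs, edges), Config(), 300.0)
    assert singles == ["A"]                      # below max(500, 600)
    assert [e.support for e in g.edges] == [5]   # n_e = 4 removed at default 5
    g2, _ = apply_filters(ScaffoldGraph(contigs, edges),
                          Config(edge_support=1), 300.0)
    assert len(g2.edges) == 2                    # long-read mode keeps n_e >= 1


def test_stage_libraries_boundaries():
    def lib(mu):
        return Library(id=f"l{mu}", orientation=INWARD, mu=mu, sigma=mu / 10,
                       q1=0, q3=1)
    libs = [lib(300), lib(3000), lib(10000), lib(20000)]
    stages = stage_libraries(libs, Config(staged=True))
    assert [[l.mu for l in s] for s in stages] == [[300], [3000, 10000], [20000]]
    assert len(stage_libraries(libs, Config(staged=False))) == 1
    assert len(stage_libraries([lib(3000)], Config(staged=True))) == 1


def test_drop_repeat_repeat_edges():
    contigs = {"R": Contig("R", 1000, is_repeat=True),
               "S": Contig("S", 1000, is_repeat=True),
               "A": Contig("A", 1000)}
    g = ScaffoldGraph(contigs, [_edge(0, 10.0, 30.0, 5, "R", "S"),
                                _edge(1, 10.0, 30.0, 5, "A", "R")])
    assert drop_repeat_repeat_edges(g) == 1
    assert len(g.edges) == 1 and g.edges[0].c2 == "R"
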