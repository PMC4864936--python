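"""Library parameter estimation: insert sizes, quartile filtering,
orientation voting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from jumpscaf.io import MappingRecord
from jumpscaf.library import (INWARD, OUTWARD, SAME, LibraryError,
                              estimate_library, iqr_filter, pair_orientation,
                              preliminary_insert)
from conftest import make_same_contig_pairs


def _pair(contig, s, span, st1="+", st2="-", rlen=100, swap=False):
    r1 = MappingRecord("q", 1 if not swap else 2, contig, s, st1, rlen, "l")
    r2 = MappingRecord("q", 2 if not swap else 1, contig, s + span - rlen,
                       st2, rlen, "l")
    return (r1, r2)


def test_preliminary_insert_uses_first_1000():
    pairs = [_pair("c", 0, 3000) for _ in range(1000)]
    pairs += [_pair("c", 0, 9000) for _ in range(500)]   # ignored: beyond 1000
    assert preliminary_insert(pairs) == 3000


def test_preliminary_insert_mean():
    pairs = [_pair("c", 0, 2900) for _ in range(5)]
    pairs += [_pair("c", 0, 3100) for _ in range(5)]
    assert preliminary_insert(pairs) == 3000


def test_preliminary_insert_no_pairs():
    r1 = MappingRecord("q", 1, "a", 0, "+", 100, "l")
    r2 = MappingRecord("q", 2, "b", 0, "-", 100, "l")
    with pytest.raises(LibraryError):
        preliminary_insert([(r1, r2)])


def test_iqr_filter_degenerate_and_outlier():
    assert list(iqr_filter([100.0] * 10)) == [100.0] * 10
    dense = list(np.linspace(2900, 3100, 99)) + [9000.0]
    kept = iqr_filter(dense)
    assert 9000.0 not in kept and len(kept) == 99


def test_iqr_filter_idempotent():
    rng = np.random.default_rng(0)
    d = rng.normal(3000, 300, 500)
    once = iqr_filter(d)
    twice = iqr_filter(once)
    assert sorted(once) == sorted(twice)


@given(st.lists(st.floats(min_value=0, max_value=1e6,
                          allow_nan=False), min_size=4, max_size=60))
def test_iqr_filter_output_subset(d):
    kept = list(iqr_filter(d))
    pool = list(d)
    for v in kept:
        pool.remove(v)          # raises if kept is not a sub-multiset


def test_pair_orientation_classes():
    assert pair_orientation(*_pair("c", 0, 3000, "+", "-")) == INWARD
    assert pair_orientation(*_pair("c", 0, 3000, "-", "+")) == OUTWARD
    assert pair_orientation(*_pair("c", 0, 3000, "+", "+")) == SAME


def test_estimate_library_recovers_parameters():
    pairs = make_same_contig_pairs(10000, 3000, 300, seed=11)
    lib = estimate_library(pairs, {"big": 10**6}, "l")
    assert lib.orientation == INWARD
    assert abs(lib.mu - 3000) / 3000 < 0.01
    assert abs(lib.sigma - 300) / 300 < 0.05
    assert lib.upper == pytest.approx(lib.mu + 6 * lib.sigma)


def test_estimate_library_same_strand_and_tie():
    pairs = make_same_contig_pairs(200, 3000, 100, seed=2, orientation="same")
    lib = estimate_library(pairs, {"big": 10**6}, "l")
    assert lib.orientation == SAME
    # tie: equal inward and outward votes -> inward preferred
    pairs = (make_same_contig_pairs(100, 3000, 100, seed=3, orientation="inward")
             + make_same_contig_pairs(100, 3000, 100, seed=4,
                                      orientation="outward"))
    lib = estimate_library(pairs, {"big": 10**6}, "l")
    assert lib.orientation == INWARD


def test_orientation_invariant_to_mate_swap():
    pairs = make_same_contig_pairs(500, 3000, 300, seed=7)
    swapped = [
        (MappingRecord(r2.qname, 1, r2.contig, r2.pos, r2.strand, r2.rlen, r2.lib),
         MappingRecord(r1.qname, 2, r1.contig, r1.pos, r1.strand, r1.rlen, r1.lib))
        for r1, r2 in pairs]
    a = estimate_library(pairs, {"big": 10**6}, "l")
    b = estimate_library(swapped, {"big": 10**6}, "l")
    assert a.orientation == b.orientation == INWARD
    assert a.mu == pytest.approx(b.mu)


def test_short_contigs_excluded():
    # all pairs on a contig barely above the preliminary insert: excluded
    pairs = make_same_contig_pairs(100, 3000, 100, seed=9, contig="small",
                                   contig_len=8000)
    with pytest.raises(LibraryError):
        estimate_library(pairs, {"small": 5000}, "l")
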