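"""Gap sizing: worked examples, agreement with independent bounded
least-squares solutions, translation invariance."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import lsq_linear

from jumpscaf.gaps import GapConstraint, GapSystem, estimate_gap_sizes


def test_single_edge_single_gap():
    sys = GapSystem(lengths=[1000, 1000],
                    constraints=[GapConstraint(0, 1, 500.0, 50.0)])
    x, info = estimate_gap_sizes(sys)
    assert x[0] == pytest.approx(500.0)
    assert info["kkt_residual"] < 1e-6


def test_two_edges_weighted_mean():
    # (500, sd 50) and (800, sd 100), equal support -> 560
    sys = GapSystem(lengths=[1000, 1000],
                    constraints=[GapConstraint(0, 1, 500.0, 50.0),
                                 GapConstraint(0, 1, 800.0, 100.0)])
    x, _ = estimate_gap_sizes(sys)
    assert x[0] == pytest.approx(560.0)


def test_tight_edge_pins_spanned_gap():
    # spanning edge g=3000 over a 1000-bp interior contig; a near-exact
    # edge fixes gap1 = 400, so gap2 -> 1600
    sys = GapSystem(lengths=[1000, 1000, 1000],
                    constraints=[GapConstraint(0, 1, 400.0, 0.01),
                                 GapConstraint(0, 2, 3000.0, 100.0)])
    x, _ = estimate_gap_sizes(sys)
    assert x[0] == pytest.approx(400.0, abs=0.1)
    assert x[1] == pytest.approx(1600.0, abs=0.1)


def test_support_weighting_switch():
    sys = GapSystem(lengths=[1000, 1000],
                    constraints=[GapConstraint(0, 1, 500.0, 100.0, support=4),
                                 GapConstraint(0, 1, 800.0, 100.0, support=1)])
    x_w, _ = estimate_gap_sizes(sys, weight_by_support=True)
    x_u, _ = estimate_gap_sizes(sys, weight_by_support=False)
    assert x_w[0] == pytest.approx(560.0)      # 4:1 weights
    assert x_u[0] == pytest.approx(650.0)      # plain average


def test_unconstrained_gap_keeps_default():
    sys = GapSystem(lengths=[1000, 1000, 1000],
                    constraints=[GapConstraint(0, 1, 500.0, 50.0)],
                    defaults=[0.0, 321.0])
    x, _ = estimate_gap_sizes(sys)
    assert x[1] == pytest.approx(321.0)


def test_infeasible_bounds():
    sys = GapSystem(lengths=[1000, 1000], constraints=[],
                    delta_min=10.0, delta_max=-10.0)
    with pytest.raises(ValueError):
        estimate_gap_sizes(sys)


def _random_system(rng, n_gaps):
    lengths = rng.integers(500, 5000, n_gaps + 1).astype(float)
    cons = []
    for _ in range(rng.integers(n_gaps, 2 * n_gaps + 1)):
        i = int(rng.integers(0, n_gaps))
        j = int(rng.integers(i + 1, n_gaps + 1))
        interior = float(lengths[i + 1:j].sum())
        cons.append(GapConstraint(i, j, interior + float(rng.integers(0, 2000)),
                                  float(rng.integers(20, 200)),
                                  int(rng.integers(1, 20))))
    for t in range(n_gaps):           # cover every gap so the QP is bounded
        cons.append(GapConstraint(t, t + 1, float(rng.integers(0, 1500)),
                                  float(rng.integers(20, 200))))
    return GapSystem(lengths=list(lengths), constraints=cons,
                     delta_min=-500.0, delta_max=50000.0)


@pytest.mark.parametrize("seed", range(8))
def test_matches_independent_bounded_least_squares(seed):
    """Coordinate descent agrees with scipy's bounded LSQ on dense systems."""
    rng = np.random.default_rng(seed)
    n_gaps = int(rng.integers(2, 7))
    sys = _random_system(rng, n_gaps)
    x, info = estimate_gap_sizes(sys)
    rows, b, w = [], [], []
    for c in sys.constraints:
        row = np.zeros(n_gaps)
        row[c.i:c.j] = 1.0
        rows.append(row)
        b.append(c.gap - float(np.sum(sys.lengths[c.i + 1:c.j])))
        w.append(np.sqrt(c.support) / c.sd)
    A = np.array(rows) * np.array(w)[:, None]
    ref = lsq_linear(A, np.array(b) * np.array(w),
                     bounds=(sys.delta_min, sys.delta_max), tol=1e-14)
    assert np.allclose(x, ref.x, rtol=1e-6, atol=1e-4)
    assert info["kkt_residual"] < 1e-4


@given(st.integers(min_value=-400, max_value=2000))
def test_translation_of_single_gap_edges(delta):
    """Shifting every single-gap constraint by delta shifts the solution."""
    base = [GapConstraint(0, 1, 600.0, 50.0), GapConstraint(1, 2, 900.0, 50.0)]
    shifted = [GapConstraint(c.i, c.j, c.gap + delta, c.sd) for c in base]
    x0, _ = estimate_gap_sizes(GapSystem([1000, 1000, 1000], base))
    x1, _ = estimate_gap_sizes(GapSystem([1000, 1000, 1000], shifted))
    assert np.allclose(x1, x0 + delta, atol=1e-6)
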