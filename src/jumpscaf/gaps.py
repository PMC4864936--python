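"""Maximum-likelihood gap sizing for a fixed contig order and orientation.

Scaffold edges impose Gaussian distance constraints that may span
several gaps, so the gap vector is estimated jointly: with D_e(x) the
distance implied by gap vector x (interior contig lengths plus spanned
gaps), the negative log-likelihood is the weighted least-squares
objective

    sum_e  w_e (D_e(x) - g_e)^2,     w_e = n_e / sigma_e^2

minimized subject to box bounds on each gap (a modest negative lower
bound allows contig overlap).  The objective is convex; a projected
coordinate descent with a deterministic sweep order solves the bound-
constrained quadratic program.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


@dataclass
class GapConstraint:
    i: int          # left instance index
    j: int          # right instance index (i < j)
    gap: float      # g_e
    sd: float
    support: int = 1

    def __post_init__(self):
        if self.i >= self.j:
            raise ValueError("constraint must have i < j")


@dataclass
class GapSystem:
    lengths: Sequence[float]             # instance lengths, in scaffold order
    constraints: List[GapConstraint]
    delta_min: float = -500.0
    delta_max: float = 1e9
    defaults: Optional[Sequence[float]] = None   # for unconstrained gaps

    @property
    def n_gaps(self) -> int:
        return len(self.lengths) - 1


def estimate_gap_sizes(system: GapSystem, weight_by_support: bool = True,
                       tol: float = 1e-8, max_iter: int = 10000
                       ) -> Tuple[np.ndarray, dict]:
    """Solve the bound-constrained weighted least-squares gap program.

    Returns (gaps, info); info reports iterations, the final objective
    and the maximum projected-gradient (KKT) residual.  Gaps spanned by
    no constraint keep their default (source-edge estimate) or the lower
    bound.  Flat directions resolve toward the lower bound (the solver
    is initialized there).
    """
    if system.delta_min > system.delta_max:
        raise ValueError("infeasible gap bounds: delta_min > delta_max")
    n = system.n_gaps
    x = np.full(n, system.delta_min, dtype=float)
    covered = np.zeros(n, dtype=bool)
    rows = []          # (gap index array, b_e, w_e)
    lengths = np.asarray(system.lengths, dtype=float)
    for c in system.constraints:
        idx = np.arange(c.i, c.j)
        covered[idx] = True
        interior = float(lengths[c.i + 1:c.j].sum())
        w = (c.support if weight_by_support else 1.0) / (c.sd ** 2)
        rows.append((idx, c.gap - interior, w))
    if system.defaults is not None:
        d = np.clip(np.asarray(system.defaults, float),
                    system.delta_min, system.delta_max)
        x[~covered] = d[~covered]

    by_gap: Dict[int, List[int]] = {t: [] for t in range(n)}
    for r, (idx, b, w) in enumerate(rows):
        for t in idx:
            by_gap[t].append(r)

    def objective():
        return sum(w * (x[idx].sum() - b) ** 2 for idx, b, w in rows)

    it = 0
    for it in range(1, max_iter + 1):
        dx = 0.0
        for t in range(n):
            if not by_gap[t]:
                continue
            num = den = 0.0
            for r in by_gap[t]:
                idx, b, w = rows[r]
                num += w * (b - (x[idx].sum() - x[t]))
                den += w
            new = min(max(num / den, system.delta_min), system.delta_max)
            dx = max(dx, abs(new - x[t]))
            x[t] = new
        if dx < tol * (1.0 + float(np.max(np.abs(x)))):
            break
    obj = objective()

    kkt = 0.0
    for t in range(n):
        if not by_gap[t]:
            continue
        grad = sum(2 * rows[r][2] * (x[rows[r][0]].sum() - rows[r][1])
                   for r in by_gap[t])
        if x[t] <= system.delta_min + 1e-12:
            viol = max(0.0, -grad)
        elif x[t] >= system.delta_max - 1e-12:
            viol = max(0.0, grad)
        else:
            viol = abs(grad)
        kkt = max(kkt, viol)
    return x, {"iterations": it, "objective": obj, "kkt_residual": kkt}
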