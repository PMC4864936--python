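"""Per-library insert-size and orientation estimation.

Library parameters (orientation, mean insert mu, standard deviation
sigma) are estimated directly from read mappings rather than taken from
user input: a preliminary insert size from the first 1000 same-contig
pairs selects the contigs long enough (> 2x the insert) to be unbiased,
and quartile-based outlier rejection guards against mis-assemblies and
mis-mappings.  The pair distance convention throughout is the
outermost-coordinate span, which includes both read lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .io import MappingRecord

log = logging.getLogger("jumpscaf")

INWARD, OUTWARD, SAME = "inward", "outward", "same-strand"
_TIE_ORDER = (INWARD, OUTWARD, SAME)


class LibraryError(ValueError):
    pass


@dataclass
class Library:
    """Estimated properties of one jumping library."""

    id: str
    orientation: str
    mu: float
    sigma: float
    q1: float
    q3: float
    support_threshold: int = 5
    sd_multiplier: float = 6.0
    upper: Optional[float] = None          # L; default mu + k*sigma
    distances: Optional[np.ndarray] = None  # IQR-filtered same-contig spans

    def __post_init__(self):
        if self.upper is None:
            self.upper = self.mu + self.sd_multiplier * self.sigma

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def pair_span(r1: MappingRecord, r2: MappingRecord) -> int:
    """Outermost-coordinate span of a same-contig pair."""
    return max(r1.end, r2.end) - min(r1.pos, r2.pos)


def pair_orientation(r1: MappingRecord, r2: MappingRecord) -> str:
    """Orientation class of a same-contig pair (by leftmost read)."""
    left, right = (r1, r2) if (r1.pos, r1.mate) <= (r2.pos, r2.mate) else (r2, r1)
    if left.strand == right.strand:
        return SAME
    return INWARD if left.strand == "+" else OUTWARD


def same_contig_pairs(pairs: Iterable[Tuple[MappingRecord, MappingRecord]]):
    for r1, r2 in pairs:
        if r1.contig == r2.contig:
            yield r1, r2


def preliminary_insert(pairs: Sequence[Tuple[MappingRecord, MappingRecord]],
                       n: int = 1000) -> float:
    """Mean span of the first ``n`` same-contig pairs, in input order."""
    spans = []
    for r1, r2 in same_contig_pairs(pairs):
        spans.append(pair_span(r1, r2))
        if len(spans) >= n:
            break
    if not spans:
        raise LibraryError(
            "no read pairs map with both ends on one contig; the contigs may "
            "be shorter than the library insert size")
    return float(np.mean(spans))


def iqr_filter(distances: Sequence[float]) -> np.ndarray:
    """Keep distances within [Q1 - 3*IQR, Q3 + 3*IQR].

    Quartiles use linear interpolation between order statistics and are
    computed once on the input (the filter is not iterated).
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 4:
        raise LibraryError("need at least 4 distances for quartile filtering")
    q1, q3 = np.percentile(d, [25, 75])
    iqr = q3 - q1
    return d[(d >= q1 - 3 * iqr) & (d <= q3 + 3 * iqr)]


def estimate_library(pairs: Sequence[Tuple[MappingRecord, MappingRecord]],
                     contig_lengths: dict, lib_id: str,
                     support_threshold: int = 5,
                     sd_multiplier: float = 6.0,
                     sigma_floor: float = 1.0) -> Library:
    """Estimate orientation, mu and sigma from same-contig pairs.

    Only pairs on contigs longer than twice the preliminary insert
    estimate contribute (both to orientation voting and to mu/sigma).
    """
    prelim = preliminary_insert(pairs)
    min_len = 2 * prelim
    votes = {INWARD: 0, OUTWARD: 0, SAME: 0}
    spans = []
    for r1, r2 in same_contig_pairs(pairs):
        if contig_lengths.get(r1.contig, 0) <= min_len:
            continue
        votes[pair_orientation(r1, r2)] += 1
        spans.append(pair_span(r1, r2))
    if not spans:
        raise LibraryError(
            f"library {lib_id}: no contig exceeds 2x the preliminary insert "
            f"({prelim:.0f} bp); supply library parameters manually")
    best = max(votes.values())
    orientation = next(o for o in _TIE_ORDER if votes[o] == best)
    if sum(1 for v in votes.values() if v == best) > 1:
        log.info("library %s: orientation tie, preferring %s", lib_id, orientation)
    kept = iqr_filter(spans) if len(spans) >= 4 else np.asarray(spans, float)
    q1, q3 = np.percentile(np.asarray(spans, float), [25, 75])
    mu = float(np.mean(kept))
    sigma = max(float(np.std(kept)), sigma_floor)
    lib = Library(id=lib_id, orientation=orientation, mu=mu, sigma=sigma,
                  q1=float(q1), q3=float(q3),
                  support_threshold=support_threshold,
                  sd_multiplier=sd_multiplier, distances=kept)
    log.info("library %s: %s, mu=%.1f sigma=%.1f (n=%d, L=%.0f)",
             lib_id, orientation, mu, sigma, kept.size, lib.upper)
    return lib
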