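"""Scaffold-graph construction.

Nodes are contigs, classified unique/repeat by read coverage; edges are
bundles of read pairs linking two contigs in one relative-orientation
class, annotated with a gap estimate and its standard deviation.  Gap
estimation corrects for the truncation bias of observed inserts: pairs
spanning a gap are only observed when the insert fits the flanking
contigs, so the naive estimate mu - mean(span) is biased.  Following
the reverse-lookup construction, for gap size g and flanking contig
length sum l we tabulate E(S_hat) = E(I | g <= I <= g + l) - g over g
in [0, L] (S_hat being the portion of the insert covered by contig
sequence) and invert the table at the observed mean of S_hat.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io import Config, MappingRecord
from .library import INWARD, OUTWARD, SAME, Library

log = logging.getLogger("jumpscaf")


# ---------------------------------------------------------------------------
# node and edge types
# ---------------------------------------------------------------------------

@dataclass
class Contig:
    id: str
    length: int
    coverage: Optional[float] = None
    is_repeat: bool = False

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"contig {self.id}: non-positive length")


@dataclass
class ScaffoldEdge:
    """Bundled orientation/distance constraint between two contigs.

    Semantics: the scaffold satisfies the edge iff it contains c1 with
    orientation o1 followed (left to right) by c2 with orientation o2 at
    a gap close to ``gap`` -- or the mirror image (c2 at -o2 then c1 at
    -o1).  Endpoints are canonical: c1 <= c2 lexicographically.
    """

    id: int
    c1: str
    o1: int          # +1 / -1
    c2: str
    o2: int
    gap: float
    sd: float
    support: int
    libs: Tuple[str, ...] = ()
    flagged: bool = False     # gap estimate clamped to the table boundary

    def key(self) -> tuple:
        return (self.c1, self.o1, self.c2, self.o2)

    def other(self, contig: str) -> str:
        return self.c2 if contig == self.c1 else self.c1


@dataclass
class RawEdge:
    """Read-pair bundle for one (contig pair, orientation class, library)."""

    c1: str
    o1: int
    c2: str
    o2: int
    lib: str
    s_obs: List[float] = field(default_factory=list)

    def key(self) -> tuple:
        return (self.c1, self.o1, self.c2, self.o2)


class ScaffoldGraph:
    def __init__(self, contigs: Dict[str, Contig],
                 edges: Optional[List[ScaffoldEdge]] = None):
        self.contigs = contigs
        self.edges: List[ScaffoldEdge] = list(edges or [])

    def add_edge(self, edge: ScaffoldEdge) -> None:
        for c in (edge.c1, edge.c2):
            if c not in self.contigs:
                raise KeyError(f"edge endpoint {c!r} not in graph")
        self.edges.append(edge)

    def adjacency(self) -> Dict[str, List[ScaffoldEdge]]:
        adj: Dict[str, List[ScaffoldEdge]] = {c: [] for c in self.contigs}
        for e in self.edges:
            adj[e.c1].append(e)
            if e.c2 != e.c1:
                adj[e.c2].append(e)
        return adj

    def unique_edges(self) -> List[ScaffoldEdge]:
        """Edges of u(G): both endpoints unique."""
        return [e for e in self.edges
                if not self.contigs[e.c1].is_repeat
                and not self.contigs[e.c2].is_repeat]


# ---------------------------------------------------------------------------
# coverage and repeat classification
# ---------------------------------------------------------------------------

def compute_coverage(contigs: Dict[str, Contig],
                     mappings: Iterable[MappingRecord]) -> None:
    """Mean reads-per-base per contig from primary alignments."""
    bases = {c: 0 for c in contigs}
    for rec in mappings:
        bases[rec.contig] += rec.rlen
    for c, ctg in contigs.items():
        ctg.coverage = bases[c] / ctg.length


def classify_contigs(contigs: Dict[str, Contig],
                     repeat_factor: float = 1.5) -> float:
    """Mark repeats: coverage >= factor x length-weighted genome mean.

    Returns the genome mean coverage.  Contigs strictly below the
    threshold are unique; the boundary itself is a repeat.
    """
    total_len = sum(c.length for c in contigs.values())
    mean = sum((c.coverage or 0.0) * c.length for c in contigs.values()) / total_len
    thresh = repeat_factor * mean
    for c in contigs.values():
        c.is_repeat = (c.coverage or 0.0) >= thresh
    n_rep = sum(c.is_repeat for c in contigs.values())
    log.info("coverage mean %.2f; %d/%d contigs classified repeat",
             mean, n_rep, len(contigs))
    return mean


# ---------------------------------------------------------------------------
# read pairs -> raw edges
# ---------------------------------------------------------------------------

def _sgn(strand: str) -> int:
    return 1 if strand == "+" else -1


def pair_to_raw_key(r1: MappingRecord, r2: MappingRecord,
                    orientation: str, contig_lengths: Dict[str, int]):
    """Orientation class and S_hat observation for a cross-contig pair.

    Returns ((c1, o1, c2, o2), s_hat) in canonical (c1 <= c2) form, or
    None for same-contig pairs.
    """
    if r1.contig == r2.contig:
        return None
    # choose the left-hand read of the implied configuration
    if orientation == SAME:
        left, right = (r1, r2) if r1.mate == 1 else (r2, r1)
    else:
        left, right = r1, r2
    sl, sr = _sgn(left.strand), _sgn(right.strand)
    if orientation == INWARD:
        ol, orr = sl, -sr
    elif orientation == OUTWARD:
        ol, orr = -sl, sr
    else:
        ol, orr = sl, sr
    ll = contig_lengths[left.contig]
    lr = contig_lengths[right.contig]
    # overhang toward the gap on each side (outermost-span convention)
    s_left = (ll - left.pos) if ol == 1 else (left.pos + left.rlen)
    s_right = (right.pos + right.rlen) if orr == 1 else (lr - right.pos)
    s_hat = float(s_left + s_right)
    if left.contig <= right.contig:
        key = (left.contig, ol, right.contig, orr)
    else:
        key = (right.contig, -orr, left.contig, -ol)
    return key, s_hat


def bundle_pairs(library: Library,
                 pairs: Sequence[Tuple[MappingRecord, MappingRecord]],
                 contig_lengths: Dict[str, int]) -> List[RawEdge]:
    """Group cross-contig read pairs into one raw edge per
    (contig pair, orientation class)."""
    raw: Dict[tuple, RawEdge] = {}
    for r1, r2 in pairs:
        hit = pair_to_raw_key(r1, r2, library.orientation, contig_lengths)
        if hit is None:
            continue
        key, s_hat = hit
        edge = raw.get(key)
        if edge is None:
            edge = raw[key] = RawEdge(key[0], key[1], key[2], key[3], library.id)
        edge.s_obs.append(s_hat)
    return sorted(raw.values(), key=lambda e: e.key())


# ---------------------------------------------------------------------------
# truncation-corrected edge length estimation
# ---------------------------------------------------------------------------

class TruncatedInsertModel:
    """Reverse-lookup tables g -> E(S_hat) for one library.

    Built from the empirical insert histogram; one table per flanking
    contig-length-sum bucket l (500-bp resolution).  Within a table,
    E(S_hat)(g) = E(I | g <= I <= g + l) - g, computed in linear time
    with cumulative sums.  E(S_hat) decreases in g wherever defined, so
    the reverse lookup is unique up to table resolution.
    """

    def __init__(self, library: Library, bucket_size: int = 500):
        if library.distances is None or len(library.distances) == 0:
            raise ValueError(f"library {library.id} has no insert sample")
        self.library = library
        self.bucket_size = int(bucket_size)
        vals = np.asarray(np.round(library.distances), dtype=np.int64)
        vals = vals[vals >= 0]
        self.max_insert = int(vals.max())
        hist = np.bincount(vals, minlength=self.max_insert + 1)
        self._cum_n = np.concatenate([[0], np.cumsum(hist)])
        self._cum_s = np.concatenate(
            [[0], np.cumsum(hist * np.arange(self.max_insert + 1))])
        self.upper = int(math.ceil(library.upper))
        self._tables: Dict[int, np.ndarray] = {}

    def bucket_for(self, l: float) -> int:
        b = self.bucket_size
        q, r = divmod(int(round(l)), b)
        return b * (q if r <= b // 2 else q + 1)

    def table(self, l_bucket: int) -> np.ndarray:
        """E(S_hat) over g = 0..L for one bucket; NaN where no insert mass."""
        tab = self._tables.get(l_bucket)
        if tab is None:
            g = np.arange(self.upper + 1)
            lo = np.minimum(g, self.max_insert + 1)
            hi = np.minimum(g + l_bucket, self.max_insert)
            hi = np.maximum(hi, lo - 1)
            n = self._cum_n[hi + 1] - self._cum_n[lo]
            s = self._cum_s[hi + 1] - self._cum_s[lo]
            with np.errstate(invalid="ignore", divide="ignore"):
                tab = np.where(n > 0, s / np.maximum(n, 1) - g, np.nan)
            self._tables[l_bucket] = tab
        return tab

    def is_monotone(self, l_bucket: int) -> bool:
        tab = self.table(l_bucket)
        valid = tab[~np.isnan(tab)]
        return bool(np.all(np.diff(valid) <= 1e-9))

    def lookup(self, l: float, mean_s: float) -> Tuple[int, bool]:
        """Invert the table nearest to contig-length sum l at mean_s.

        Returns (g, clamped); clamped is True when mean_s falls outside
        the table's range and the boundary value was returned.
        """
        tab = self.table(self.bucket_for(l))
        valid = ~np.isnan(tab)
        if not valid.any():
            raise ValueError("insert histogram has no mass in the lookup range")
        vmax, vmin = np.nanmax(tab), np.nanmin(tab)
        clamped = mean_s > vmax + 1e-9 or mean_s < vmin - 1e-9
        g = int(np.nanargmin(np.abs(tab - mean_s)))
        return g, clamped


def build_lookup_table(library: Library, l: float,
                       bucket_size: int = 500) -> np.ndarray:
    """Convenience wrapper: the g -> E(S_hat) table for one length sum."""
    model = TruncatedInsertModel(library, bucket_size)
    return model.table(model.bucket_for(l))


def estimate_edge_gap(raw: RawEdge, model: TruncatedInsertModel,
                      contig_lengths: Dict[str, int],
                      sigma_floor: float = 1.0) -> Tuple[float, float, bool]:
    """Gap estimate and its standard error for one raw edge.

    The gap is the reverse-lookup inversion of E(S_hat) at the observed
    mean of S_hat; the edge standard deviation is the library sigma
    scaled by sqrt(support) (standard error of the bundled estimate).
    """
    if not raw.s_obs:
        raise ValueError("raw edge carries no S_hat observations")
    l = contig_lengths[raw.c1] + contig_lengths[raw.c2]
    mean_s = float(np.mean(raw.s_obs))
    g, clamped = model.lookup(l, mean_s)
    n = len(raw.s_obs)
    sd = max(model.library.sigma / math.sqrt(n), sigma_floor)
    return float(g), sd, clamped


# ---------------------------------------------------------------------------
# multi-library merging, filters, staging
# ---------------------------------------------------------------------------

def _merge_cluster(cluster: List[ScaffoldEdge]) -> ScaffoldEdge:
    w = np.array([1.0 / e.sd ** 2 for e in cluster])
    gap = float(np.dot(w, [e.gap for e in cluster]) / w.sum())
    sd = float(1.0 / math.sqrt(w.sum()))
    libs = tuple(sorted({l for e in cluster for l in e.libs}))
    return replace(cluster[0], gap=gap, sd=sd,
                   support=sum(e.support for e in cluster), libs=libs,
                   flagged=any(e.flagged for e in cluster))


def merge_libraries(edges: Sequence[ScaffoldEdge],
                    contigs: Dict[str, Contig],
                    sd_multiplier: float = 6.0) -> List[ScaffoldEdge]:
    """Combine edges from all libraries into a unified edge set.

    Per (contig pair, orientation class): seed a cluster with the
    largest-sd unmerged edge, absorb edges whose means lie within
    ``sd_multiplier`` seed standard deviations, and merge each cluster by
    inverse-variance weighting.  If more than one merged edge survives
    for a unique-unique pair, the best-supported one wins; pairs
    involving a repeat retain all surviving edges.
    """
    groups: Dict[tuple, List[ScaffoldEdge]] = {}
    for e in edges:
        groups.setdefault(e.key(), []).append(e)
    out: List[ScaffoldEdge] = []
    for key in sorted(groups):
        remaining = sorted(groups[key],
                           key=lambda e: (-e.sd, e.gap, e.libs, e.id))
        merged: List[ScaffoldEdge] = []
        while remaining:
            seed = remaining[0]
            inside = [e for e in remaining
                      if abs(e.gap - seed.gap) <= sd_multiplier * seed.sd]
            outside = [e for e in remaining
                       if abs(e.gap - seed.gap) > sd_multiplier * seed.sd]
            merged.append(_merge_cluster(inside))
            remaining = outside
        uu = not contigs[key[0]].is_repeat and not contigs[key[2]].is_repeat
        if uu and len(merged) > 1:
            merged.sort(key=lambda e: (-e.support, e.sd, e.gap))
            log.info("conflicting edges for %s: keeping support %d, "
                     "discarding %d edge(s)", key, merged[0].support,
                     len(merged) - 1)
            merged = merged[:1]
        out.extend(merged)
    for i, e in enumerate(out):
        e.id = i
    return out


def apply_filters(graph: ScaffoldGraph, config: Config,
                  pe_insert: float) -> Tuple[ScaffoldGraph, List[str]]:
    """Drop short contigs and weakly supported edges.

    Contigs below max(500, 2 x paired-end insert) are not scaffolded and
    are returned as singletons; edges with support below the threshold
    are discarded.
    """
    thresh = config.contig_threshold(pe_insert)
    keep = {c: ctg for c, ctg in graph.contigs.items() if ctg.length >= thresh}
    singletons = sorted(c for c in graph.contigs if c not in keep)
    edges = [e for e in graph.edges
             if e.c1 in keep and e.c2 in keep
             and e.support >= config.edge_support]
    for i, e in enumerate(edges):
        e.id = i
    log.info("filters: %d contigs below %d bp set aside; %d/%d edges kept",
             len(singletons), thresh, len(edges), len(graph.edges))
    return ScaffoldGraph(keep, edges), singletons


def stage_libraries(libraries: Sequence[Library], config: Config) -> List[List[Library]]:
    """Partition libraries into insert-size stages.

    Boundaries are (0, low], (low, high], (high, inf) bp; disabling
    staging yields a single stage with every library.
    """
    if not config.staged:
        return [list(libraries)]
    lo, hi = config.stage_bound_low, config.stage_bound_high
    stages = [[], [], []]
    for lib in libraries:
        stages[0 if lib.mu <= lo else 1 if lib.mu <= hi else 2].append(lib)
    return [s for s in stages if s]


def drop_repeat_repeat_edges(graph: ScaffoldGraph) -> int:
    """Remove edges between two repeats (their concordance is ignored)."""
    before = len(graph.edges)
    graph.edges = [e for e in graph.edges
                   if not (graph.contigs[e.c1].is_repeat
                           and graph.contigs[e.c2].is_repeat)]
    for i, e in enumerate(graph.edges):
        e.id = i
    dropped = before - len(graph.edges)
    if dropped:
        log.info("ignoring %d repeat-repeat edge(s)", dropped)
    return dropped
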