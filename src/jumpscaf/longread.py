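"""Long-read contig links as synthetic mate-pair libraries.

Each long-read-derived contig link carries an estimated distance and a
support count; indel noise in the reads makes the distance error roughly
proportional to the distance, so the standard deviation is fixed at 10%
of the estimate (floored at 30 bp, 10% of the smallest bin's upper
edge).  Links are grouped into synthetic libraries by distance range and
fed to the standard scaffolder as ready-made scaffold edges, with the
edge support threshold down at 1 by default because chimeric links are
rare.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .graph import ScaffoldEdge
from .io import ContigLink

log = logging.getLogger("jumpscaf")

# half-open, lower-inclusive; the last bin includes its upper edge
DISTANCE_BINS: Tuple[Tuple[int, int], ...] = (
    (0, 300), (300, 1000), (1000, 2000), (2000, 5000),
    (5000, 15000), (15000, 40000))
MAX_LINK_DISTANCE = 40000
SIGMA_FLOOR = 30.0


@dataclass
class SyntheticLibrary:
    id: str
    lo: int
    hi: int
    edges: List[ScaffoldEdge] = field(default_factory=list)


def _bin_for(distance: float):
    for lo, hi in DISTANCE_BINS:
        if lo <= distance < hi or (hi == MAX_LINK_DISTANCE and distance == hi):
            return lo, hi
    return None


def _sgn(o: str) -> int:
    return 1 if o == "+" else -1


def links_to_libraries(links: Sequence[ContigLink],
                       support_threshold: int = 1,
                       sigma_floor: float = SIGMA_FLOOR
                       ) -> Tuple[List[SyntheticLibrary], List[ScaffoldEdge]]:
    """Convert contig links into synthetic libraries and scaffold edges.

    Duplicate links for one (contig pair, orientation class) merge by
    support summing and inverse-variance distance averaging; links
    beyond 40 kbp are discarded with a logged count.  Every retained
    link lands in exactly one distance-range library.
    """
    groups: Dict[tuple, List[ContigLink]] = {}
    n_far = n_self = 0
    for link in links:
        if link.c1 == link.c2:
            n_self += 1
            continue
        if link.distance > MAX_LINK_DISTANCE:
            n_far += 1
            continue
        if link.c1 <= link.c2:
            key = (link.c1, _sgn(link.o1), link.c2, _sgn(link.o2))
        else:
            key = (link.c2, -_sgn(link.o2), link.c1, -_sgn(link.o1))
        groups.setdefault(key, []).append(link)
    if n_far:
        log.info("discarded %d link(s) beyond %d bp", n_far, MAX_LINK_DISTANCE)
    if n_self:
        log.info("discarded %d self-link(s)", n_self)

    libraries = {(lo, hi): SyntheticLibrary(f"links_{lo}_{hi}", lo, hi)
                 for lo, hi in DISTANCE_BINS}
    edges: List[ScaffoldEdge] = []
    for key in sorted(groups):
        members = groups[key]
        ws, dsum, support = 0.0, 0.0, 0
        for link in members:
            sd = max(0.1 * link.distance, sigma_floor)
            w = 1.0 / sd ** 2
            ws += w
            dsum += w * link.distance
            support += link.support
        if support < support_threshold:
            continue
        distance = dsum / ws
        b = _bin_for(distance)
        if b is None:
            n_far += 1
            continue
        sd = max(0.1 * distance, sigma_floor)
        edge = ScaffoldEdge(id=len(edges), c1=key[0], o1=key[1],
                            c2=key[2], o2=key[3], gap=float(distance),
                            sd=sd, support=support,
                            libs=(libraries[b].id,))
        edges.append(edge)
        libraries[b].edges.append(edge)
    return [libraries[b] for b in DISTANCE_BINS], edges
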