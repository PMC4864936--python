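"""Synthetic data: genomes with planted repeats, contigs, mate pairs.

The generator emulates the inputs a scaffolder sees after assembly and
read mapping: a reference genome with planted repeat families, contigs
tiling it with each repeat family collapsed to a single contig (as a
de Bruijn assembler would), and mate-pair mappings drawn with
Normal(mu, sigma) insert sizes whose reads are placed directly on the
containing contig, so no base-level error model or aligner is needed.
Everything is deterministic per seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph import Contig
from .io import MappingRecord
from .library import INWARD, OUTWARD, SAME

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class RepeatFamilySpec:
    length: int
    copies: int


@dataclass
class LibrarySpec:
    id: str
    mu: float
    sigma: float
    read_len: int = 100
    coverage: float = 2.0            # base-pair coverage of the pairs
    orientation: str = INWARD


@dataclass
class TruthEntry:
    """True coordinates of a contig: one copy per genomic occurrence."""

    contig: str
    chrom: str
    is_repeat: bool
    copies: List[Tuple[int, int, str]]   # (start, end, strand)


@dataclass
class Tile:
    gstart: int
    gend: int
    contig: str
    strand: str     # orientation of the contig copy on the genome


def simulate_genome(seed: int, size: int,
                    repeat_spec: Sequence[RepeatFamilySpec] = (),
                    margin: int = 20000, chrom: str = "chr1"):
    """I.i.d. uniform genome with planted repeat copies.

    Each family is a random template copied to its stated copy count at
    non-overlapping positions separated by at least ``margin`` bp of
    unique sequence.  Returns (sequence, placements) where placements
    are (family index, start, end, strand) with strand '+'.
    """
    rng = np.random.default_rng(seed)
    seq = _BASES[rng.integers(0, 4, size=size)]
    placements: List[Tuple[int, int, int, str]] = []
    taken: List[Tuple[int, int]] = []
    for fi, fam in enumerate(repeat_spec):
        template = _BASES[rng.integers(0, 4, size=fam.length)]
        placed = 0
        attempts = 0
        while placed < fam.copies:
            attempts += 1
            if attempts > 10000:
                raise RuntimeError("cannot place repeat copies; genome too small")
            start = int(rng.integers(margin, size - fam.length - margin))
            end = start + fam.length
            if any(start < e + margin and s - margin < end for s, e in taken):
                continue
            seq[start:end] = template
            taken.append((start, end))
            placements.append((fi, start, end, "+"))
            placed += 1
    placements.sort(key=lambda p: p[1])
    return seq.tobytes().decode(), placements


def derive_contigs(genome: str, placements, seed: int,
                   min_unique_len: int = 15000,
                   mean_unique_len: int = 30000, chrom: str = "chr1"):
    """Tile the genome into contigs, collapsing each repeat family.

    Unique stretches between repeat copies are split at random
    breakpoints (segments at least ``min_unique_len``); each repeat
    family becomes one contig whose coverage will reflect its copy
    count.  Returns (contigs, seqs, truth, tiles).
    """
    rng = np.random.default_rng(seed + 1)
    size = len(genome)
    contigs: Dict[str, Contig] = {}
    seqs: Dict[str, str] = {}
    truth: Dict[str, TruthEntry] = {}
    tiles: List[Tile] = []

    fam_contig: Dict[int, str] = {}
    for fi, start, end, strand in placements:
        name = fam_contig.get(fi)
        if name is None:
            name = fam_contig[fi] = f"rep{fi:02d}"
            contigs[name] = Contig(id=name, length=end - start, is_repeat=False)
            seqs[name] = genome[start:end]
            truth[name] = TruthEntry(name, chrom, True, [])
        truth[name].copies.append((start, end, strand))
        tiles.append(Tile(start, end, name, strand))

    bounds = [0] + [p for _, s, e, _ in placements for p in (s, e)] + [size]
    n_ctg = 0
    for a, b in zip(bounds[::2], bounds[1::2]):
        pos = a
        while pos < b:
            remain = b - pos
            if remain < 2 * min_unique_len:
                seg = remain
            else:
                seg = int(min(remain - min_unique_len,
                              max(min_unique_len,
                                  rng.exponential(mean_unique_len))))
            name = f"ctg{n_ctg:04d}"
            n_ctg += 1
            contigs[name] = Contig(id=name, length=seg, is_repeat=False)
            seqs[name] = genome[pos:pos + seg]
            truth[name] = TruthEntry(name, chrom, False,
                                     [(pos, pos + seg, "+")])
            tiles.append(Tile(pos, pos + seg, name, "+"))
            pos += seg
    tiles.sort(key=lambda t: t.gstart)
    return contigs, seqs, truth, tiles


def simulate_mate_pairs(genome_size: int, tiles: Sequence[Tile],
                        spec: LibrarySpec, seed: int
                        ) -> List[Tuple[MappingRecord, MappingRecord]]:
    """Draw mate pairs and map their reads onto the tiling contigs.

    Fragment positions are uniform, inserts Normal(mu, sigma) (the
    insert is the outermost span, read lengths included); a read
    straddling a contig boundary drops the whole pair.  Reads landing in
    a repeat copy map to the collapsed repeat contig.  For inward and
    outward libraries the mate labels of each pair are swapped at
    random, as in real data.
    """
    rng = np.random.default_rng(seed + 2)
    n_pairs = int(round(spec.coverage * genome_size / (2 * spec.read_len)))
    starts = rng.integers(0, genome_size, size=n_pairs)
    inserts = np.round(rng.normal(spec.mu, spec.sigma, size=n_pairs)).astype(int)
    swap = rng.integers(0, 2, size=n_pairs).astype(bool)
    tile_starts = [t.gstart for t in tiles]
    rlen = spec.read_len
    if spec.orientation == INWARD:
        strands = ("+", "-")
    elif spec.orientation == OUTWARD:
        strands = ("-", "+")
    else:
        strands = ("+", "+")
    pairs = []
    for i in range(n_pairs):
        ins = int(inserts[i])
        if ins < 2 * rlen:
            continue
        g1 = int(starts[i])
        g2 = g1 + ins - rlen
        if g2 + rlen > genome_size:
            continue
        hit1 = _map_read(tiles, tile_starts, g1, rlen, strands[0])
        hit2 = _map_read(tiles, tile_starts, g2, rlen, strands[1])
        if hit1 is None or hit2 is None:
            continue
        qname = f"{spec.id}:{i}"
        left_mate, right_mate = (2, 1) if (swap[i] and spec.orientation != SAME) \
            else (1, 2)
        r1 = MappingRecord(qname, left_mate, hit1[0], hit1[1], hit1[2],
                           rlen, spec.id)
        r2 = MappingRecord(qname, right_mate, hit2[0], hit2[1], hit2[2],
                           rlen, spec.id)
        pairs.append((r1, r2) if left_mate == 1 else (r2, r1))
    return pairs


def _map_read(tiles, tile_starts, gpos: int, rlen: int, strand: str):
    ti = bisect.bisect_right(tile_starts, gpos) - 1
    if ti < 0:
        return None
    t = tiles[ti]
    if gpos + rlen > t.gend:
        return None
    if t.strand == "+":
        return t.contig, gpos - t.gstart, strand
    flipped = "-" if strand == "+" else "+"
    return t.contig, t.gend - (gpos + rlen), flipped


# ---------------------------------------------------------------------------
# truth TSV round trip
# ---------------------------------------------------------------------------

def write_truth(truth: Dict[str, TruthEntry], path) -> None:
    lines = ["#contig\tchrom\tis_repeat\tcopies"]
    for name in sorted(truth):
        t = truth[name]
        copies = ";".join(f"{s}-{e}:{st}" for s, e, st in t.copies)
        lines.append(f"{t.contig}\t{t.chrom}\t{int(t.is_repeat)}\t{copies}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_truth(path) -> Dict[str, TruthEntry]:
    truth: Dict[str, TruthEntry] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            contig, chrom, is_rep, copies = line.split("\t")
            parsed = []
            for item in copies.split(";"):
                span, strand = item.split(":")
                s, e = span.split("-")
                parsed.append((int(s), int(e), strand))
            truth[contig] = TruthEntry(contig, chrom, bool(int(is_rep)), parsed)
    return truth


def random_scaffold_graph(seed: int, n_unique_max: int = 7,
                          n_repeat_max: int = 2, max_edges: int = 12,
                          noise_edges_max: int = 2):
    """Random small scaffold graph planted from a true layout.

    A random signed arrangement of unique contigs with repeat copies
    interleaved yields truth-derived edges (adjacent pairs always, a few
    longer-range ones); a handful of contradictory noise edges force
    discordance.  Used to compare the exact search against the
    brute-force oracle.  Returns (contigs, edges).
    """
    from .graph import ScaffoldEdge

    rng = np.random.default_rng(seed)
    n_r = int(rng.integers(0, n_repeat_max + 1))
    n_u = int(rng.integers(4, max(5, n_unique_max + 1 - n_r)))
    contigs: Dict[str, Contig] = {}
    for i in range(n_u):
        contigs[f"u{i}"] = Contig(f"u{i}", int(rng.integers(2000, 20000)))
    for i in range(n_r):
        contigs[f"r{i}"] = Contig(f"r{i}", int(rng.integers(1000, 4000)),
                                  is_repeat=True)
    # true layout: unique order with repeat instances slotted between
    order = [f"u{i}" for i in rng.permutation(n_u)]
    for i in range(n_r):
        for _ in range(int(rng.integers(1, 3))):
            slot = int(rng.integers(1, len(order) + 1))
            order.insert(slot, f"r{i}")
    layout = []
    pos = 0.0
    for c in order:
        orient = int(rng.choice([1, -1]))
        layout.append((c, orient, pos, pos + contigs[c].length))
        pos += contigs[c].length + float(rng.integers(50, 500))

    def true_edge(i: int, j: int, eid: int, support=None):
        ca, qa, sa, ea = layout[i]
        cb, qb, sb, eb = layout[j]
        gap = sb - ea + float(rng.normal(0, 30))
        sd = float(rng.integers(30, 100))
        sup = support or int(rng.integers(5, 20))
        if ca <= cb:
            return ScaffoldEdge(eid, ca, qa, cb, qb, gap, sd, sup)
        return ScaffoldEdge(eid, cb, -qb, ca, -qa, gap, sd, sup)

    edges = []
    for i in range(len(layout) - 1):
        if layout[i][0] == layout[i + 1][0]:
            continue                      # tandem: would be a self edge
        edges.append(true_edge(i, i + 1, len(edges)))
    # mate pairs spanning a (short) repeat run link its unique flanks,
    # keeping the unique subgraph connected
    i = 0
    while i < len(layout):
        if contigs[layout[i][0]].is_repeat:
            j = i
            while j < len(layout) and contigs[layout[j][0]].is_repeat:
                j += 1
            if i > 0 and j < len(layout):
                edges.append(true_edge(i - 1, j, len(edges)))
            i = j
        else:
            i += 1
    # a few longer-range edges within plausible insert reach
    for _ in range(int(rng.integers(0, 4))):
        i = int(rng.integers(0, len(layout) - 2))
        j = i + 2
        if layout[i][0] != layout[j][0] and len(edges) < max_edges:
            edges.append(true_edge(i, j, len(edges)))
    # contradictory noise edges between unique contigs
    for _ in range(int(rng.integers(0, noise_edges_max + 1))):
        if len(edges) >= max_edges:
            break
        a, b = rng.choice(n_u, size=2, replace=False)
        ca, cb = f"u{a}", f"u{b}"
        if ca > cb:
            ca, cb = cb, ca
        edges.append(ScaffoldEdge(
            len(edges), ca, int(rng.choice([1, -1])), cb,
            int(rng.choice([1, -1])), float(rng.integers(100, 8000)),
            float(rng.integers(30, 100)), int(rng.integers(5, 12))))
    # dedupe identical (pair, orientation) keys: keep the first
    seen = set()
    kept = []
    for e in edges:
        if e.key() in seen:
            continue
        seen.add(e.key())
        e.id = len(kept)
        kept.append(e)
    return contigs, kept


def random_bordered_graph(seed: int, n_contigs: int = 12,
                          border_len: int = 60000):
    """Random chain graph with planted border contigs.

    Like :func:`random_scaffold_graph` but larger, with two or three
    unique contigs long enough (``border_len``) that no edge window can
    span them.  Returns (contigs, edges, border ids).
    """
    from .graph import ScaffoldEdge

    rng = np.random.default_rng(seed + 10_000)
    n_r = int(rng.integers(0, 2))
    n_u = n_contigs - n_r
    contigs: Dict[str, Contig] = {}
    borders = sorted(rng.choice(n_u, size=int(rng.integers(2, 4)),
                                replace=False))
    for i in range(n_u):
        length = border_len if i in borders else int(rng.integers(2000, 15000))
        contigs[f"u{i}"] = Contig(f"u{i}", length)
    for i in range(n_r):
        contigs[f"r{i}"] = Contig(f"r{i}", int(rng.integers(1000, 3000)),
                                  is_repeat=True)
    order = [f"u{i}" for i in rng.permutation(n_u)]
    for i in range(n_r):
        for _ in range(int(rng.integers(1, 3))):
            slot = int(rng.integers(1, len(order) + 1))
            order.insert(slot, f"r{i}")
    layout = []
    pos = 0.0
    for c in order:
        orient = int(rng.choice([1, -1]))
        layout.append((c, orient, pos, pos + contigs[c].length))
        pos += contigs[c].length + float(rng.integers(50, 400))

    def true_edge(i, j, eid):
        ca, qa, sa, ea = layout[i]
        cb, qb, sb, eb = layout[j]
        gap = sb - ea + float(rng.normal(0, 30))
        sd = float(rng.integers(30, 100))
        sup = int(rng.integers(5, 20))
        if ca <= cb:
            return ScaffoldEdge(eid, ca, qa, cb, qb, gap, sd, sup)
        return ScaffoldEdge(eid, cb, -qb, ca, -qa, gap, sd, sup)

    edges = []
    for i in range(len(layout) - 1):
        if layout[i][0] == layout[i + 1][0]:
            continue
        edges.append(true_edge(i, i + 1, len(edges)))
    i = 0
    while i < len(layout):
        if contigs[layout[i][0]].is_repeat:
            j = i
            while j < len(layout) and contigs[layout[j][0]].is_repeat:
                j += 1
            if i > 0 and j < len(layout):
                edges.append(true_edge(i - 1, j, len(edges)))
            i = j
        else:
            i += 1
    # one optional contradictory edge between short uniques
    if rng.random() < 0.5:
        short = [i for i in range(n_u) if i not in borders]
        a, b = rng.choice(short, size=2, replace=False)
        ca, cb = sorted((f"u{a}", f"u{b}"))
        edges.append(ScaffoldEdge(
            len(edges), ca, int(rng.choice([1, -1])), cb,
            int(rng.choice([1, -1])), float(rng.integers(100, 6000)),
            float(rng.integers(30, 80)), int(rng.integers(5, 12))))
    seen = set()
    kept = []
    for e in edges:
        if e.key() in seen:
            continue
        seen.add(e.key())
        e.id = len(kept)
        kept.append(e)
    border_ids = {f"u{i}" for i in borders}
    return contigs, kept, border_ids


@dataclass
class Dataset:
    genome: str
    contigs: Dict[str, Contig]
    seqs: Dict[str, str]
    truth: Dict[str, TruthEntry]
    tiles: List[Tile]
    pairs: Dict[str, list]           # library id -> read pairs
    specs: List[LibrarySpec]

    @property
    def genome_size(self) -> int:
        return len(self.genome)


def simulate_dataset(seed: int, genome_size: int = 1_000_000,
                     repeat_spec: Sequence[RepeatFamilySpec] = (
                         RepeatFamilySpec(length=8000, copies=3),
                         RepeatFamilySpec(length=8000, copies=3),
                         RepeatFamilySpec(length=8000, copies=3),
                         RepeatFamilySpec(length=8000, copies=3),
                     ),
                     specs: Sequence[LibrarySpec] = (
                         LibrarySpec("lib3k", 3000.0, 300.0),
                         LibrarySpec("lib10k", 10000.0, 1000.0),
                     )) -> Dataset:
    """One-call synthetic study: genome, contigs and per-library pairs.

    Defaults model a 1-Mbp genome with ~10% repeat content (four
    families of three 8-kbp copies) and two inward libraries
    (3 kbp +/- 300 and 10 kbp +/- 1000) at 2x pair coverage each.
    """
    genome, placements = simulate_genome(seed, genome_size, repeat_spec)
    contigs, seqs, truth, tiles = derive_contigs(genome, placements, seed)
    pairs = {}
    for li, spec in enumerate(specs):
        pairs[spec.id] = simulate_mate_pairs(len(genome), tiles, spec,
                                             seed + 1000 * (li + 1))
    return Dataset(genome=genome, contigs=contigs, seqs=seqs, truth=truth,
                   tiles=tiles, pairs=pairs, specs=list(specs))
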