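"""Readers and writers for the external formats the scaffolder touches.

Contigs arrive as FASTA, read mappings as SAM (one file per jumping
library), long-read contig links as a 6-column TSV.  Scaffolds leave as
AGP v2.0 plus a rendered FASTA.  All internal coordinates are 0-based,
half-open; SAM's 1-based POS is converted at this boundary and nowhere
else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("jumpscaf")


class FormatError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(ValueError):
    """Unknown or invalid configuration key/value."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MappingRecord:
    """One aligned read end.

    ``pos`` is the leftmost aligned base, 0-based.  For reverse-strand
    mappings this is still the leftmost coordinate (SAM convention);
    pair distances are computed from outermost coordinates.
    """

    qname: str
    mate: int               # 1 or 2
    contig: str
    pos: int                # 0-based leftmost
    strand: str             # '+' or '-'
    rlen: int
    lib: str

    def __post_init__(self):
        if self.mate not in (1, 2):
            raise FormatError(f"mate index must be 1 or 2, got {self.mate}")
        if self.pos < 0:
            raise FormatError(f"negative position for read {self.qname}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"bad strand {self.strand!r}")

    @property
    def end(self) -> int:
        return self.pos + self.rlen


@dataclass(frozen=True)
class ContigLink:
    """A long-read-derived link between two contigs."""

    c1: str
    o1: str
    c2: str
    o2: str
    distance: int
    support: int

    def __post_init__(self):
        if self.distance < 0:
            raise FormatError(f"negative link distance {self.distance}")
        if self.support < 1:
            raise FormatError(f"link support must be >= 1, got {self.support}")
        if self.o1 not in "+-" or self.o2 not in "+-":
            raise FormatError("link orientations must be '+' or '-'")


@dataclass
class ScaffoldComponent:
    contig: str
    orient: str             # '+' or '-'
    start: int              # rendered offset within scaffold, 0-based
    length: int


@dataclass
class ScaffoldGapRecord:
    size: float             # estimated gap, may be <= 0
    rendered: int = 0       # max(1, round(size)); filled by layout()


@dataclass
class ScaffoldDoc:
    """A scaffold: ordered contig components interleaved with gap records."""

    id: str
    parts: list             # [ScaffoldComponent, ScaffoldGapRecord, Component, ...]
    flags: tuple = ()       # e.g. ("hybrid: edge support raised to 6",)

    def components(self) -> list:
        return [p for p in self.parts if isinstance(p, ScaffoldComponent)]

    def gaps(self) -> list:
        return [p for p in self.parts if isinstance(p, ScaffoldGapRecord)]

    def layout(self) -> None:
        """Assign rendered offsets: each gap renders as max(1, round(size))."""
        off = 0
        for p in self.parts:
            if isinstance(p, ScaffoldComponent):
                p.start = off
                off += p.length
            else:
                p.rendered = max(1, int(round(p.size)))
                off += p.rendered

    @property
    def span(self) -> int:
        self.layout()
        comps = self.components()
        return comps[-1].start + comps[-1].length if comps else 0


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """Run configuration; defaults follow the method's published settings."""

    repeat_factor: float = 1.5       # coverage multiple separating repeats
    edge_support: int = 5            # minimum read pairs per scaffold edge
    sd_multiplier: float = 6.0       # k in mu + k*sigma bounds and windows
    state_cap: int = 1_000_000       # explored-state bound per subgraph
    support_step: int = 1            # escalation step for hybrid fallback
    stage_bound_low: int = 1000      # staged library boundaries (bp)
    stage_bound_high: int = 10000
    staged: bool = False             # single stage unless enabled
    min_contig_len: Optional[int] = None  # default max(500, 2 x PE insert)
    delta_min: float = -500.0        # gap lower bound (contig overlap allowed)
    delta_max: Optional[float] = None  # default: max library upper bound
    sigma_floor: float = 1.0
    bucket_size: int = 500           # lookup-table contig-length resolution
    memo_enabled: bool = True
    weight_by_support: bool = True   # include n_e in the gap-sizing weights
    max_repeat_copies: int = 8       # safety bound on instances per repeat

    def contig_threshold(self, pe_insert: float) -> int:
        if self.min_contig_len is not None:
            return int(self.min_contig_len)
        return max(500, int(round(2 * pe_insert)))


_ALIASES = {"support": "edge_support"}
_BOOLS = {"true": True, "1": True, "yes": True,
          "false": False, "0": False, "no": False}


def parse_config(source: Union[str, Path, dict, None] = None, **overrides) -> Config:
    """Build a Config from a key=value file, a dict, and/or keyword overrides.

    Unknown keys raise :class:`ConfigError` naming the key.
    """
    cfg = Config()
    items: list = []
    if isinstance(source, dict):
        items = list(source.items())
    elif source is not None:
        for lineno, line in enumerate(Path(source).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected key=value, got {line!r}")
            k, v = (s.strip() for s in line.split("=", 1))
            items.append((k, v))
    items += list(overrides.items())

    valid = {f.name: f.type for f in fields(Config)}
    for key, value in items:
        key = _ALIASES.get(key, key)
        if key not in valid:
            raise ConfigError(f"unknown configuration key: {key!r}")
        cur = getattr(cfg, key)
        if isinstance(value, str):
            if key in ("staged", "memo_enabled", "weight_by_support"):
                try:
                    value = _BOOLS[value.lower()]
                except KeyError:
                    raise ConfigError(f"bad boolean for {key}: {value!r}")
            elif value.lower() == "none":
                value = None
            else:
                try:
                    value = float(value) if "." in value or "e" in value.lower() \
                        else int(value)
                except ValueError:
                    raise ConfigError(f"bad numeric value for {key}: {value!r}")
        if isinstance(cur, bool) and not isinstance(value, bool):
            raise ConfigError(f"bad boolean for {key}: {value!r}")
        if isinstance(cur, float) and isinstance(value, int):
            value = float(value)
        setattr(cfg, key, value)
    return cfg


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]):
    """Read contigs; returns ({id: length}, {id: sequence str}).

    Lengths count every character of the record (lowercase and N
    included).  Duplicate ids and empty files are errors.
    """
    lengths: dict = {}
    seqs: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in lengths:
            raise FormatError(f"duplicate FASTA record id: {rec.id!r}")
        seq = str(rec.seq)
        lengths[rec.id] = len(seq)
        seqs[rec.id] = seq
    if not lengths:
        raise FormatError(f"no FASTA records found in {path}")
    return lengths, seqs


def write_fasta(seqs: dict, path: Union[str, Path]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def read_sam_pairs(path: Union[str, Path], lib: str,
                   contig_lengths: Optional[dict] = None):
    """Parse a SAM file into read pairs matched by QNAME.

    Unmapped, secondary and supplementary records are dropped; reads
    whose mate never shows up are dropped with a logged count.  Returns
    (pairs, n_orphans) where pairs is a list of (mate1, mate2)
    MappingRecord tuples in first-completed order.
    """
    half: dict = {}
    pairs: list = []
    unknown: set = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            name = aln.reference_name
            if contig_lengths is not None and name not in contig_lengths:
                unknown.add(name)
                continue
            mate = 2 if aln.is_read2 else 1
            rec = MappingRecord(
                qname=aln.query_name, mate=mate, contig=name,
                pos=aln.reference_start,            # pysam is already 0-based
                strand="-" if aln.is_reverse else "+",
                rlen=aln.query_length or aln.infer_read_length() or 0,
                lib=lib)
            other = half.pop((rec.qname, 3 - mate), None)
            if other is None:
                half[(rec.qname, mate)] = rec
            else:
                pairs.append((other, rec) if other.mate == 1 else (rec, other))
    if unknown:
        raise FormatError(
            "SAM references contigs absent from the FASTA: "
            + ", ".join(sorted(unknown)))
    n_orphans = len(half)
    if n_orphans:
        log.info("library %s: dropped %d unpaired reads", lib, n_orphans)
    return pairs, n_orphans


def write_sam(pairs: Iterable, contig_lengths: dict,
              path: Union[str, Path]) -> None:
    """Write mapped read pairs as plain-text SAM (deterministic order)."""
    names = sorted(contig_lengths)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for n in names:
            fh.write(f"@SQ\tSN:{n}\tLN:{contig_lengths[n]}\n")
        for r1, r2 in pairs:
            for rec, other in ((r1, r2), (r2, r1)):
                flag = 0x1 | 0x2
                flag |= 0x40 if rec.mate == 1 else 0x80
                if rec.strand == "-":
                    flag |= 0x10
                if other.strand == "-":
                    flag |= 0x20
                fh.write("\t".join([
                    rec.qname, str(flag), rec.contig, str(rec.pos + 1), "60",
                    f"{rec.rlen}M", "=" if other.contig == rec.contig else other.contig,
                    str(other.pos + 1), "0", "*", "*"]) + "\n")


# ---------------------------------------------------------------------------
# AGP v2.0 + scaffold FASTA
# ---------------------------------------------------------------------------

def write_scaffolds(docs: Sequence[ScaffoldDoc], seqs: Optional[dict],
                    agp_path: Union[str, Path],
                    fasta_path: Optional[Union[str, Path]] = None) -> None:
    """Render scaffolds as AGP v2.0 and (optionally) FASTA.

    Negative or zero gap estimates render as a single N (AGP forbids
    non-positive gap lengths); the estimate is preserved in a trailing
    ``est=`` column so the structure round-trips losslessly.
    """
    lines = ["##agp-version\t2.0"]
    out_seqs: dict = {}
    for doc in docs:
        doc.layout()
        for flag in doc.flags:
            lines.append(f"# scaffold {doc.id} flagged: {flag}")
        part_no = 0
        offset = 0
        pieces: list = []
        for p in doc.parts:
            part_no += 1
            if isinstance(p, ScaffoldComponent):
                lines.append("\t".join([
                    doc.id, str(offset + 1), str(offset + p.length),
                    str(part_no), "W", p.contig, "1", str(p.length), p.orient]))
                offset += p.length
                if seqs is not None:
                    if p.contig not in seqs:
                        raise FormatError(f"no sequence for contig {p.contig!r}")
                    s = seqs[p.contig]
                    pieces.append(s if p.orient == "+" else _revcomp(s))
            else:
                lines.append("\t".join([
                    doc.id, str(offset + 1), str(offset + p.rendered),
                    str(part_no), "N", str(p.rendered), "scaffold", "yes",
                    "paired-ends", f"est={p.size:g}"]))
                offset += p.rendered
                pieces.append("N" * p.rendered)
        if seqs is not None:
            out_seqs[doc.id] = "".join(pieces)
    Path(agp_path).write_text("\n".join(lines) + "\n")
    if fasta_path is not None and seqs is not None:
        write_fasta(out_seqs, fasta_path)


def read_agp(path: Union[str, Path]) -> list:
    """Parse AGP written by :func:`write_scaffolds` back into ScaffoldDocs."""
    docs: dict = {}
    order: list = []
    flags: dict = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("##") or not line.strip():
            continue
        if line.startswith("#"):
            words = line[1:].split()
            if len(words) >= 3 and words[0] == "scaffold" and words[2] == "flagged:":
                flags.setdefault(words[1], []).append(" ".join(words[3:]))
            continue
        f = line.split("\t")
        sid = f[0]
        if sid not in docs:
            docs[sid] = []
            order.append(sid)
        if f[4] == "W":
            length = int(f[7]) - int(f[6]) + 1
            docs[sid].append(ScaffoldComponent(
                contig=f[5], orient=f[8], start=int(f[1]) - 1, length=length))
        elif f[4] == "N":
            est = float(f[9][4:]) if len(f) > 9 and f[9].startswith("est=") \
                else float(f[5])
            docs[sid].append(ScaffoldGapRecord(size=est, rendered=int(f[5])))
        else:
            raise FormatError(f"unsupported AGP component type {f[4]!r}")
    out = []
    for sid in order:
        doc = ScaffoldDoc(id=sid, parts=docs[sid],
                          flags=tuple(flags.get(sid, ())))
        doc.layout()
        out.append(doc)
    return out


_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# long-read links TSV
# ---------------------------------------------------------------------------

def read_links_tsv(path: Union[str, Path],
                   contig_lengths: Optional[dict] = None) -> list:
    """Read contig links: columns c1, o1, c2, o2, distance, support."""
    links: list = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t") if "\t" in line else line.split()
        if len(f) != 6:
            raise FormatError(f"links line {lineno}: expected 6 columns, got {len(f)}")
        c1, o1, c2, o2, dist, sup = f
        if contig_lengths is not None:
            for c in (c1, c2):
                if c not in contig_lengths:
                    raise FormatError(f"links line {lineno}: unknown contig {c!r}")
        links.append(ContigLink(c1, o1, c2, o2, int(dist), int(sup)))
    return links
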