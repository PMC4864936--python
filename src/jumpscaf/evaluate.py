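"""Truth-based evaluation of scaffolds from synthetic data.

Adjacent unique-contig joins are classified against the known contig
coordinates: translocation (different chromosomes), inversion (wrong
relative orientation), relocation (wrong order, or separation grossly
off), scaffold-indel (estimated separation off by more than 1 kbp --
room for a missing contig).  Repeat placements between unique flanks
are checked for family, order and orientation against the true copies
in that gap.  The corrected N50 is computed after breaking scaffolds at
every erroneous join.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .io import ScaffoldComponent, ScaffoldDoc, ScaffoldGapRecord
from .simulate import TruthEntry


@dataclass
class ErrorReport:
    total_joins: int = 0
    correct_joins: int = 0
    translocations: int = 0
    inversions: int = 0
    relocations: int = 0
    scaffold_indels: int = 0
    n50: int = 0
    corrected_n50: int = 0
    repeat_placed: int = 0
    repeat_correct: int = 0
    repeat_placeable: int = 0

    @property
    def correct_join_fraction(self) -> float:
        return self.correct_joins / self.total_joins if self.total_joins else 1.0

    @property
    def repeat_fraction_correct(self) -> float:
        return self.repeat_correct / self.repeat_placed if self.repeat_placed else 1.0

    @property
    def repeat_fraction_placed(self) -> float:
        return (self.repeat_correct / self.repeat_placeable
                if self.repeat_placeable else 1.0)

    def summary(self) -> str:
        return (
            f"joins: {self.correct_joins}/{self.total_joins} correct "
            f"({100 * self.correct_join_fraction:.2f}%)\n"
            f"errors: {self.translocations} translocation, "
            f"{self.inversions} inversion, {self.relocations} relocation, "
            f"{self.scaffold_indels} scaffold-indel\n"
            f"N50 {self.n50} bp; corrected N50 {self.corrected_n50} bp\n"
            f"repeats: {self.repeat_correct}/{self.repeat_placed} placed "
            f"correctly; {self.repeat_correct}/{self.repeat_placeable} of "
            f"placeable copies recovered")

    def to_tsv(self) -> str:
        keys = ["total_joins", "correct_joins", "translocations", "inversions",
                "relocations", "scaffold_indels", "n50", "corrected_n50",
                "repeat_placed", "repeat_correct", "repeat_placeable"]
        head = "\t".join(keys)
        vals = "\t".join(str(getattr(self, k)) for k in keys)
        return head + "\n" + vals + "\n"


def corrected_n50(lengths: Sequence[int], genome_size: int) -> int:
    """Fragment length such that >50% of the genome is in fragments at
    least that long (strictly greater-than at the midpoint)."""
    total = 0
    for length in sorted(lengths, reverse=True):
        total += length
        if total > genome_size / 2:
            return int(length)
    return 0


def _float_positions(doc: ScaffoldDoc):
    """Component positions using estimated (not rendered) gap sizes."""
    pos = 0.0
    out = []
    for p in doc.parts:
        if isinstance(p, ScaffoldComponent):
            out.append((p, pos))
            pos += p.length
        else:
            pos += p.size
    return out


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _classify_join(ta: TruthEntry, tb: TruthEntry, oa: str, ob: str,
                   sep: float, slack: float) -> str:
    sa, ea, stra = ta.copies[0]
    sb, eb, strb = tb.copies[0]
    if ta.chrom != tb.chrom:
        return "translocation"
    fa = 1 if oa == stra else -1       # scaffold direction vs genome for A
    fb = 1 if ob == strb else -1
    if fa != fb:
        return "inversion"
    if fa == 1:
        order_ok = sb > sa
        true_sep = sb - ea
    else:
        order_ok = sb < sa
        true_sep = sa - eb
    if not order_ok:
        return "relocation"
    delta = abs(sep - true_sep)
    if slack > 1000 and delta > slack:
        return "relocation"
    if delta > 1000:
        return "scaffold_indel"
    return "correct"


def evaluate(docs: Sequence[ScaffoldDoc], truth: Dict[str, TruthEntry],
             genome_size: int,
             join_sd: Optional[dict] = None) -> ErrorReport:
    """Score scaffolds against the simulation truth.

    ``join_sd`` may map unordered unique-contig pairs to the standard
    deviation of the supporting edge; the relocation distance class is
    then max(1 kbp, 6 sd), otherwise 1 kbp.
    """
    rep = ErrorReport()
    frag_lengths: List[int] = []
    orig_lengths: List[int] = []
    for doc in docs:
        doc.layout()
        orig_lengths.append(doc.span)
        placed = _float_positions(doc)
        uniques = [(p, pos) for p, pos in placed
                   if p.contig in truth and not truth[p.contig].is_repeat]
        rep.repeat_placed += sum(
            1 for p, _ in placed
            if p.contig in truth and truth[p.contig].is_repeat)
        # classify consecutive unique joins
        error_breaks: List[int] = []      # rendered offsets to break at
        for (pa, xa), (pb, xb) in zip(uniques, uniques[1:]):
            rep.total_joins += 1
            ta, tb = truth[pa.contig], truth[pb.contig]
            sep = xb - (xa + pa.length)
            slack = 1000.0
            if join_sd:
                sd = join_sd.get(frozenset((pa.contig, pb.contig)))
                if sd:
                    slack = max(1000.0, 6.0 * sd)
            verdict = _classify_join(ta, tb, pa.orient, pb.orient, sep, slack)
            if verdict == "correct":
                rep.correct_joins += 1
            else:
                setattr(rep, verdict + "s", getattr(rep, verdict + "s") + 1)
                error_breaks.append(pb.start)
            _score_repeat_run(rep, doc, truth, pa, pb, verdict)
        # corrected fragments: split before each erroneous right-hand contig
        comps = doc.components()
        cur_start = 0
        for brk in error_breaks:
            left = [c for c in comps if c.start < brk and c.start >= cur_start]
            if left:
                frag_lengths.append(left[-1].start + left[-1].length - cur_start)
            cur_start = brk
        frag_lengths.append(comps[-1].start + comps[-1].length - cur_start)
    rep.n50 = corrected_n50(orig_lengths, genome_size)
    rep.corrected_n50 = corrected_n50(frag_lengths, genome_size)
    return rep


def _score_repeat_run(rep: ErrorReport, doc: ScaffoldDoc,
                      truth: Dict[str, TruthEntry],
                      pa: ScaffoldComponent, pb: ScaffoldComponent,
                      verdict: str) -> None:
    """Check repeat instances scaffolded between unique flanks A and B."""
    comps = doc.components()
    ia, ib = comps.index(pa), comps.index(pb)
    run = [c for c in comps[ia + 1:ib]
           if c.contig in truth and truth[c.contig].is_repeat]
    ta, tb = truth[pa.contig], truth[pb.contig]
    if ta.chrom != tb.chrom:
        return
    sa, ea, stra = ta.copies[0]
    sb, eb, strb = tb.copies[0]
    f = 1 if pa.orient == stra else -1
    lo, hi = (ea, sb) if f == 1 else (eb, sa)
    if lo > hi:
        return
    # true copies (of any repeat contig) inside the gap, in scaffold order
    inside = []
    for name, entry in truth.items():
        if not entry.is_repeat:
            continue
        for (s, e, strand) in entry.copies:
            if s >= lo and e <= hi:
                inside.append((s, name, strand))
    inside.sort(reverse=(f == -1))
    rep.repeat_placeable += len(inside)
    if verdict != "correct":
        return
    ptr = 0
    for c in run:
        want_strand = c.orient if f == 1 else _flip(c.orient)
        while ptr < len(inside):
            s, name, strand = inside[ptr]
            ptr += 1
            if name == c.contig and strand == want_strand:
                rep.repeat_correct += 1
                break
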