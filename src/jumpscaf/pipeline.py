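"""End-to-end scaffolding: mappings -> scaffold graph -> scaffolds.

Each stage estimates its libraries, bundles pairs into distance-
corrected edges, merges them across libraries, filters, contracts the
graph into fenced subgraphs, solves each subgraph exactly, stitches at
border contigs, and sizes gaps by maximum likelihood.  With staging
enabled, short-insert libraries run first and later stages treat the
resulting scaffolds as units, with read mappings projected onto them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import graph as gb
from .contraction import decompose, find_border_contigs, stitch
from .gaps import GapConstraint, GapSystem, estimate_gap_sizes
from .graph import Contig, ScaffoldEdge, ScaffoldGraph, TruncatedInsertModel
from .io import (Config, MappingRecord, ScaffoldComponent, ScaffoldDoc,
                 ScaffoldGapRecord)
from .library import Library, estimate_library
from .search import GraphView, pair_satisfies, scaffold_subgraph

log = logging.getLogger("jumpscaf")


@dataclass
class RunResult:
    docs: List[ScaffoldDoc]
    graph: Optional[ScaffoldGraph] = None
    libraries: Dict[str, Library] = field(default_factory=dict)
    join_sd: Dict[frozenset, float] = field(default_factory=dict)
    stats: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# edges from read pairs
# ---------------------------------------------------------------------------

def build_edges(libraries: Sequence[Library], lib_pairs: Dict[str, list],
                contigs: Dict[str, Contig], config: Config
                ) -> List[ScaffoldEdge]:
    lengths = {c: ctg.length for c, ctg in contigs.items()}
    edges: List[ScaffoldEdge] = []
    for lib in libraries:
        model = TruncatedInsertModel(lib, config.bucket_size)
        for raw in gb.bundle_pairs(lib, lib_pairs[lib.id], lengths):
            g, sd, clamped = gb.estimate_edge_gap(
                raw, model, lengths, config.sigma_floor)
            edges.append(ScaffoldEdge(
                id=len(edges), c1=raw.c1, o1=raw.o1, c2=raw.c2, o2=raw.o2,
                gap=g, sd=sd, support=len(raw.s_obs), libs=(lib.id,),
                flagged=clamped))
    return edges


# ---------------------------------------------------------------------------
# pieces -> documents
# ---------------------------------------------------------------------------

def split_pieces(instances: Sequence[tuple], break_threshold: float
                 ) -> List[List[tuple]]:
    """Split a placement at break-sized gaps into scaffold pieces."""
    inst = sorted(instances, key=lambda t: (t[2], t[0]))
    pieces: List[List[tuple]] = []
    cur: List[tuple] = []
    prev_end = None
    for t in inst:
        if prev_end is not None and t[2] - prev_end > break_threshold:
            pieces.append(cur)
            cur = []
        cur.append(t)
        prev_end = t[3] if prev_end is None else max(prev_end, t[3])
    if cur:
        pieces.append(cur)
    return pieces


def _piece_constraints(piece: List[tuple], edges: Sequence[ScaffoldEdge],
                       m: float) -> List[GapConstraint]:
    """Distance constraints from edges satisfied within one piece."""
    by_contig: Dict[str, List[int]] = {}
    for i, (c, o, s, e) in enumerate(piece):
        by_contig.setdefault(c, []).append(i)
    cons: List[GapConstraint] = []
    for edge in edges:
        best = None
        for i in by_contig.get(edge.c1, ()):
            for j in by_contig.get(edge.c2, ()):
                if i == j:
                    continue
                a = (piece[i][1], piece[i][2], piece[i][3])
                b = (piece[j][1], piece[j][2], piece[j][3])
                if pair_satisfies(edge, a, b, m):
                    lo, hi = min(i, j), max(i, j)
                    implied = piece[hi][2] - piece[lo][3]
                    resid = abs(implied - edge.gap)
                    key = (resid, lo, hi)
                    if best is None or key < best[0]:
                        best = (key, lo, hi)
        if best is not None:
            _, lo, hi = best
            cons.append(GapConstraint(lo, hi, edge.gap, edge.sd, edge.support))
    return cons


def pieces_to_docs(pieces: Sequence[List[tuple]],
                   edges: Sequence[ScaffoldEdge], config: Config,
                   delta_max: float, prefix: str = "scaffold",
                   flags_by_contig: Optional[dict] = None
                   ) -> List[ScaffoldDoc]:
    """Final documents: re-estimate gap sizes jointly per piece."""
    docs: List[ScaffoldDoc] = []
    ordered = sorted(pieces, key=lambda p: min(c for c, _, _, _ in p))
    for pi, piece in enumerate(ordered):
        piece = sorted(piece, key=lambda t: (t[2], t[0]))
        provisional = [max(piece[i + 1][2] - piece[i][3], config.delta_min)
                       for i in range(len(piece) - 1)]
        cons = _piece_constraints(piece, edges, config.sd_multiplier)
        system = GapSystem(
            lengths=[t[3] - t[2] for t in piece], constraints=cons,
            delta_min=config.delta_min, delta_max=delta_max,
            defaults=provisional)
        gaps, _ = estimate_gap_sizes(
            system, weight_by_support=config.weight_by_support)
        parts: list = []
        flags: list = []
        for i, (c, o, s, e) in enumerate(piece):
            parts.append(ScaffoldComponent(
                contig=c, orient="+" if o == 1 else "-", start=0,
                length=int(round(e - s))))
            if flags_by_contig and c in flags_by_contig:
                for f in flags_by_contig[c]:
                    if f not in flags:
                        flags.append(f)
            if i < len(piece) - 1:
                parts.append(ScaffoldGapRecord(size=float(gaps[i])))
        doc = ScaffoldDoc(id=f"{prefix}_{pi:05d}", parts=parts,
                          flags=tuple(flags))
        doc.layout()
        docs.append(doc)
    return docs


# ---------------------------------------------------------------------------
# one scaffolding stage
# ---------------------------------------------------------------------------

def scaffold_stage(contigs: Dict[str, Contig], libraries: Sequence[Library],
                   lib_pairs: Dict[str, list], config: Config,
                   prefix: str = "scaffold") -> RunResult:
    edges = build_edges(libraries, lib_pairs, contigs, config)
    merged = gb.merge_libraries(edges, contigs, config.sd_multiplier)
    graph = ScaffoldGraph(contigs, merged)
    gb.drop_repeat_repeat_edges(graph)
    pe_insert = min(lib.mu for lib in libraries)
    graph, singletons = gb.apply_filters(graph, config, pe_insert)

    borders = find_border_contigs(graph, libraries, config.sd_multiplier)
    subs = decompose(graph, borders)
    log.info("%d fenced subgraphs (%d border contigs)", len(subs), len(borders))

    max_reach = max((e.gap + config.sd_multiplier * e.sd for e in graph.edges),
                    default=0.0)
    break_threshold = max_reach + 0.5
    pieces: List[List[tuple]] = []
    flags_by_contig: Dict[str, list] = {}
    stats = {"subgraphs": len(subs), "states": 0, "flagged_subgraphs": 0}
    for sub in subs:
        res = scaffold_subgraph(sub.contigs, sub.edges, config)
        stats["states"] += res.stats.get("states", 0)
        if res.flags:
            stats["flagged_subgraphs"] += 1
            for c in sub.contigs:
                flags_by_contig.setdefault(c, []).extend(res.flags)
        pieces.extend(split_pieces(res.instances, break_threshold))
    stitched = stitch(pieces, borders)

    placed = {c for piece in stitched for c, _, _, _ in piece}
    delta_max = config.delta_max if config.delta_max is not None \
        else max(lib.upper for lib in libraries)
    docs = pieces_to_docs(stitched, graph.edges, config, delta_max,
                          prefix=prefix, flags_by_contig=flags_by_contig)
    # singletons: filtered-out contigs plus any contig never placed
    extra = sorted(set(singletons) | (set(contigs) - placed - set(singletons)))
    for c in extra:
        doc = ScaffoldDoc(id=f"{prefix}_s_{c}", parts=[ScaffoldComponent(
            contig=c, orient="+", start=0, length=contigs[c].length)])
        doc.layout()
        docs.append(doc)

    join_sd = _join_sd_map(docs, graph)
    return RunResult(docs=docs, graph=graph,
                     libraries={l.id: l for l in libraries},
                     join_sd=join_sd, stats=stats)


def _join_sd_map(docs, graph: ScaffoldGraph) -> Dict[frozenset, float]:
    sd = {}
    for e in graph.edges:
        key = frozenset((e.c1, e.c2))
        if key not in sd or e.sd < sd[key]:
            sd[key] = e.sd
    return sd


# ---------------------------------------------------------------------------
# staging: scaffolds as units for the next stage
# ---------------------------------------------------------------------------

def collapse_to_meta(docs: Sequence[ScaffoldDoc],
                     contigs: Dict[str, Contig]) -> Tuple[dict, dict]:
    """Scaffolds become meta-contigs; returns (meta contigs, placement).

    ``placement`` maps each contig placed exactly once to
    (meta id, component); contigs placed several times (repeats) cannot
    be projected and are dropped from later stages.
    """
    meta: Dict[str, Contig] = {}
    count: Dict[str, int] = {}
    placement: Dict[str, tuple] = {}
    for doc in docs:
        doc.layout()
        total = 0.0
        length = 0
        for comp in doc.components():
            count[comp.contig] = count.get(comp.contig, 0) + 1
            placement[comp.contig] = (doc.id, comp)
            cov = contigs[comp.contig].coverage or 0.0
            total += cov * comp.length
            length += comp.length
        meta[doc.id] = Contig(id=doc.id, length=doc.span,
                              coverage=total / max(length, 1), is_repeat=False)
    for c, n in count.items():
        if n > 1:
            placement.pop(c, None)
    return meta, placement


def project_mappings(pairs: Sequence[tuple], placement: dict
                     ) -> List[tuple]:
    """Lift read pairs from contig coordinates onto meta-contigs."""
    out = []
    for r1, r2 in pairs:
        lifted = []
        for rec in (r1, r2):
            hit = placement.get(rec.contig)
            if hit is None:
                lifted = None
                break
            doc_id, comp = hit
            if comp.orient == "+":
                pos = comp.start + rec.pos
                strand = rec.strand
            else:
                pos = comp.start + (comp.length - rec.pos - rec.rlen)
                strand = "-" if rec.strand == "+" else "+"
            lifted.append(MappingRecord(rec.qname, rec.mate, doc_id, pos,
                                        strand, rec.rlen, rec.lib))
        if lifted:
            out.append(tuple(lifted))
    return out


def expand_meta_docs(docs: Sequence[ScaffoldDoc],
                     stage_docs: Dict[str, ScaffoldDoc]) -> List[ScaffoldDoc]:
    """Replace meta-contig components with the scaffolds they stand for."""
    out = []
    for doc in docs:
        parts: list = []
        for p in doc.parts:
            if isinstance(p, ScaffoldGapRecord):
                parts.append(ScaffoldGapRecord(size=p.size))
                continue
            inner = stage_docs.get(p.contig)
            if inner is None:
                parts.append(p)
                continue
            inner_parts = list(inner.parts)
            if p.orient == "-":
                inner_parts = [
                    (ScaffoldComponent(q.contig,
                                       "-" if q.orient == "+" else "+",
                                       0, q.length)
                     if isinstance(q, ScaffoldComponent)
                     else ScaffoldGapRecord(size=q.size))
                    for q in reversed(inner_parts)]
            else:
                inner_parts = [
                    (ScaffoldComponent(q.contig, q.orient, 0, q.length)
                     if isinstance(q, ScaffoldComponent)
                     else ScaffoldGapRecord(size=q.size))
                    for q in inner_parts]
            parts.extend(inner_parts)
        new = ScaffoldDoc(id=doc.id, parts=parts, flags=doc.flags)
        new.layout()
        out.append(new)
    return out


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def scaffold_pairs(contigs: Dict[str, Contig], lib_pairs: Dict[str, list],
                   config: Config,
                   libraries: Optional[Dict[str, Library]] = None
                   ) -> RunResult:
    """Scaffold contigs from per-library read pairs.

    Estimates library parameters and contig coverage from the mappings,
    then runs one scaffolding stage per insert-size group (scaffolds of
    earlier stages become units of later ones).
    """
    lengths = {c: ctg.length for c, ctg in contigs.items()}
    all_records = [rec for pairs in lib_pairs.values()
                   for pair in pairs for rec in pair]
    gb.compute_coverage(contigs, all_records)
    gb.classify_contigs(contigs, config.repeat_factor)

    libs: List[Library] = []
    for lib_id in sorted(lib_pairs):
        if libraries and lib_id in libraries:
            libs.append(libraries[lib_id])
        else:
            libs.append(estimate_library(
                lib_pairs[lib_id], lengths, lib_id,
                support_threshold=config.edge_support,
                sd_multiplier=config.sd_multiplier,
                sigma_floor=config.sigma_floor))
    stages = gb.stage_libraries(libs, config)

    cur_contigs = contigs
    cur_pairs = lib_pairs
    result: Optional[RunResult] = None
    stage_docs: Dict[str, ScaffoldDoc] = {}
    for si, stage in enumerate(stages):
        stage_pairs = {lib.id: cur_pairs[lib.id] for lib in stage}
        result = scaffold_stage(cur_contigs, stage, stage_pairs, config,
                                prefix=f"stage{si}" if len(stages) > 1
                                else "scaffold")
        if stage_docs:
            result.docs = expand_meta_docs(result.docs, stage_docs)
        if si < len(stages) - 1:
            meta, placement = collapse_to_meta(result.docs, contigs)
            next_pairs = {}
            for lib in [l for s in stages[si + 1:] for l in s]:
                next_pairs[lib.id] = project_mappings(cur_pairs[lib.id],
                                                      placement)
            stage_docs = {d.id: d for d in result.docs}
            cur_contigs = meta
            cur_pairs = next_pairs
    assert result is not None
    if len(stages) > 1:
        for i, doc in enumerate(result.docs):
            doc.id = f"scaffold_{i:05d}"
    return result


def scaffold_from_edges(contigs: Dict[str, Contig],
                        edges: Sequence[ScaffoldEdge], config: Config,
                        delta_max: float = 50000.0) -> RunResult:
    """Scaffold directly from ready-made edges (long-read link mode)."""
    for ctg in contigs.values():
        if ctg.coverage is None:
            ctg.coverage = 1.0
    graph = ScaffoldGraph(contigs, list(edges))
    gb.drop_repeat_repeat_edges(graph)
    graph.edges = [e for e in graph.edges if e.support >= config.edge_support]
    for i, e in enumerate(graph.edges):
        e.id = i
    max_reach = max((e.gap + config.sd_multiplier * e.sd for e in graph.edges),
                    default=0.0)
    pieces: List[List[tuple]] = []
    subs = decompose(graph, set())
    for sub in subs:
        res = scaffold_subgraph(sub.contigs, sub.edges, config)
        pieces.extend(split_pieces(res.instances, max_reach + 0.5))
    docs = pieces_to_docs(pieces, graph.edges, config, delta_max)
    placed = {c for piece in pieces for c, _, _, _ in piece}
    for c in sorted(set(contigs) - placed):
        doc = ScaffoldDoc(id=f"scaffold_s_{c}", parts=[ScaffoldComponent(
            contig=c, orient="+", start=0, length=contigs[c].length)])
        doc.layout()
        docs.append(doc)
    return RunResult(docs=docs, graph=graph)
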