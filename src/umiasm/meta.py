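"""Meta-assembly: pool all cells, assemble the super-cell, assign back.

Sparse per-cell coverage drops transcripts that the population as a whole
supports well. The meta mode pools every cell's deduplicated fragments into
one "super-cell" (PCR dedup stays per cell: identical molecules in two cells
are real), assembles it with the ordinary pipeline, and hands a pooled
transcript to a cell when that cell's own fragments support a sufficient
share of its exons. Each cell's final assembly is the union of its
single-cell transcripts with the transcripts assigned to it.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

from .assemble import AssemblyParams, Transcript, assemble_fragments
from .graph import IRParams
from .loci import LocusFilterParams
from .reads import Fragment, dedup_fragments, load_fragments


@dataclass
class MetaResult:
    """Super-cell transcripts plus per-cell fragment index and assemblies."""

    super_transcripts: list[Transcript]
    cell_fragments: dict[str, list[Fragment]]
    single_cell: dict[str, list[Transcript]] = field(default_factory=dict)
    unioned: dict[str, list[Transcript]] = field(default_factory=dict)


def meta_assemble(
    cell_alignment_paths: dict[str, str | os.PathLike],
    locus_params: LocusFilterParams | None = None,
    ir_params: IRParams | None = None,
    asm_params: AssemblyParams | None = None,
    min_mapq: int = 1,
    genome=None,
) -> tuple[list[Transcript], dict[str, list[Fragment]]]:
    """Assemble the pooled super-cell.

    ``cell_alignment_paths`` maps cell id to its alignment file. Dedup runs
    within each cell before pooling; cell identity is retained on every
    fragment. Returns (super-cell transcripts, cell -> fragments index). The
    result is independent of cell input order.
    """
    if not cell_alignment_paths:
        raise ValueError("meta-assembly needs at least one cell")
    index: dict[str, list[Fragment]] = {}
    for cell in sorted(cell_alignment_paths):
        frags = load_fragments(cell_alignment_paths[cell], min_mapq=min_mapq,
                               genome=genome, cell_id=cell)
        index[cell] = dedup_fragments(frags)
    pooled = sorted((f for frags in index.values() for f in frags),
                    key=lambda f: (f.chrom, f.start, f.end, f.cell_id or "",
                                   f.dedup_key))
    supers = assemble_fragments(
        pooled, locus_params, ir_params, asm_params,
        cell_id="super", source="meta_assigned")
    return supers, index


def assign_transcript_to_cell(
    transcript: Transcript,
    cell_fragments: list[Fragment],
    frac: float = 0.30,
    by_bases: bool = False,
) -> bool:
    """True when the cell's own reads support >= ``frac`` of the exons.

    An exon counts as supported when >= 1 aligned base of any of the cell's
    fragments overlaps it. With ``by_bases`` the fraction is computed over
    exonic bases instead of exon count.
    """
    blocks = sorted(b for f in cell_fragments
                    if f.chrom == transcript.chrom for b in f.blocks)
    if by_bases:
        supported = sum(_overlap_bases(exon, blocks) for exon in transcript.exons)
        return supported / transcript.length >= frac
    supported = sum(1 for exon in transcript.exons
                    if _overlap_bases(exon, blocks) > 0)
    return supported / len(transcript.exons) >= frac


def _overlap_bases(exon: tuple[int, int], blocks: list[tuple[int, int]]) -> int:
    lo, hi = exon
    total = 0
    for b0, b1 in blocks:
        if b0 >= hi:
            break
        total += max(0, min(b1, hi) - max(b0, lo))
    return total


def union_transcripts(
    single_cell: list[Transcript],
    assigned: list[Transcript],
) -> list[Transcript]:
    """Union the two assemblies of one cell.

    Keyed by intron chain for multi-exon transcripts and by the exon interval
    for single-exon ones; on a collision the single-cell record wins (its
    coverage was estimated from this cell's own reads).
    """
    merged: dict[tuple, Transcript] = {}
    for t in assigned:
        merged[t.chain_key()] = t
    for t in single_cell:
        merged[t.chain_key()] = t
    out = sorted(merged.values(),
                 key=lambda t: (t.chrom, t.start, t.end, t.strand,
                                t.transcript_id or ""))
    return out


def meta_assemble_cells(
    cell_alignment_paths: dict[str, str | os.PathLike],
    locus_params: LocusFilterParams | None = None,
    ir_params: IRParams | None = None,
    asm_params: AssemblyParams | None = None,
    min_mapq: int = 1,
    genome=None,
    assign_frac: float = 0.30,
    assign_by_bases: bool = False,
) -> MetaResult:
    """Full meta pipeline: super-cell assembly, assignment, per-cell union."""
    supers, index = meta_assemble(
        cell_alignment_paths, locus_params, ir_params, asm_params,
        min_mapq=min_mapq, genome=genome)
    result = MetaResult(super_transcripts=supers, cell_fragments=index)
    for cell in sorted(index):
        single = assemble_fragments(
            index[cell], locus_params, ir_params, asm_params,
            cell_id=cell, source="single_cell")
        assigned = [t for t in supers
                    if assign_transcript_to_cell(t, index[cell], assign_frac,
                                                 assign_by_bases)]
        result.single_cell[cell] = single
        result.unioned[cell] = union_transcripts(single, assigned)
    return result
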