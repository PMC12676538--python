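"""Alignment parsing, read-type classification, mate merging and PCR dedup.

Smart-seq3-style libraries mix two kinds of sequenced molecules: *UMI reads*,
which carry a unique molecular identifier ligated to the 5' end of the RNA
(stored by the upstream pipeline in the ``UB`` tag), and *internal reads* from
fragmented cDNA, which carry no UMI. UMI reads are strand-specific and pile up
near transcript start sites; internal reads cover the gene body like bulk
RNA-seq but are unstranded and noisier. Everything downstream of this module
works on :class:`Fragment` objects: one sequenced molecule observation, with
mates merged, classified as UMI or internal, and PCR duplicates removed.

Coordinates are 0-based half-open throughout the package; conversion to the
1-based closed GTF convention happens only in :mod:`umiasm.gtf`.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pysam

log = logging.getLogger(__name__)

UMI_TAG = "UB"
CELL_TAG = "BC"
TRANSCRIPT_STRAND_TAG = "XS"

#: read-type labels
UMI = "umi"
INTERNAL = "internal"
#: unknown strand marker
UNKNOWN = "."

# splice-site dinucleotide motifs (genomic plus-strand orientation)
_MOTIF_STRAND = {("GT", "AG"): "+", ("CT", "AC"): "-"}

# CIGAR op codes consuming the reference
_REF_OPS = {0, 2, 7, 8}  # M, D, =, X
_N_OP = 3


class AlignmentInputError(ValueError):
    """Unreadable, unsorted or otherwise unusable alignment input."""


@dataclass(frozen=True)
class AlignedRead:
    """A single filtered alignment record, pre mate-merging."""

    query_name: str
    chrom: str
    aligned_strand: str
    blocks: tuple[tuple[int, int], ...]
    junctions: tuple[tuple[int, int], ...]
    cigar_key: tuple[int, str]
    cell_barcode: str | None
    umi: str | None
    junction_strand_hint: str
    mapq: int
    is_paired: bool
    is_first_mate: bool
    duplicate_flag: bool


@dataclass(frozen=True)
class Fragment:
    """One sequenced molecule observation (merged mate pair or single read)."""

    chrom: str
    read_type: str
    umi: str | None
    blocks: tuple[tuple[int, int], ...]
    junctions: tuple[tuple[int, int], ...]
    strand: str
    dedup_key: tuple
    mate1_strand: str | None = None
    cell_id: str | None = None
    duplicate_flag: bool = False
    weight: int = 1

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def with_strand(self, strand: str) -> "Fragment":
        return replace(self, strand=strand)


@dataclass
class ReadTypeStats:
    """Per-cell tally of read types and their FR/RF orientation."""

    n_umi: int = 0
    n_internal: int = 0
    umi_fr: int = 0
    umi_rf: int = 0
    umi_unknown: int = 0
    internal_fr: int = 0
    internal_rf: int = 0
    internal_unknown: int = 0

    @property
    def internal_fraction(self) -> float:
        total = self.n_umi + self.n_internal
        return self.n_internal / total if total else 0.0

    @property
    def umi_fraction(self) -> float:
        total = self.n_umi + self.n_internal
        return self.n_umi / total if total else 0.0


def _walk_cigar(aln: pysam.AlignedSegment) -> tuple[tuple, tuple]:
    """Aligned blocks and implied introns from the CIGAR.

    Deletions (D) are bridged into the surrounding block -- only N operations
    open an intron.
    """
    blocks: list[list[int]] = []
    junctions: list[tuple[int, int]] = []
    pos = aln.reference_start
    for op, length in aln.cigartuples:
        if op in _REF_OPS:
            if blocks and blocks[-1][1] == pos:
                blocks[-1][1] = pos + length
            else:
                blocks.append([pos, pos + length])
            pos += length
        elif op == _N_OP:
            junctions.append((pos, pos + length))
            pos += length
        # I, S, H, P consume no reference
    return tuple((a, b) for a, b in blocks), tuple(junctions)


def _fetch_seq(genome, chrom: str, start: int, end: int) -> str:
    if isinstance(genome, Mapping):
        return str(genome[chrom][start:end]).upper()
    return str(genome[chrom][start:end]).upper()  # pyfaidx.Fasta and friends


def _motif_strand(genome, chrom: str, junctions: Sequence[tuple[int, int]]) -> str:
    hints = set()
    for js, je in junctions:
        donor = _fetch_seq(genome, chrom, js, js + 2)
        acceptor = _fetch_seq(genome, chrom, je - 2, je)
        hints.add(_MOTIF_STRAND.get((donor, acceptor), UNKNOWN))
    hints.discard(UNKNOWN)
    if len(hints) == 1:
        return hints.pop()
    return UNKNOWN


def _to_aligned_read(aln: pysam.AlignedSegment, genome=None) -> AlignedRead:
    umi = aln.get_tag(UMI_TAG) if aln.has_tag(UMI_TAG) else None
    if umi == "":
        umi = None
    blocks, junctions = _walk_cigar(aln)
    hint = UNKNOWN
    if junctions:
        if aln.has_tag(TRANSCRIPT_STRAND_TAG):
            tag = aln.get_tag(TRANSCRIPT_STRAND_TAG)
            if tag in "+-":
                hint = tag
        if hint == UNKNOWN and genome is not None:
            hint = _motif_strand(genome, aln.reference_name, junctions)
    return AlignedRead(
        query_name=aln.query_name,
        chrom=aln.reference_name,
        aligned_strand="-" if aln.is_reverse else "+",
        blocks=blocks,
        junctions=junctions,
        cigar_key=(aln.reference_start, aln.cigarstring),
        cell_barcode=aln.get_tag(CELL_TAG) if aln.has_tag(CELL_TAG) else None,
        umi=umi,
        junction_strand_hint=hint,
        mapq=aln.mapping_quality,
        is_paired=aln.is_paired,
        is_first_mate=(not aln.is_paired) or aln.is_read1,
        duplicate_flag=aln.is_duplicate,
    )


def _merge_blocks(blocks: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for b0, b1 in sorted(blocks):
        if merged and b0 <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b1)
        else:
            merged.append([b0, b1])
    return tuple((a, b) for a, b in merged)


def merge_mates(reads: Sequence[AlignedRead], cell_id: str | None = None) -> Fragment:
    """Merge one or two mates of a pair into a single :class:`Fragment`.

    Overlapping mate blocks are unioned; the gap between non-overlapping mates
    (the unsequenced insert) is *not* recorded as a junction.
    """
    umi = next((r.umi for r in reads if r.umi), None)
    read_type = UMI if umi else INTERNAL
    blocks = _merge_blocks(b for r in reads for b in r.blocks)
    junctions = tuple(sorted({j for r in reads for j in r.junctions}))
    hints = {r.junction_strand_hint for r in reads} - {UNKNOWN}
    hint = hints.pop() if len(hints) == 1 else UNKNOWN
    first = next((r for r in reads if r.is_first_mate), reads[0])
    mate1_strand = first.aligned_strand if first.is_first_mate else (
        "+" if first.aligned_strand == "-" else "-")
    if read_type == UMI:
        # UMI reads are FR strand-specific: fall back on read-1 orientation
        strand = hint if hint != UNKNOWN else mate1_strand
    else:
        strand = hint
    key = (reads[0].chrom, tuple(sorted(r.cigar_key for r in reads)))
    barcode = next((r.cell_barcode for r in reads if r.cell_barcode), None)
    return Fragment(
        chrom=reads[0].chrom,
        read_type=read_type,
        umi=umi,
        blocks=blocks,
        junctions=junctions,
        strand=strand,
        dedup_key=key,
        mate1_strand=mate1_strand,
        cell_id=cell_id if cell_id is not None else barcode,
        duplicate_flag=any(r.duplicate_flag for r in reads),
    )


def load_fragments(
    alignment_path: str | os.PathLike,
    region: tuple[str, int, int] | None = None,
    min_mapq: int = 1,
    genome=None,
    cell_id: str | None = None,
) -> list[Fragment]:
    """Load one cell's alignments into coordinate-sorted fragments.

    Unmapped, secondary and supplementary records and records below the MAPQ
    floor are dropped. Mates sharing a query name are merged. ``genome`` (a
    mapping of chromosome to sequence, or a ``pyfaidx.Fasta``) enables
    splice-motif strand inference when the aligner left no transcript-strand
    tag. Records whose CIGAR cannot be interpreted are skipped with a warning.
    """
    mode = "rb" if str(alignment_path).endswith(".bam") else "r"
    try:
        af = pysam.AlignmentFile(str(alignment_path), mode, check_sq=True)
    except (OSError, ValueError) as exc:
        raise AlignmentInputError(f"cannot read {alignment_path}: {exc}") from exc

    so = (af.header.to_dict().get("HD") or {}).get("SO")
    if so is not None and so != "coordinate":
        raise AlignmentInputError(
            f"{alignment_path} is not coordinate-sorted (SO={so})")

    pending: dict[str, AlignedRead] = {}
    fragments: list[Fragment] = []
    n_skipped = 0
    last = (-1, -1)
    chrom_order: dict[str, int] = {}
    with af:
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            cid = chrom_order.setdefault(aln.reference_name,
                                         len(chrom_order))
            if (cid, aln.reference_start) < last and cid == last[0]:
                raise AlignmentInputError(
                    f"{alignment_path} is not coordinate-sorted")
            last = (cid, aln.reference_start)
            if aln.query_sequence and aln.infer_query_length() not in (
                    None, len(aln.query_sequence)):
                n_skipped += 1
                continue
            try:
                read = _to_aligned_read(aln, genome=genome)
            except (ValueError, KeyError):
                n_skipped += 1
                continue
            if read.is_paired and read.query_name in pending:
                mate = pending.pop(read.query_name)
                if mate.chrom == read.chrom:
                    fragments.append(merge_mates([mate, read], cell_id))
                else:  # cross-chromosome pair: keep each side alone
                    fragments.append(merge_mates([mate], cell_id))
                    fragments.append(merge_mates([read], cell_id))
            elif read.is_paired and aln.mate_is_mapped and \
                    aln.next_reference_name == aln.reference_name:
                pending[read.query_name] = read
            else:
                fragments.append(merge_mates([read], cell_id))
    for read in pending.values():  # mate never showed up (filtered)
        fragments.append(merge_mates([read], cell_id))
    if n_skipped:
        log.warning("%s: skipped %d malformed records", alignment_path, n_skipped)
    fragments.sort(key=lambda f: (f.chrom, f.start, f.end, f.dedup_key))
    if region is not None:
        chrom, lo, hi = region
        fragments = [f for f in fragments
                     if f.chrom == chrom and f.start < hi and f.end > lo]
    return fragments


def dedup_fragments(fragments: Iterable[Fragment]) -> list[Fragment]:
    """Remove PCR duplicates within one cell.

    Two fragments are duplicates when their alignment is identical: same
    chromosome and the same (position, CIGAR) for every constituent read. The
    first fragment in input (coordinate) order is kept. Fragments already
    flagged as duplicates upstream are dropped as well.
    """
    seen: set = set()
    out: list[Fragment] = []
    for f in fragments:
        if f.duplicate_flag:
            continue
        if f.dedup_key in seen:
            continue
        seen.add(f.dedup_key)
        out.append(f)
    return out


def summarize_read_types(fragments: Iterable[Fragment]) -> ReadTypeStats:
    """Tally read types and FR/RF orientation relative to the inferred strand."""
    stats = ReadTypeStats()
    for f in fragments:
        if f.read_type == UMI:
            stats.n_umi += 1
        else:
            stats.n_internal += 1
        if f.strand == UNKNOWN or f.mate1_strand is None:
            orient = "unknown"
        elif f.mate1_strand == f.strand:
            orient = "fr"
        else:
            orient = "rf"
        key = f"{f.read_type}_{orient}"
        setattr(stats, key, getattr(stats, key) + 1)
    return stats
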