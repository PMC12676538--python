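"""Gene-locus construction and contaminant-locus purging.

Fragments with a determined strand are clustered per chromosome and strand
into loci: maximal chains in which consecutive spans overlap or lie within a
small gap. Junction-free internal fragments have no strand of their own; they
are recruited by nearby loci whose strand is vouched for by at least one UMI
fragment. Loci that end up with too few UMI fragments, in count or in
proportion, are treated as intergenic/intronic contamination by internal
reads and are purged before any graph is built.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .reads import Fragment, UMI, UNKNOWN


@dataclass
class LocusFilterParams:
    """Thresholds governing locus formation and purging.

    ``min_umi_count`` / ``min_umi_ratio``: a locus is purged when its UMI
    fragment count is below the former *or* the UMI fraction of its fragments
    is below the latter. ``nearby_window`` (bp) bounds how far an
    unknown-strand internal fragment may sit from a locus and still be
    recruited. ``cluster_gap`` (bp) is the largest gap between consecutive
    fragment spans that still keeps them in one locus.
    """

    min_umi_count: int = 2
    min_umi_ratio: float = 0.05
    nearby_window: int = 100
    cluster_gap: int = 50

    def __post_init__(self) -> None:
        if self.nearby_window < 0 or not (0.0 <= self.min_umi_ratio <= 1.0):
            raise ValueError("invalid locus filter parameters")


@dataclass
class Locus:
    """A strand-resolved cluster of fragments on one chromosome."""

    chrom: str
    strand: str
    start: int
    end: int
    fragments: list[Fragment] = field(default_factory=list)

    @property
    def umi_count(self) -> int:
        return sum(1 for f in self.fragments if f.read_type == UMI)

    @property
    def internal_count(self) -> int:
        return sum(1 for f in self.fragments if f.read_type != UMI)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def distance_to(self, span: tuple[int, int]) -> int:
        """Closest-edge distance to an interval; 0 when overlapping."""
        lo, hi = span
        if hi <= self.start:
            return self.start - hi
        if lo >= self.end:
            return lo - self.end
        return 0


def cluster_loci(fragments: list[Fragment], params: LocusFilterParams) -> list[Locus]:
    """Cluster strand-determined fragments into loci.

    Input must be sorted by chromosome and leftmost coordinate; fragments with
    unknown strand are ignored here (see :func:`resolve_internal_strand`).
    """
    last: dict[str, int] = {}
    order: dict[str, int] = {}
    for f in fragments:
        order.setdefault(f.chrom, len(order))
        if f.start < last.get(f.chrom, -1):
            raise ValueError("fragments are not coordinate-sorted")
        last[f.chrom] = f.start

    open_loci: dict[tuple[str, str], Locus] = {}
    loci: list[Locus] = []
    for f in fragments:
        if f.strand == UNKNOWN:
            continue
        key = (f.chrom, f.strand)
        cur = open_loci.get(key)
        if cur is not None and f.start - cur.end <= params.cluster_gap:
            cur.fragments.append(f)
            cur.end = max(cur.end, f.end)
        else:
            cur = Locus(f.chrom, f.strand, f.start, f.end, [f])
            open_loci[key] = cur
            loci.append(cur)
    loci.sort(key=lambda l: (order[l.chrom], l.start, l.end, l.strand))
    return loci


def resolve_internal_strand(
    unknown_fragments: list[Fragment],
    loci: list[Locus],
    window: int = 100,
) -> list[tuple[Fragment, list[Locus]]]:
    """Assign unknown-strand internal fragments to nearby UMI-supported loci.

    A fragment joins every locus that overlaps it or lies within ``window`` bp
    and has at least one UMI fragment of its own (a locus with no UMI evidence
    cannot vouch for a strand). When loci on both strands qualify the fragment
    is duplicated into each. Fragments matching no locus are held out of
    assembly. Returns the per-fragment assignment for auditing; recruited
    loci are mutated in place (fragment appended, span extended as needed).
    """
    by_chrom: dict[str, list[Locus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    assignment: list[tuple[Fragment, list[Locus]]] = []
    for f in unknown_fragments:
        homes: list[Locus] = []
        for locus in by_chrom.get(f.chrom, []):
            if locus.umi_count < 1:
                continue
            if locus.distance_to(f.span) <= window:
                homes.append(locus)
        for locus in homes:
            locus.fragments.append(f.with_strand(locus.strand))
            locus.start = min(locus.start, f.start)
            locus.end = max(locus.end, f.end)
        assignment.append((f, homes))
    return assignment


def filter_contaminant_loci(
    loci: list[Locus], params: LocusFilterParams
) -> tuple[list[Locus], list[Locus]]:
    """Split loci into (kept, purged) by UMI support.

    A locus is purged iff ``umi_count < min_umi_count`` or the UMI fraction of
    its fragments is below ``min_umi_ratio``; such loci are overwhelmingly
    intergenic or intronic piles of internal reads.
    """
    kept: list[Locus] = []
    purged: list[Locus] = []
    for locus in loci:
        n_umi = locus.umi_count
        total = n_umi + locus.internal_count
        ratio = n_umi / total if total else 0.0
        if n_umi < params.min_umi_count or ratio < params.min_umi_ratio:
            purged.append(locus)
        else:
            kept.append(locus)
    return kept, purged
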