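"""Graph decomposition into transcripts and UMI-anchored transcript selection.

The pruned splice graph is decomposed into s-t paths in a phase-preserving
manner: every vertex chain co-observed inside a single fragment must appear
contiguously in at least one reported path. Decomposition is a greedy chain
extension. The highest-multiplicity unsatisfied phasing path seeds a chain,
which is extended towards the source and sink one vertex at a time; at every
step, phasing paths overlapping the current chain end vote for the next
vertex (heaviest total multiplicity wins; edge weight breaks the remaining
ties, then genomic coordinate). Extension repeats until every phasing path
is contained in some chain; each edge's fragment weight is then split evenly
among the chains using it, and a chain's abundance is the bottleneck of its
shares -- so paralogous paths through a shared junction divide, rather than
race for, its support.

Because Smart-seq3 UMIs mark the 5' terminus of the RNA, a candidate whose
5'-terminal exon carries no UMI support is almost always intronic or
intergenic contamination picked up by internal reads. Candidates are
therefore anchored at the first exon: the 5'-most exon of the path (leftmost
on '+', rightmost on '-') must be supported by at least ``first_exon_min_umi``
UMI fragments.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from . import graph as sg
from .graph import SOURCE, SINK, IRParams, PhasingPath, SpliceGraph
from .loci import Locus, LocusFilterParams, cluster_loci, \
    filter_contaminant_loci, resolve_internal_strand
from .reads import Fragment, UNKNOWN, dedup_fragments, load_fragments

log = logging.getLogger(__name__)


@dataclass
class AssemblyParams:
    """Transcript selection knobs.

    ``first_exon_min_umi``: UMI fragments required on the 5'-terminal exon.
    ``min_transcript_coverage`` / ``min_transcript_length`` are reporting
    floors (set to 0 to disable). ``phasing_min_support``: fragments required
    before a phasing path constrains decomposition.
    """

    first_exon_min_umi: int = 1
    min_transcript_coverage: float = 1.0
    min_transcript_length: int = 150
    phasing_min_support: int = 1

    def __post_init__(self) -> None:
        if min(self.first_exon_min_umi, self.min_transcript_coverage,
               self.min_transcript_length, self.phasing_min_support) < 0:
            raise ValueError("assembly parameters must be non-negative")


@dataclass(frozen=True)
class Transcript:
    """An assembled transcript: ordered exons on one strand of one chromosome."""

    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    coverage: float = 0.0
    cell_id: str | None = None
    source: str = "single_cell"
    transcript_id: str | None = None
    gene_id: str | None = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((a[1], b[0]) for a, b in zip(self.exons, self.exons[1:]))

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    def chain_key(self) -> tuple:
        """Identity key: intron chain for multi-exon, exon span for single-exon."""
        if self.is_multi_exon:
            return (self.chrom, self.strand, self.introns)
        return (self.chrom, self.strand, self.exons[0])


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def _contains_contiguous(chain: tuple[int, ...], sub: tuple[int, ...]) -> bool:
    k = len(sub)
    return any(chain[i:i + k] == sub for i in range(len(chain) - k + 1))


def decompose_graph(
    g: SpliceGraph,
    paths: list[PhasingPath],
    params: AssemblyParams | None = None,
) -> list[tuple[tuple[int, ...], float]]:
    """Decompose the pruned graph into (vertex chain, abundance) candidates."""
    params = params or AssemblyParams()
    if g.n_vertices == 0 or not paths:
        if g.n_vertices and not paths:
            log.warning("graph %s:%s has vertices but no phasing support",
                        g.chrom, g.strand)
        return []

    guidance = sorted(paths, key=lambda p: (-p.multiplicity,
                                            g.interval(p.vertices[0]),
                                            p.vertices))
    active = [p for p in guidance if p.multiplicity >= params.phasing_min_support]
    satisfied = [False] * len(active)
    results: list[tuple[tuple[int, ...], float]] = []

    def _vote(anchor: int, want_pred: bool, chain: list[int]) -> int | None:
        votes: dict[int, int] = {}
        for q in guidance:
            qv = q.vertices
            if anchor not in qv:
                continue
            i = qv.index(anchor)
            if want_pred:
                if i == 0:
                    continue
                k = min(len(qv) - i, len(chain))
                if all(qv[i + j] == chain[j] for j in range(k)):
                    votes[qv[i - 1]] = votes.get(qv[i - 1], 0) + q.multiplicity
            else:
                if i == len(qv) - 1:
                    continue
                k = min(i + 1, len(chain))
                if all(qv[i - j] == chain[-1 - j] for j in range(k)):
                    votes[qv[i + 1]] = votes.get(qv[i + 1], 0) + q.multiplicity
        if not votes:
            return None
        return min(votes, key=lambda v: (-votes[v], v))

    chains: list[tuple[int, ...]] = []
    while not all(satisfied):
        idx = next(i for i in range(len(active)) if not satisfied[i])
        chain = list(active[idx].vertices)
        # extend towards the source
        while not g.has_edge(SOURCE, chain[0]) or \
                _vote(chain[0], True, chain) is not None:
            pred = _vote(chain[0], True, chain)
            if pred is None:
                ins = [u for u in g.in_neighbors(chain[0]) if u != SOURCE]
                if not ins:
                    break
                pred = min(ins, key=lambda u: (-g.we(u, chain[0]), u))
            chain.insert(0, pred)
        # extend towards the sink
        while not g.has_edge(chain[-1], SINK) or \
                _vote(chain[-1], False, chain) is not None:
            succ = _vote(chain[-1], False, chain)
            if succ is None:
                outs = [u for u in g.out_neighbors(chain[-1]) if u != SINK]
                if not outs:
                    break
                succ = min(outs, key=lambda u: (-g.we(chain[-1], u), u))
            chain.append(succ)
        tchain = tuple(chain)
        for i, p in enumerate(active):
            if not satisfied[i] and _contains_contiguous(tchain, p.vertices):
                satisfied[i] = True
        chains.append(tchain)

    # abundance: each edge's fragment weight is split evenly among the
    # chains using it; a chain's abundance is its bottleneck share
    users: dict[tuple[int, int], int] = {}
    starts: dict[int, int] = {}
    for chain in chains:
        if len(chain) == 1:
            starts[chain[0]] = starts.get(chain[0], 0) + 1
        for e in zip(chain, chain[1:]):
            users[e] = users.get(e, 0) + 1
    for chain in chains:
        if len(chain) == 1:
            v = chain[0]
            abundance = g.we(SOURCE, v) / starts[v] if g.has_edge(SOURCE, v) \
                else 0.0
        else:
            abundance = min(g.we(u, v) / users[(u, v)]
                            for u, v in zip(chain, chain[1:]))
        results.append((chain, abundance))
    results.sort(key=lambda r: (g.interval(r[0][0]), r[0]))
    return results


# ---------------------------------------------------------------------------
# path -> transcript
# ---------------------------------------------------------------------------

def path_to_exons(g: SpliceGraph, chain: tuple[int, ...]) -> tuple:
    """Merge immediately-joint consecutive vertices of a path into exons."""
    exon_runs: list[list[int]] = [[chain[0]]]
    for u, v in zip(chain, chain[1:]):
        if g.immediately_joint(u, v):
            exon_runs[-1].append(v)
        else:
            exon_runs.append([v])
    exons = tuple((g.interval(run[0])[0], g.interval(run[-1])[1])
                  for run in exon_runs)
    return exons, exon_runs


def anchor_first_exon(
    candidates: list[tuple[tuple[int, ...], float]],
    g: SpliceGraph,
    params: AssemblyParams,
    strand: str,
) -> list[tuple[tuple[int, ...], float]]:
    """Keep candidates whose 5'-terminal exon has sufficient UMI support.

    The 5'-terminal exon is the leftmost exon of the path on '+' and the
    rightmost on '-'; its support is the max ``w_m`` over the vertices merged
    into it.
    """
    kept = []
    for chain, abundance in candidates:
        _, runs = path_to_exons(g, chain)
        terminal = runs[0] if strand == "+" else runs[-1]
        support = max(g.wm(v) for v in terminal)
        if support >= params.first_exon_min_umi:
            kept.append((chain, abundance))
    return kept


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class AssemblyReport:
    """Per-run counters, logged and kept for auditing."""

    n_fragments: int = 0
    n_after_dedup: int = 0
    n_loci: int = 0
    n_loci_purged: int = 0
    n_vertices_pruned: int = 0
    n_candidates: int = 0
    n_transcripts: int = 0
    purged_loci: list[Locus] = field(default_factory=list)


def assemble_locus(
    locus: Locus,
    gene_id: str,
    ir_params: IRParams,
    asm_params: AssemblyParams,
    cell_id: str | None = None,
    source: str = "single_cell",
    report: AssemblyReport | None = None,
) -> list[Transcript]:
    """Assemble one kept locus: build, prune, phase, decompose, anchor, floor."""
    g = sg.build_graph(locus)
    before = g.n_vertices
    sg.prune(g, ir_params)
    if report is not None:
        report.n_vertices_pruned += before - g.n_vertices
    if g.n_vertices == 0:
        return []
    phasing = sg.extract_phasing_paths(locus, g)
    candidates = decompose_graph(g, phasing, asm_params)
    if report is not None:
        report.n_candidates += len(candidates)
    candidates = anchor_first_exon(candidates, g, asm_params, locus.strand)
    out: list[Transcript] = []
    n = 0
    for chain, abundance in candidates:
        exons, _ = path_to_exons(g, chain)
        length = sum(b - a for a, b in exons)
        if asm_params.min_transcript_coverage > 0 and \
                abundance < asm_params.min_transcript_coverage:
            continue
        if asm_params.min_transcript_length > 0 and \
                length < asm_params.min_transcript_length:
            continue
        n += 1
        out.append(Transcript(
            chrom=locus.chrom, strand=locus.strand, exons=exons,
            coverage=abundance, cell_id=cell_id, source=source,
            transcript_id=f"{gene_id}.{n}", gene_id=gene_id))
    return out


def assemble_fragments(
    fragments: list[Fragment],
    locus_params: LocusFilterParams | None = None,
    ir_params: IRParams | None = None,
    asm_params: AssemblyParams | None = None,
    cell_id: str | None = None,
    source: str = "single_cell",
    report: AssemblyReport | None = None,
) -> list[Transcript]:
    """Assemble deduplicated, coordinate-sorted fragments of one (super-)cell."""
    locus_params = locus_params or LocusFilterParams()
    ir_params = ir_params or IRParams()
    asm_params = asm_params or AssemblyParams()
    report = report if report is not None else AssemblyReport()
    report.n_after_dedup = len(fragments)

    loci = cluster_loci(fragments, locus_params)
    unknown = [f for f in fragments if f.strand == UNKNOWN]
    resolve_internal_strand(unknown, loci, locus_params.nearby_window)
    kept, purged = filter_contaminant_loci(loci, locus_params)
    report.n_loci = len(loci)
    report.n_loci_purged = len(purged)
    report.purged_loci = purged

    transcripts: list[Transcript] = []
    for i, locus in enumerate(kept, start=1):
        gene_id = f"LOC{i:06d}"
        transcripts.extend(assemble_locus(
            locus, gene_id, ir_params, asm_params,
            cell_id=cell_id, source=source, report=report))
    transcripts.sort(key=lambda t: (t.chrom, t.start, t.end, t.strand,
                                    t.transcript_id or ""))
    report.n_transcripts = len(transcripts)
    log.info("assembled %d transcripts from %d loci (%d purged, "
             "%d vertices pruned)", report.n_transcripts, report.n_loci,
             report.n_loci_purged, report.n_vertices_pruned)
    return transcripts


def assemble_cell(
    alignment_path: str | os.PathLike,
    locus_params: LocusFilterParams | None = None,
    ir_params: IRParams | None = None,
    asm_params: AssemblyParams | None = None,
    min_mapq: int = 1,
    genome=None,
    cell_id: str | None = None,
    report: AssemblyReport | None = None,
) -> list[Transcript]:
    """Full single-cell pipeline from an alignment file to transcripts."""
    report = report if report is not None else AssemblyReport()
    fragments = load_fragments(alignment_path, min_mapq=min_mapq,
                               genome=genome, cell_id=cell_id)
    report.n_fragments = len(fragments)
    fragments = dedup_fragments(fragments)
    return assemble_fragments(
        fragments, locus_params, ir_params, asm_params,
        cell_id=cell_id, source="single_cell", report=report)
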