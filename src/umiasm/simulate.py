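"""Synthetic ground truth and Smart-seq3-like alignments for testing.

The generator fabricates a genome, a set of gene loci with 1-3 isoforms
each, and per-cell paired-end alignments reproducing the read-type
disparities of Smart-seq3 libraries: UMI fragments (UB tag) start near the
transcript 5' end with a geometric decay and are FR strand-specific;
internal fragments tile the gene body near-uniformly with ~50/50
orientation; optional contamination injects intronic piles, full/partial
intron-retention support and PCR duplicates. Splice motifs are written as
GT..AG (CT..AC on '-') so motif-based strand inference works on the
fabricated genome. Output is byte-deterministic for a fixed seed, and every
random layer draws from its own seed stream, so switching one kind of
contamination on or off leaves all other records identical.
"""
from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .assemble import Transcript
from .graph import SINK, SOURCE, SpliceGraph
from .gtf import write_gtf

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Read-type composition follows the tallies observed in Smart-seq3 data:
    about a quarter of fragments carry UMIs, UMI fragments are strongly FR
    (default 0.85) while internal fragments are orientation-balanced, and UMI
    fragment starts decay geometrically away from the TSS.
    """

    seed: int = 0
    n_cells: int = 1
    n_loci: int = 20
    exons_per_transcript: tuple[int, int] = (2, 5)
    transcripts_per_locus: tuple[int, int] = (1, 3)
    exon_length: tuple[int, int] = (80, 250)
    intron_length: tuple[int, int] = (150, 400)
    locus_spacing: int = 3000
    umi_fraction: float = 0.25
    umi_5prime_bias: float = 0.02      # geometric decay of TSS offset
    umi_fr_fraction: float = 0.85
    internal_fr_fraction: float = 0.50
    intronic_contamination_rate: float = 0.05
    intergenic_contamination_rate: float = 0.05
    full_ir_injection_rate: float = 0.0
    partial_ir_injection_rate: float = 0.0
    ir_relative_support: float = 0.2   # injected IR support vs splice support
    pcr_duplicate_rate: float = 0.05
    read_length: int = 100
    fragment_length_mean: float = 170.0
    fragment_length_sd: float = 15.0
    fragment_length_range: tuple[int, int] = (130, 195)
    fragments_per_transcript: int = 30
    guaranteed_first_exon_umi: int = 2
    expressed_fraction: float = 0.9
    write_xs_tags: bool = True
    chrom: str = "chrS"
    withhold_first_exon_umi: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        fracs = (self.umi_fraction, self.umi_fr_fraction,
                 self.internal_fr_fraction, self.intronic_contamination_rate,
                 self.intergenic_contamination_rate, self.pcr_duplicate_rate,
                 self.expressed_fraction)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if self.exon_length[0] < self.read_length // 2:
            raise ValueError(
                f"exons of {self.exon_length[0]} bp are too short for "
                f"{self.read_length} bp reads")

    @classmethod
    def clean(cls, seed: int = 0, n_loci: int = 50, n_cells: int = 1,
              **kw) -> "SimConfig":
        """Noiseless conditions: no contamination, fully FR UMI reads,
        every transcript expressed with >=2 first-exon UMI fragments."""
        return cls(seed=seed, n_loci=n_loci, n_cells=n_cells,
                   umi_fr_fraction=1.0, intronic_contamination_rate=0.0,
                   intergenic_contamination_rate=0.0, pcr_duplicate_rate=0.0,
                   expressed_fraction=1.0, **kw)

    @classmethod
    def with_intron_retention(cls, seed: int = 0, n_loci: int = 50,
                              n_cells: int = 1, **kw) -> "SimConfig":
        """Clean conditions plus full/partial IR support in every locus,
        sized so the injected vertices satisfy the default pruning rules."""
        return cls.clean(seed=seed, n_loci=n_loci, n_cells=n_cells,
                         full_ir_injection_rate=1.0,
                         partial_ir_injection_rate=1.0, **kw)


@dataclass(frozen=True)
class TruthTranscript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((a[1], b[0]) for a, b in zip(self.exons, self.exons[1:]))


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: dict[str, str]
    truth: list[TruthTranscript]
    genome_path: Path
    truth_gtf: Path
    truth_table: pd.DataFrame
    truth_table_path: Path
    sam_paths: dict[str, Path]


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


# ---------------------------------------------------------------------------
# gene structures
# ---------------------------------------------------------------------------

def _make_structures(cfg: SimConfig) -> list[TruthTranscript]:
    rng = _rng(cfg.seed, 0)
    cursor = 1000
    truth: list[TruthTranscript] = []
    for gi in range(cfg.n_loci):
        gene = f"G{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(cfg.exons_per_transcript[0],
                             cfg.exons_per_transcript[1] + 1))
        n_tx = int(rng.integers(cfg.transcripts_per_locus[0],
                                cfg.transcripts_per_locus[1] + 1))
        exons: list[tuple[int, int]] = []
        pos = cursor
        for j in range(k):
            el = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            exons.append((pos, pos + el))
            pos += el
            if j < k - 1:
                pos += int(rng.integers(cfg.intron_length[0],
                                        cfg.intron_length[1] + 1))
        master = tuple(exons)
        isoforms: list[tuple[tuple[int, int], ...]] = [master]
        # isoforms vary at a single alternative-splicing event so that
        # fragment-level phasing identifies every chain unambiguously
        if n_tx >= 2:
            if k >= 3:
                j = int(rng.integers(1, k - 1))  # internal exon to vary
                isoforms.append(master[:j] + master[j + 1:])  # exon skipping
                if n_tx >= 3:
                    # mutually exclusive exon in the same window, disjoint
                    # from the master exon so fragment phasing stays unique
                    lo, hi = master[j - 1][1], master[j + 1][0]
                    windows = [(lo + 40, master[j][0] - 40),
                               (master[j][1] + 40, hi - 40)]
                    alt_len = min(int(rng.integers(cfg.exon_length[0],
                                                   cfg.exon_length[1] + 1)),
                                  max(b - a for a, b in windows))
                    fits = [(a, b) for a, b in windows if b - a >= alt_len]
                    if alt_len >= 50 and fits:
                        a, b = fits[int(rng.integers(len(fits)))]
                        start = a + int(rng.integers(0, b - a - alt_len + 1))
                        isoforms.append(master[:j] + ((start, start + alt_len),)
                                        + master[j + 1:])
            else:  # two exons: alternative first exon inside the intron
                lo, hi = master[0][1], master[1][0]
                alt_len = min(int(rng.integers(cfg.exon_length[0],
                                               cfg.exon_length[1] + 1)),
                              hi - lo - 80)
                if alt_len >= 50:
                    a = lo + 40
                    isoforms.append(((a, a + alt_len),) + master[1:])
        for ti, iso in enumerate(isoforms, start=1):
            truth.append(TruthTranscript(f"{gene}.T{ti}", gene, cfg.chrom,
                                         strand, iso))
        cursor = pos + cfg.locus_spacing
    return truth


def _make_genome(cfg: SimConfig, truth: list[TruthTranscript]) -> dict[str, str]:
    rng = _rng(cfg.seed, 1)
    length = max(t.exons[-1][1] for t in truth) + 1000
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length)
    for t in truth:  # canonical splice motifs so strand is motif-inferrable
        donor, acceptor = (b"GT", b"AG") if t.strand == "+" else (b"CT", b"AC")
        for js, je in t.introns:
            seq[js:js + 2] = [donor[:1], donor[1:]]
            seq[je - 2:je] = [acceptor[:1], acceptor[1:]]
    return {cfg.chrom: b"".join(seq).decode()}


# ---------------------------------------------------------------------------
# transcript coordinate mapping
# ---------------------------------------------------------------------------

def _tx_interval_to_blocks(t: TruthTranscript, p0: int, p1: int):
    """Genomic blocks and junctions of the 5'-based interval [p0, p1)."""
    if t.strand == "-":
        p0, p1 = t.length - p1, t.length - p0
    blocks: list[tuple[int, int]] = []
    acc = 0
    for a, b in t.exons:
        el = b - a
        lo, hi = max(p0 - acc, 0), min(p1 - acc, el)
        if lo < hi:
            blocks.append((a + lo, a + hi))
        acc += el
    junctions = tuple((x[1], y[0]) for x, y in zip(blocks, blocks[1:]))
    return tuple(blocks), junctions


# ---------------------------------------------------------------------------
# SAM record assembly
# ---------------------------------------------------------------------------

def _cigar(blocks) -> list[tuple[int, int]]:
    ops = []
    for i, (a, b) in enumerate(blocks):
        if i:
            ops.append((3, a - blocks[i - 1][1]))  # N
        ops.append((0, b - a))  # M
    return ops


def _seq(genome: dict[str, str], chrom: str, blocks) -> str:
    return "".join(genome[chrom][a:b] for a, b in blocks)


@dataclass
class _Rec:
    qname: str
    flag: int
    pos: int
    blocks: tuple
    junctions: tuple
    mate_pos: int = -1
    tlen: int = 0
    umi: str | None = None
    xs: str | None = None
    cell: str = ""


def _pair_records(qname, t, p, flen, rl, fr, umi, cell, xs_on) -> list[_Rec]:
    rl = min(rl, flen)
    b1, j1 = _tx_interval_to_blocks(t, p, p + rl)
    b2, j2 = _tx_interval_to_blocks(t, p + flen - rl, p + flen)
    read1_strand = t.strand if fr else ("-" if t.strand == "+" else "+")
    r1_rev = read1_strand == "-"
    f1 = 0x1 | 0x2 | 0x40 | (0x10 if r1_rev else 0) | (0x20 if not r1_rev else 0)
    f2 = 0x1 | 0x2 | 0x80 | (0x10 if not r1_rev else 0) | (0x20 if r1_rev else 0)
    lo = min(b1[0][0], b2[0][0])
    hi = max(b1[-1][1], b2[-1][1])
    xs = t.strand if xs_on else None
    recs = [
        _Rec(qname, f1, b1[0][0], b1, j1, b2[0][0],
             hi - lo if not r1_rev else lo - hi, umi,
             xs if j1 else None, cell),
        _Rec(qname, f2, b2[0][0], b2, j2, b1[0][0],
             lo - hi if not r1_rev else hi - lo, umi,
             xs if j2 else None, cell),
    ]
    return recs


def _single_record(qname, pos, length, rev, cell) -> _Rec:
    return _Rec(qname, 0x10 if rev else 0, pos, ((pos, pos + length),), (),
                cell=cell)


# ---------------------------------------------------------------------------
# per-cell read generation
# ---------------------------------------------------------------------------

def _sample_flen(rng, cfg: SimConfig, upper: int) -> int:
    flen = int(round(rng.normal(cfg.fragment_length_mean,
                                cfg.fragment_length_sd)))
    flen = max(cfg.fragment_length_range[0],
               min(cfg.fragment_length_range[1], flen))
    return min(flen, upper)


def _base_fragments_for_transcript(cfg, cell_idx, gi, ti, t, cell,
                                   records, rows, junction_support):
    rng = _rng(cfg.seed, 2, cell_idx, gi, ti)
    expressed = rng.random() < cfg.expressed_fraction
    if not expressed:
        return
    L = t.length
    n = cfg.fragments_per_transcript
    n_umi = max(cfg.guaranteed_first_exon_umi,
                int(round(n * cfg.umi_fraction)))
    n_int = max(n - n_umi, 2)
    withheld = t.transcript_id in cfg.withhold_first_exon_umi
    first_exon_len = (t.exons[0][1] - t.exons[0][0] if t.strand == "+"
                      else t.exons[-1][1] - t.exons[-1][0])

    made = []
    for u in range(n_umi):
        flen = _sample_flen(rng, cfg, L)
        if u < cfg.guaranteed_first_exon_umi:
            off = 0
        else:
            off = min(int(rng.geometric(cfg.umi_5prime_bias)) - 1, L - flen)
        fr = rng.random() < cfg.umi_fr_fraction
        umi = "".join(rng.choice(list("ACGT"), size=8)) + f"{u:02d}"
        if withheld and off < first_exon_len:
            continue  # the held-out 5'-exon UMI evidence
        made.append((f"{cell}:{t.transcript_id}:u{u}", off, flen, fr, umi))
    grid = np.linspace(0, max(L - cfg.fragment_length_range[0], 0),
                       num=n_int)
    for i in range(n_int):
        flen = _sample_flen(rng, cfg, L)
        jit = int(rng.integers(-10, 11)) if 0 < i < n_int - 1 else 0
        p = int(round(grid[i])) + jit
        p = max(0, min(p, L - flen))
        fr = rng.random() < cfg.internal_fr_fraction
        made.append((f"{cell}:{t.transcript_id}:i{i}", p, flen, fr, None))

    dup_rng = _rng(cfg.seed, 7, cell_idx, gi, ti)
    for qname, p, flen, fr, umi in made:
        recs = _pair_records(qname, t, p, flen, cfg.read_length, fr, umi,
                             cell, cfg.write_xs_tags)
        records.extend(recs)
        for j in set(j for r in recs for j in r.junctions):
            junction_support[j] += 1
        cat = "umi" if umi else "internal"
        rows.append((cell, qname, cat, t.transcript_id, t.chrom,
                     min(r.pos for r in recs),
                     max(r.blocks[-1][1] for r in recs),
                     t.strand, "FR" if fr else "RF"))
        if dup_rng.random() < cfg.pcr_duplicate_rate:
            records.extend(replace(r, qname=qname + ":dup") for r in recs)
            rows.append((cell, qname + ":dup", "duplicate", t.transcript_id,
                         t.chrom, min(r.pos for r in recs),
                         max(r.blocks[-1][1] for r in recs),
                         t.strand, "FR" if fr else "RF"))


def _common_introns(isoforms: list[TruthTranscript]) -> list[tuple[int, int]]:
    """Maximal intervals intronic in *every* isoform of the locus."""
    exonic = sorted(e for t in isoforms for e in t.exons)
    merged: list[list[int]] = []
    for a, b in exonic:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(x[1], y[0]) for x, y in zip(merged, merged[1:])]


def _inject_full_ir(cfg, cell_idx, gi, isoforms, cell, records, rows,
                    junction_support):
    rng = _rng(cfg.seed, 4, cell_idx, gi)
    if rng.random() >= cfg.full_ir_injection_rate:
        return
    chrom = isoforms[0].chrom
    # a retained intron must coincide with a real junction and be intronic
    # in every isoform, so its vertex sits between the two flanking exons
    commons = set(_common_introns(isoforms))
    cands = sorted({j for t in isoforms for j in t.introns if j in commons
                    and junction_support[j] >= 4 and j[1] - j[0] >= 150})
    if not cands:
        return
    js, je = cands[int(rng.integers(len(cands)))]
    k = max(1, int(cfg.ir_relative_support * junction_support[(js, je)]))
    k = min(k, int(0.25 * junction_support[(js, je)]))
    if k < 1:
        return
    n = 0
    for jrep in range(k):  # staggered bridges over both intron boundaries
        records.append(_single_record(f"{cell}:G{gi:04d}:fir{n}",
                                      js - 30 - 7 * jrep, 120,
                                      bool(rng.integers(2)), cell))
        rows.append((cell, records[-1].qname, "full_ir", "", chrom,
                     records[-1].pos, records[-1].pos + 120, ".", "."))
        n += 1
        records.append(_single_record(f"{cell}:G{gi:04d}:fir{n}",
                                      je - 90 + 7 * jrep, 120,
                                      bool(rng.integers(2)), cell))
        rows.append((cell, records[-1].qname, "full_ir", "", chrom,
                     records[-1].pos, records[-1].pos + 120, ".", "."))
        n += 1
    pos = js + 30
    while pos + 120 < je - 30:  # contiguous interior tiling
        records.append(_single_record(f"{cell}:G{gi:04d}:fir{n}", pos, 120,
                                      bool(rng.integers(2)), cell))
        rows.append((cell, records[-1].qname, "full_ir", "", chrom,
                     pos, pos + 120, ".", "."))
        n += 1
        pos += 60


def _inject_partial_ir(cfg, cell_idx, gi, isoforms, cell, records, rows,
                       junction_support):
    rng = _rng(cfg.seed, 5, cell_idx, gi)
    if rng.random() >= cfg.partial_ir_injection_rate:
        return
    chrom = isoforms[0].chrom
    commons = _common_introns(isoforms)
    cands = []
    for lo, hi in commons:
        if hi - lo < 200:
            continue
        # calibrate against the heaviest single in-edge of the acceptor exon
        acc = max((n for (js, je), n in junction_support.items() if je == hi),
                  default=0)
        if acc >= 5:
            cands.append((lo, hi, acc))
    if not cands:
        return
    lo, hi, acc = cands[int(rng.integers(len(cands)))]
    k = max(1, int(0.15 * acc))
    k = min(k, int(0.2 * acc), 10)
    if k < 1:
        return
    for jrep in range(k):  # cover only the tail of the intron, bridging out
        pos = hi - 80 + 7 * jrep
        records.append(_single_record(f"{cell}:G{gi:04d}:pir{jrep}", pos, 120,
                                      bool(rng.integers(2)), cell))
        rows.append((cell, records[-1].qname, "partial_ir", "", chrom,
                     pos, pos + 120, ".", "."))


def _inject_intronic(cfg, cell_idx, gi, isoforms, cell, n_base, records, rows):
    rng = _rng(cfg.seed, 3, cell_idx, gi)
    commons = [iv for iv in _common_introns(isoforms) if iv[1] - iv[0] >= 160]
    n = int(round(cfg.intronic_contamination_rate * n_base))
    if not commons or n == 0:
        return
    chrom = isoforms[0].chrom
    for i in range(n):
        lo, hi = commons[int(rng.integers(len(commons)))]
        length = 100
        pos = int(rng.integers(lo + 20, hi - 20 - length))
        records.append(_single_record(f"{cell}:G{gi:04d}:ic{i}", pos, length,
                                      bool(rng.integers(2)), cell))
        rows.append((cell, records[-1].qname, "intronic", "", chrom,
                     pos, pos + length, ".", "."))


def _inject_intergenic(cfg, cell_idx, loci_spans, cell, records, rows):
    rng = _rng(cfg.seed, 6, cell_idx)
    n = int(round(cfg.intergenic_contamination_rate
                  * cfg.fragments_per_transcript))
    gaps = [(a[1] + 500, b[0] - 500)
            for a, b in zip(loci_spans, loci_spans[1:])
            if b[0] - a[1] > 1200]
    if not gaps or n == 0:
        return
    for i in range(n):
        lo, hi = gaps[int(rng.integers(len(gaps)))]
        pos = int(rng.integers(lo, hi - 100))
        records.append(_single_record(f"{cell}:ig{i}", pos, 100,
                                      bool(rng.integers(2)), cell))
        rows.append((cell, records[-1].qname, "intergenic", "", cfg.chrom,
                     pos, pos + 100, ".", "."))


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimConfig, outdir: str | os.PathLike
                     ) -> SimulatedDataset:
    """Write genome FASTA, truth GTF/TSV and one SAM per cell under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = _make_structures(cfg)
    genome = _make_genome(cfg, truth)

    genome_path = outdir / "genome.fa"
    with open(genome_path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")

    truth_gtf = outdir / "truth.gtf"
    write_gtf([Transcript(chrom=t.chrom, strand=t.strand, exons=t.exons,
                          transcript_id=t.transcript_id, gene_id=t.gene_id,
                          source="truth")
               for t in truth], truth_gtf, source="truthsim")

    by_gene: dict[str, list[TruthTranscript]] = {}
    for t in truth:
        by_gene.setdefault(t.gene_id, []).append(t)
    genes = sorted(by_gene)
    loci_spans = [(min(t.exons[0][0] for t in by_gene[g]),
                   max(t.exons[-1][1] for t in by_gene[g])) for g in genes]

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.items()]}
    sam_paths: dict[str, Path] = {}
    all_rows: list[tuple] = []
    for cell_idx in range(cfg.n_cells):
        cell = f"CELL{cell_idx:02d}"
        records: list[_Rec] = []
        rows: list[tuple] = []
        for gi, gene in enumerate(genes):
            isoforms = by_gene[gene]
            junction_support: Counter = Counter()
            n_before = len(records)
            for ti, t in enumerate(isoforms):
                _base_fragments_for_transcript(cfg, cell_idx, gi, ti, t, cell,
                                               records, rows, junction_support)
            n_base = (len(records) - n_before) // 2
            _inject_intronic(cfg, cell_idx, gi, isoforms, cell, n_base,
                             records, rows)
            _inject_full_ir(cfg, cell_idx, gi, isoforms, cell, records, rows,
                            junction_support)
            _inject_partial_ir(cfg, cell_idx, gi, isoforms, cell, records,
                               rows, junction_support)
        _inject_intergenic(cfg, cell_idx, loci_spans, cell, records, rows)

        path = outdir / f"{cell}.sam"
        _write_sam(path, header, records, genome, cfg.chrom)
        sam_paths[cell] = path
        all_rows.extend(rows)

    table = pd.DataFrame(all_rows, columns=[
        "cell", "qname", "category", "transcript_id", "chrom", "start",
        "end", "strand", "orientation"])
    table_path = outdir / "truth_fragments.tsv"
    table.to_csv(table_path, sep="\t", index=False)
    return SimulatedDataset(cfg, genome, truth, genome_path, truth_gtf,
                            table, table_path, sam_paths)


def _write_sam(path, header, records: list[_Rec], genome, chrom) -> None:
    records = sorted(records, key=lambda r: (r.pos, r.qname, r.flag))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.qname
            a.flag = r.flag
            a.reference_id = 0
            a.reference_start = r.pos
            a.mapping_quality = 60
            a.cigartuples = _cigar(r.blocks)
            a.query_sequence = _seq(genome, chrom, r.blocks)
            if r.flag & 0x1:
                a.next_reference_id = 0
                a.next_reference_start = r.mate_pos
                a.template_length = r.tlen
            tags = [("BC", r.cell)]
            if r.umi:
                tags.append(("UB", r.umi))
            if r.xs:
                tags.append(("XS", r.xs))
            a.set_tags(tags)
            out.write(a)


# ---------------------------------------------------------------------------
# splice-graph fixtures
# ---------------------------------------------------------------------------

class GraphFixtureError(ValueError):
    """Malformed textual graph description; message carries the line number."""


def make_graph_fixture(text: str) -> SpliceGraph:
    """Parse a splice graph from its plain-text description.

    Format (one directive per line, ``#`` comments): a ``graph CHROM STRAND``
    header, then ``vertex NAME START END wv=F wm=N`` lines in coordinate
    order, then ``edge U V WEIGHT`` lines where U/V are vertex names or the
    reserved ``s``/``t``. Vertex names are preserved in ``graph.labels``.
    """
    g: SpliceGraph | None = None
    ids: dict[str, int] = {SOURCE: SOURCE, SINK: SINK}
    nxt = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        try:
            if parts[0] == "graph":
                g = SpliceGraph(parts[1], parts[2])
            elif parts[0] == "vertex":
                if g is None:
                    raise GraphFixtureError(f"line {lineno}: vertex before graph")
                name, start, end = parts[1], int(parts[2]), int(parts[3])
                kw = dict(kv.split("=", 1) for kv in parts[4:])
                ids[name] = nxt
                g.add_vertex(nxt, start, end, wv=float(kw.get("wv", 0)),
                             wm=int(kw.get("wm", 0)), label=name)
                nxt += 1
            elif parts[0] == "edge":
                if g is None:
                    raise GraphFixtureError(f"line {lineno}: edge before graph")
                g.add_edge(ids[parts[1]], ids[parts[2]], float(parts[3]))
            else:
                raise GraphFixtureError(
                    f"line {lineno}: unknown directive {parts[0]!r}")
        except (IndexError, KeyError, ValueError) as exc:
            if isinstance(exc, GraphFixtureError):
                raise
            raise GraphFixtureError(f"line {lineno}: {raw!r}: {exc}") from exc
    if g is None or g.n_vertices == 0:
        raise GraphFixtureError("empty graph description")
    g.validate()
    return g


#: Worked pruning example: a locus whose graph contains a full intron
#: retention (v3, between v2 and v4, skipped by a heavy junction), a partial
#: intron retention masquerading as an alternative first exon (v5, abutting
#: v6 which is also reached by a real junction), and an isolated intronic
#: pile (v7). Default thresholds remove exactly {v3, v5, v7}; v1 is the true
#: first exon, well supported by UMI fragments.
PRUNING_DEMO = """\
graph chrDemo +
vertex v1 100 200   wv=9.0  wm=6
vertex v2 300 400   wv=10.5 wm=4
vertex v3 400 700   wv=1.5  wm=0
vertex v4 700 800   wv=11.0 wm=3
vertex v5 900 1000  wv=2.0  wm=0
vertex v6 1000 1100 wv=9.5  wm=2
vertex v7 1200 1300 wv=6.0  wm=0
vertex v8 1400 1500 wv=8.0  wm=1
edge s v1 6
edge s v5 2
edge s v7 3
edge v1 v2 10
edge v2 v3 2
edge v3 v4 2
edge v2 v4 20
edge v4 v6 15
edge v5 v6 2
edge v6 v8 12
edge v7 t 3
edge v8 t 9
"""


def random_splice_graph(rng: np.random.Generator,
                        max_vertices: int = 12) -> SpliceGraph:
    """A random structurally valid splice graph for pruning-rule tests."""
    n = int(rng.integers(2, max_vertices + 1))
    g = SpliceGraph("chrR", "+" if rng.random() < 0.5 else "-")
    pos = int(rng.integers(0, 1000))
    for vid in range(n):
        if vid and rng.random() < 0.5:
            pos += int(rng.integers(5, 200))  # gapped neighbour
        length = int(rng.integers(20, 300))
        g.add_vertex(vid, pos, pos + length,
                     wv=float(np.round(rng.uniform(0.2, 30.0), 3)),
                     wm=int(rng.choice([0, 0, 0, 1, 2, 5])))
        pos += length
    for i in range(n):
        for j in range(i + 1, n):
            d = j - i
            p = 0.65 if d == 1 else (0.3 if d == 2 else 0.08)
            if rng.random() < p:
                g.add_edge(i, j, int(rng.integers(1, 30)))
    for vid in range(n):
        if not any(u for u in g.in_neighbors(vid)):
            g.add_edge(SOURCE, vid, int(rng.integers(1, 10)))
        if not any(u for u in g.out_neighbors(vid)):
            g.add_edge(vid, SINK, int(rng.integers(1, 10)))
    return g
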