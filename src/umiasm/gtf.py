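"""GTF and side-file I/O with exact coordinate conventions.

Internally every interval is 0-based half-open; GTF is 1-based closed, so an
exon ``[100, 200)`` becomes ``start=101 end=200`` on the way out and back.
The writer emits a stable attribute order (transcript_id first, then
gene_id, the dialect gffcompare expects) and is byte-deterministic for a
fixed transcript list.
"""
from __future__ import annotations

import os
import re
from typing import Iterable, Sequence

from .assemble import Transcript
from .loci import Locus

_ATTR = re.compile(r'(\w+) +"([^"]*)"')


class GtfFormatError(ValueError):
    """A GTF record that cannot be interpreted; message carries the line number."""


def write_gtf(transcripts: Sequence[Transcript], path: str | os.PathLike,
              source: str = "umiasm") -> None:
    """Write transcript + exon features (GTF2.2, 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gtf: assembled transcripts\n")
        for n, t in enumerate(transcripts, start=1):
            tid = t.transcript_id or f"tx.{n}"
            gid = t.gene_id or tid.rsplit(".", 1)[0]
            attrs = f'transcript_id "{tid}"; gene_id "{gid}";'
            attrs += f' cov "{t.coverage:.4f}";'
            if t.cell_id is not None:
                attrs += f' cell_id "{t.cell_id}";'
            fh.write(f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}"
                     f"\t.\t{t.strand}\t.\t{attrs}\n")
            for i, (a, b) in enumerate(t.exons, start=1):
                fh.write(f"{t.chrom}\t{source}\texon\t{a + 1}\t{b}\t.\t"
                         f"{t.strand}\t.\t{attrs} exon_number \"{i}\";\n")


def read_gtf(path: str | os.PathLike) -> list[Transcript]:
    """Read exon features grouped by transcript_id into transcripts.

    Exons are sorted per transcript; coordinates convert to the internal
    half-open convention. Records lacking optional attributes are tolerated;
    an exon without transcript_id is a record-level error reporting the line.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfFormatError(f"line {lineno}: expected 9 columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = \
                fields[:9]
            if feature != "exon":
                continue
            attrs = dict(_ATTR.findall(attr))
            tid = attrs.get("transcript_id")
            if not tid:
                raise GtfFormatError(f"line {lineno}: exon lacks transcript_id")
            exons.setdefault(tid, []).append((int(start) - 1, int(end)))
            if tid not in meta:
                order.append(tid)
                meta[tid] = {
                    "chrom": chrom, "strand": strand,
                    "gene_id": attrs.get("gene_id"),
                    "cell_id": attrs.get("cell_id"),
                    "cov": float(attrs["cov"]) if "cov" in attrs else 0.0,
                }
    out = []
    for tid in order:
        m = meta[tid]
        out.append(Transcript(
            chrom=m["chrom"], strand=m["strand"],
            exons=tuple(sorted(exons[tid])), coverage=m["cov"],
            cell_id=m["cell_id"], transcript_id=tid, gene_id=m["gene_id"]))
    return out


def write_purged_bed(loci: Iterable[Locus], path: str | os.PathLike) -> None:
    """BED audit file of purged loci: span, strand and read-type counts."""
    with open(path, "w") as fh:
        for locus in loci:
            name = f"umi={locus.umi_count};internal={locus.internal_count}"
            fh.write(f"{locus.chrom}\t{locus.start}\t{locus.end}\t{name}\t0\t"
                     f"{locus.strand}\n")
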