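"""Intron-chain evaluation against a reference annotation.

A predicted multi-exon transcript *matches* the reference when its ordered
intron chain is identical to that of some annotated transcript on the same
chromosome and strand (start/end positions of the terminal exons are free).
Single-exon predictions are excluded from both numerator and denominator of
the multi-exon statistics. Because most annotated transcripts are silent in
any one cell, sensitivity against the whole annotation is uninformative;
instead the matching-transcript count is reported, and precision comparisons
are made at controlled sensitivity by removing predictions in ascending
coverage order until the matching count falls to a common baseline
("adjusted precision").
"""
from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence

import pandas as pd

from .assemble import Transcript

log = logging.getLogger(__name__)


def _reference_chains(reference: Iterable[Transcript]) -> set[tuple]:
    chains = set()
    for t in reference:
        if t.strand not in "+-":
            log.warning("unstranded reference transcript %s excluded",
                        t.transcript_id)
            continue
        if t.is_multi_exon:
            chains.add((t.chrom, t.strand, t.introns))
    return chains


def match_intron_chain(predicted: Transcript,
                       reference: Iterable[Transcript] | set[tuple]) -> bool:
    """True iff a multi-exon prediction's intron chain occurs in the reference."""
    if not predicted.is_multi_exon:
        return False
    chains = reference if isinstance(reference, set) \
        else _reference_chains(reference)
    return (predicted.chrom, predicted.strand, predicted.introns) in chains


def evaluate(predicted: Sequence[Transcript],
             reference: Sequence[Transcript]) -> dict:
    """Matching count and multi-exon transcript-level precision."""
    chains = _reference_chains(reference)
    multi = [t for t in predicted if t.is_multi_exon]
    n_matching = sum(1 for t in multi if match_intron_chain(t, chains))
    precision = n_matching / len(multi) if multi else 0.0
    return {
        "n_matching": n_matching,
        "n_predicted_multiexon": len(multi),
        "precision": precision,
    }


def adjusted_precision(predicted: Sequence[Transcript],
                       reference: Sequence[Transcript],
                       baseline_matching: int) -> float:
    """Precision after trimming sensitivity down to a common baseline.

    Multi-exon predictions are removed one at a time in ascending coverage
    (ties broken by coordinate) until the matching count equals
    ``baseline_matching``. If the set already matches fewer than the baseline
    the unadjusted precision is returned with a warning.
    """
    chains = _reference_chains(reference)
    multi = sorted((t for t in predicted if t.is_multi_exon),
                   key=lambda t: (t.coverage, t.chrom, t.start, t.end,
                                  t.transcript_id or ""))
    labels = [match_intron_chain(t, chains) for t in multi]
    n_matching = sum(labels)
    if baseline_matching > n_matching:
        log.warning("baseline %d above current matching count %d; "
                    "returning unadjusted precision",
                    baseline_matching, n_matching)
        return n_matching / len(multi) if multi else 0.0
    i = 0
    while n_matching > baseline_matching:
        n_matching -= labels[i]
        i += 1
    survivors = len(multi) - i
    return n_matching / survivors if survivors else 0.0


def metrics_table(per_cell: dict[str, Sequence[Transcript]],
                  reference: Sequence[Transcript],
                  path: str | os.PathLike | None = None) -> pd.DataFrame:
    """Per-cell metrics table; written as TSV when ``path`` is given."""
    rows = []
    for cell in sorted(per_cell):
        res = evaluate(per_cell[cell], reference)
        rows.append({"cell": cell, **res})
    df = pd.DataFrame(rows,
                      columns=["cell", "n_matching", "n_predicted_multiexon",
                               "precision"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
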