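# Methods

## Model and assumptions

`umiasm` assembles transcripts from spliced alignments of one cell at a
time, assuming a Smart-seq3-like library design: a minority of fragments
carry a UMI ligated at the RNA 5' end (BAM `UB` tag) and are FR
strand-specific with a strong transcript-start bias, while the majority are
internal fragments with bulk-like body coverage, no strand specificity, and
elevated intronic noise. Three consequences drive the design:

1. UMI presence is a reliable read-type label, so the two populations can be
   modelled separately from a single BAM.
2. Strand and locus identity of junction-free internal reads are not
   observable directly but can be borrowed from UMI-supported loci nearby.
3. Transcript start sites are observable: a real transcript's 5'-terminal
   exon accumulates UMI fragments; contaminant paths do not.

Coordinates are 0-based half-open everywhere internally; GTF conversion
(1-based closed) happens only at the I/O boundary.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `min_mapq` | 1 | MAPQ floor; unmapped/secondary/supplementary always dropped |
| `LocusFilterParams.cluster_gap` | 50 bp | max gap between fragment spans within one locus |
| `LocusFilterParams.nearby_window` | 100 bp | recruitment range for unknown-strand internal fragments |
| `LocusFilterParams.min_umi_count` | 2 | UMI fragments below which a locus is purged |
| `LocusFilterParams.min_umi_ratio` | 0.05 | UMI fraction below which a locus is purged |
| `IRParams.a1..a3` | 0.25 | full-IR: vertex/edge weight relative to the skipping edge |
| `IRParams.a4` | 1 | full-IR: max UMI support of a removable vertex |
| `IRParams.a5` | 5.0 | lariat rule: vertex coverage vs. flanking edge weight |
| `IRParams.b1, b2` | 0.2 | partial-IR: weight relative to the heaviest competing edge |
| `IRParams.b3` | 1 | partial-IR: max UMI support |
| `IRParams.single_exon_min_umi` | 2 | UMI support an isolated vertex needs to survive |
| `AssemblyParams.first_exon_min_umi` | 1 | UMI fragments required on the 5'-terminal exon |
| `AssemblyParams.min_transcript_coverage` | 1.0 | abundance floor (0 disables) |
| `AssemblyParams.min_transcript_length` | 150 bp | exonic-length floor (0 disables) |
| `meta assign_frac` | 0.30 | exon fraction a cell must support to receive a pooled transcript |

The a/b pruning thresholds are deliberately exposed as configuration: the
defaults above follow the spirit of the rules (a retained intron is one
whose support is a small fraction of the skipping evidence) and every value
is overridable from the CLI config file. `min_transcript_coverage` and
`min_transcript_length` are reporting floors, not part of the model.

## Design choices where the design was open

**Source/sink attachment.** The source is connected to every vertex with no
other in-edge and the sink to every vertex with no other out-edge. A more
permissive rule (attach `s` wherever fragments start) sounds natural but
would mark every retained-intron vertex as a transcript start — contaminant
fragments always start inside the intron — and thereby disable the full-IR
rule's "not adjacent to s/t" condition. With the minimal rule every vertex
still lies on an s–t path, and all three pruning rules stay meaningful.

**In-edge counting for partial-IR.** The competing-evidence count and the
reference weight `w'` for a partial retention are taken over real
(non-source/sink) edges only; source/sink edges are bookkeeping, not read
evidence. The end-side case is the exact mirror.

**Pass semantics of pruning.** Within one pass all candidates are judged
against the pass-start graph and removed together; passes repeat to a fixed
point. This makes removal order-independent, which random-graph tests
verify against brute-force evaluators of the inequalities.

**Phase-preserving decomposition.** Decomposition seeds a chain with the
highest-multiplicity phasing path not yet contained in any reported path,
then extends it vertex-by-vertex toward source and sink. At each step the
phasing paths overlapping the chain end vote for the neighbour (total
fragment multiplicity; ties by edge weight, then genomic coordinate), so
the chain follows molecules rather than the globally heaviest route — the
property that prevents chimeric joins at shared exons. Extension continues
past a source-adjacent vertex while compatible phasing evidence extends
further 5'. Abundance is assigned after all chains are selected: each
edge's fragment weight is split evenly among the chains that traverse it
and a chain's abundance is the minimum of its shares. Splitting (rather
than sequential subtraction of bottlenecks) keeps isoforms that share
junctions from starving each other; the total abundance through any
terminal edge never exceeds its weight. A single-vertex chain's abundance
is the count of fragments starting at that vertex. This is a deterministic
heuristic chosen for the package; the decomposition sits behind a narrow
interface (`decompose_graph`) so an alternative algorithm can be swapped in.

**Mate insert gaps.** Blocks of a merged pair separated by an unsequenced
insert do not constrain phasing across the gap: the fragment contributes
one phasing path per contiguously sequenced stretch. Junction-linked blocks
phase through the junction.

**Dedup scope.** Duplicates are collapsed per cell across both read types
(the key — positions plus CIGARs — ignores the UMI), and never across
cells: identical molecules in two cells are biological signal, which the
meta mode preserves by deduplicating before pooling.

**Union key.** A cell's meta assembly is keyed by intron chain (multi-exon)
or exon interval (single-exon); on a collision the single-cell record wins
because its coverage was estimated from the cell's own reads. Exon-support
assignment counts exons by default; a `by_bases` switch measures exonic
bases instead for users who prefer a length-weighted notion of "amount of
exons".

## The synthetic data generator

`umiasm.simulate` fabricates the study conditions rather than downloading
data: a random genome with canonical GT..AG motifs written at every truth
junction, 1–3 isoforms per locus differing at a single alternative-splicing
event (exon skipping, mutually exclusive exons placed disjointly in the
same window, or an alternative terminal exon), and per-cell paired-end
alignments with:

* `umi_fraction = 0.25` of fragments UMI-tagged (the observed Smart-seq3
  share), starts decaying geometrically from the TSS
  (`umi_5prime_bias = 0.02`, mean offset ≈ 50 bp), ≥ 2 fragments pinned at
  each TSS;
* UMI FR fraction 0.85 and internal FR fraction 0.50, reproducing the
  strandness disparity;
* internal fragments laid on a jittered grid over the transcript body, so
  coverage is gap-free and every junction is spanned (the "even gene-body
  coverage" idealised deterministically);
* fragment length ~N(170, 15) clipped to [130, 195] at 2×100 bp reads, so
  mates overlap and every sequenced base of a fragment is observed;
* optional contamination layers, each on its own seed stream so enabling
  one leaves every other record byte-identical: intronic piles, intergenic
  fragments, PCR duplicates, and full/partial intron-retention support
  whose bridging depth is calibrated to a fixed fraction (0.2 / 0.15) of
  the local splice support so the injected vertices satisfy the default
  pruning inequalities.

What passing on this generator shows: the graph construction, pruning,
decomposition, anchoring and meta logic are correct under the stated read
model. What it does not show: performance under alignment artifacts
(soft-clip noise, multimappers, junction errors), non-canonical splice
sites, expression-level skew, or 3'-biased protocols — real-data behaviour
is expected to be weaker than the clean-synthetic 100%/1.0 figures, which
are a correctness bound, not a benchmark claim.

## Numerical and degenerate-input choices

* Dedup keeps the first fragment in coordinate order; ties in decomposition
  break by multiplicity, then edge weight, then genomic coordinate — all
  runs are byte-deterministic.
* Empty cell → empty transcript list; a locus whose graph loses every
  vertex to pruning emits nothing; a graph with vertices but no phasing
  support logs a warning and emits nothing.
* `adjusted_precision` with an unreachable baseline returns the unadjusted
  value with a warning rather than failing.
* Unstranded reference transcripts are excluded from evaluation with a
  warning; single-exon predictions are excluded from multi-exon matching
  statistics on both sides of the ratio.
* Problem sizes used by the test-suite and acceptance script — 50-locus
  single cells, a 5-cell meta dataset, 1000 random graphs of ≤ 12 vertices —
  were chosen as the smallest sizes at which every code path (all three
  pruning rules, multi-isoform loci, both strands, recruitment, meta
  assignment) is exercised repeatedly.

## Known limitations

* The decomposition is a greedy heuristic; loci where isoforms diverge on
  both sides of a shared exon longer than the fragment span are genuinely
  ambiguous at the fragment level and may decompose into a plausible but
  wrong chain combination.
* Transcript 5'/3' ends are taken from coverage boundaries; no TSS/TES
  peak modelling beyond the UMI anchor is attempted.
* UMI sequences are taken verbatim (no error-aware UMI collapsing), and no
  use is made of UMI identity beyond read-type classification.
* Strand inference for unspliced UMI fragments trusts read-1 orientation;
  consistently RF-oriented libraries would need a configuration switch.
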