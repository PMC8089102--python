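# Methods

This note documents the models and procedures `superbiv` implements, the
defaults and why they were chosen, what the synthetic data does and does not
emulate, and the numerical conventions that keep runs reproducible.

## Coordinate and counting conventions

All coordinates are 0-based half-open, in memory and on disk; GTF input
(1-based closed) is converted on read, and the TSS of a minus-strand gene is
its end − 1. A read belongs to a window iff its integer midpoint
((start + end) // 2) lies in the half-open span. The midpoint rule makes a
genome tiling a *partition* of the library — bin counts sum exactly to the
number of mapped reads — and is insensitive to read length for the
fragment-scale intervals ChIP-seq produces. Promoter windows are clipped at
chromosome ends and RPKM uses the clipped length, so boundary genes are not
inflated. Library size is the total number of supplied reads, which are
assumed already deduplicated and uniquely mapped; there is no input
subtraction, spike-in scaling, or pseudocount — a zero count is a zero RPKM,
and downstream z-scoring handles spread.

## Super-bivalency calling

Per sample:

1. **H3K4me3 promoter enrichment** — RPKM in the 10-kb TSS-centred window.
   "10-kb promoter" is interpreted as TSS ± 5 kb (configurable); an
   asymmetric split would change little because the simulated and typical
   real domains are TSS-centred.
2. **Z-scoring** — (x − mean)/SD with the *population* SD, computed across
   **all annotated genes**, not only bivalent ones. The housekeeping
   baseline must live on the same scale as every candidate gene, which an
   all-gene standardisation guarantees. A constant vector yields all-zero
   z-scores with a warning rather than an error.
3. **Housekeeping baseline** — the arithmetic mean z of a curated
   housekeeping list. Missing IDs are an error (a silently shrunken baseline
   would bias every call).
4. **Bivalent universe** — either an externally supplied list (when
   replicating an existing bivalent catalogue) intersected with the
   annotation, or genes with H3K4me3 ≥ 1 and H3K27me3 ≥ 1 RPKM in the
   ±2.5-kb promoter. Both paths are logged and recorded in the manifest.
5. **Super-bivalent set** — bivalent genes with z strictly above the
   housekeeping baseline *and* H3K27me3 10-kb promoter RPKM strictly above
   1.0. Strict inequalities mean ties are excluded; the H3K27me3 cutoff is
   plain RPKM, not z-scored. Monotonicity follows from the construction:
   adding H3K4me3 reads to a gene's promoter (others fixed) can only raise
   its raw value relative to the housekeeping mean, and raising the
   H3K27me3 cutoff can only shrink the set.

Overlap between two samples' sets is reported as n_shared and
round(100·n_shared/n_A); an empty reference set leaves the percentage
undefined rather than zero.

## Breadth profiles

Meta-gene profiles bin read midpoints into 100-bp bins over the 10-kb TSS
window, reverse minus-strand genes so downstream is always rightward,
average per-bin counts over the gene set, convert to RPKM and divide by the
housekeeping mean 10-kb promoter RPKM. Averaging that profile over its
window algebraically reproduces the set's mean window RPKM over the
housekeeping mean, so the housekeeping set self-normalises to exactly 1 —
a built-in calibration check. Breadth is summarised as the width of the
span at or above half the profile maximum. Genes whose full window falls
off the chromosome are dropped with a warning rather than padded.

## Methylome comparison

Bin methylation is Σmeth/Σtotal over the CpGs in each 10-kb bin — a
coverage-weighted mean, invariant to splitting a CpG's counts across
records. Bins with summed coverage below `min_coverage` (default 3, the
conventional floor for calling a bin at all; configurable) are missing.
Sample similarity uses pairwise-complete bins. Clustering uses uncentred
correlation (no mean removal: two samples differing by a constant
methylation offset are *not* identical, unlike under Pearson) with average
linkage on 1 − s; average linkage is reducible, so merge heights are
monotone. Samples are sorted lexicographically before linkage, making the
tree invariant to input order and ties deterministic. Histone bin-RPKM
matrices reuse the same functions. The scatter-plot statistic between
methylomes is ordinary Pearson r on shared bins, with the bin count
reported alongside.

## Tripartite expression classifier

Over exactly three groups, a gene is assigned to group g iff its group-mean
FPKM is ≥ `fc_min` (1.5) times the mean of each other group and ≥
`fpkm_min` (3.0). Group *means* over replicates are the comparison unit (a
per-replicate requirement would conflate replicate noise with the effect
size the thresholds encode). A fold change against a zero mean is +∞, so
division never fails and an expressed gene trivially beats a silent one.
For fc_min > 1 at most one group can win, so the output is a partition into
three specific sets plus "none". Counts are monotone non-increasing in both
thresholds. Significance testing (negative-binomial DE) is deliberately out
of scope: the fixed-threshold rule *is* the classifier implemented, and it
is exact on noiseless input. 2^−ΔCt is provided for qPCR cross-checks.

## Synthetic data: what it emulates, and what it does not

The generator plants the regimes the classifier is built to separate:

| class | H3K4me3 | H3K27me3 | methylation at promoter |
|---|---|---|---|
| housekeeping | narrow (2 kb), 2000 reads/kb | — | global |
| active | narrow (2 kb), 2000 reads/kb | — | global |
| bivalent | narrow (2 kb), 800 reads/kb | broad (8 kb), 1000 reads/kb | valley |
| super_bivalent | broad (8 kb), 2000 reads/kb | broad (8 kb), 1000 reads/kb | valley |
| silent | — | broad (8 kb), 1000 reads/kb | global |

Defaults: 220 genes (50/60/30/40/40 per class above) on one 12-Mb
chromosome at 50-kb spacing with alternating strands; 50-bp reads; uniform
background at 0.05 reads/kb; per-gene read counts Poisson(depth ×
domain-kb) placed uniformly over TSS-centred domains; CpGs every 100 bp at
coverage 20 with Binomial(20, p) methylation, p = 0.8 globally and 0.1 in
10-kb valleys over developmental (bivalent + super-bivalent) promoters;
FPKM log-normal (mean-parameterised: σ² = ln(1+CV²), μ = ln m − σ²/2) with
CV 0.2 around class/group means of 9 (own group) vs 3, and 5 for a flat
class.

Three defaults deserve their rationale spelled out:

- **A separate bivalent H3K4me3 depth (800 vs 2000 reads/kb).** Bivalent
  promoters must sit *below* the housekeeping average on the z scale and
  super-bivalent ones above it — that contrast is the phenomenon. Equal
  narrow-domain depths would put bivalent and housekeeping promoters on the
  same distribution and make the baseline comparison a coin flip, which
  corresponds to no real chromatin state.
- **Broad (8 kb) vs narrow (2 kb) domains at equal depth.** This makes
  super-bivalent promoters both broader at half-maximum (8 kb vs 2 kb) and
  ~4× stronger in the 10-kb window than housekeeping ones, reproducing the
  breadth-plus-strength signature without modelling nucleosome-level peak
  shapes — which the RPKM/breadth statistics never see.
- **Depths sized so each mark's library is ≈ 1 M reads.** The RPKM ≥ 1 and
  RPKM > 1 thresholds are only meaningful when a single background read in
  a 5-kb window is worth much less than 1 RPKM, as in real multi-million-
  read libraries; per-read RPKM scales as 1/(library millions), so a toy
  library of a few tens of thousands of reads would let lone background
  reads cross the cutoffs. One million reads on 12 Mb keeps background
  around 0.25 RPKM with an integer count threshold of ~5 — the same regime
  as 10–20 M reads on a mammalian genome.

Not emulated: sequence content (no FASTA/FASTQ), mappability and GC bias,
nucleosome positioning and peak shape, replicate-level biological
variability in chromatin, chromosome-scale heterogeneity (one chromosome by
default), scRNA-seq. Consequently, passing the planted-recovery suite shows
the *procedure* is implemented correctly and separates the encoded regimes
at realistic signal-to-background; it does not show that real libraries of
a given depth would achieve those precision/recall values, since real data
add the biases above.

## Determinism and numerics

Every stochastic step draws from `numpy` Generators seeded through a
`SeedSequence` keyed by the run seed plus CRC-32 of string tags (component,
mark, sample), so streams are independent and stable across runs and
platforms. TSV floats are written with a fixed `%.6g` format and manifests
with sorted keys, making whole-run outputs byte-identical under a repeated
seed — asserted by a test. Degenerate inputs are handled explicitly:
constant vectors z-score to zero with a warning, empty read sets give
all-zero enrichment columns, bins without coverage are missing rather than
zero (zero methylation is data; absence is not), and fewer than three
shared bins is an error for correlation.

## Problem sizes used in validation

The validation suites run the generator at its default conditions (220
genes, ~1 M reads per mark, 1200 bins): 20 replicates for the
bivalency-recovery scores, 20 seeds for the methylome pairing rate, single
replicates for profile diagnostics, and a reduced 44-gene / 2.5-Mb
configuration for orchestration and byte-identity checks, where only
structure, not statistics, is under test.

## Known limitations

- The bivalent-universe thresholds (1 RPKM each mark in ±2.5 kb) are
  sensible for ~1 M-read scaled or ~10–20 M-read real libraries but are not
  depth-adaptive; very shallow libraries need a fixed external bivalent
  list instead (supported via `fixed_set`).
- The housekeeping baseline is a plain mean; a single aberrant housekeeping
  gene shifts it. Curate the list rather than relying on robustness.
- Uncentred correlation is computed pairwise-complete, so different sample
  pairs may use different bin sets when missingness is uneven.
- No DMV segmentation, peak calling, input correction, or DE significance
  testing; these are adjacent analyses, not part of this pipeline.
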