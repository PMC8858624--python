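# Methods

## Data model

Single-cell data live in a gene × cell `ExpressionMatrix` with an explicit
layer tag: the raw layer holds non-negative integer counts, the normalized
layer holds `ln(1 + 10⁴ · count / cell_total)`.  Matrices are read and
written as 10x-style Matrix Market triplets (`matrix.mtx`, `genes.tsv`,
`barcodes.tsv`, optional `annotation.tsv` sidecar) or dense TSVs.  Bulk
cohorts are genes × samples DataFrames with per-sample metadata
(metastasis group, survival time, event flag, optional histology).

## Quality control

Cells are excluded when they express fewer than 200 unique genes, more than
5000 unique genes, or when more than 20% of their counts map to
mitochondrial genes.  All three rules are strict inequalities, so a cell
sitting exactly on a threshold is retained.  "Expressed" means count > 0.
Mitochondrial genes are identified by a configurable name prefix (default
`MT-`).  A cell failing several rules is counted once under the first
failing rule in the order low-genes → high-genes → mito, which makes the
report's removal counts sum exactly to input − retained.  QC is applied to
the combined (post-merge) matrix.

## Module scoring

`module_score` is the control-matched scheme standard in single-cell
toolkits: all genes are ranked by average expression and cut into 24
equal-frequency bins; for each set gene, 100 control genes are drawn from
its bin (without replacement when the bin is large enough, otherwise with
replacement), and a cell's score is the mean expression of the set genes
minus the mean over all drawn controls.  Control draws exclude the set
genes themselves — when a planted program dominates the top expression
bins, sampling other set genes as "controls" would absorb the very signal
being measured; if a bin holds no non-set gene, the nearest non-set genes
by average expression stand in.  Scores are computed on all genes post-QC
(not a variable-gene subset) and are reproducible under the configured
seed.  Missing set genes are dropped with a warning, not zero-imputed.

The functional scores (proliferation: MKI67, IGF1, ITGB2, PDGFC, JAG1,
PHGDH; migration: VIM, SNAI1, MMP9, AREG, ARID5B, FAT1; M1: TNF, CXCL9,
CXCL10, IL12A; M2: TGFB1, CD163, CCL18, MRC1) are plain means of
normalized expression over the listed genes; the lists ship as editable
defaults.

## Malignancy division

Each epithelial cell gets a malignant and a non-malignant module score; the
differences, sorted ascending, form the growth curve.  The threshold is
found in two steps:

1. *Inflection*: the index maximising the discrete second difference of the
   curve, after a centred moving-average smooth (window 5).  Smoothing is
   skipped for curves shorter than 25 points, where a 5-wide window spans
   a large fraction of the curve and displaces the inflection.  The
   extreme 5% of positions at each end are excluded from the search: the
   curvature there is dominated by extreme order statistics, not by the
   transition between the two classes.
2. *Gap*: within ±20% of the curve length around the inflection, the widest
   consecutive gap wins; the threshold is its midpoint.  If the window is
   flat, the search falls back to the whole curve.

Cells strictly above the threshold are malignant (a boundary cell is
non-malignant).  A fixed first-iteration threshold (the −0.02 preset of the
original analysis) can be supplied instead of gap-finding; whether that
value was fixed a priori or emerged from gap-finding is not decidable from
the source, so both modes exist.

Reference sets are then refreshed: Wilcoxon rank-sum markers of each
putative class versus the other (detection-fraction and fold-change
pre-filters as below), genes upregulated at Bonferroni-adjusted p < .01,
ranked by (adjusted p ↑, logFC ↓, gene id), top 50 per class.  Control bins
and scores are recomputed every iteration, since scores depend only on the
current sets.  Convergence is exact label equality between consecutive
iterations (the per-iteration change counts are recorded); after 20
iterations without a fixed point the state is returned with
`converged=False` rather than raising.  The classifier takes its initial
reference sets as input — planted truth programs in simulation, curated
tumour/normal marker lists in applications — keeping it agnostic to their
provenance.

## Marker detection and signatures

`wilcoxon_deg` compares one cell group against its complement per gene on
the normalized layer.  Genes are pre-filtered to
`max(pct_in, pct_out) ≥ 0.2` (the permissive max-of-groups variant) and
`|logFC| ≥ 0.2`, with `logFC = ln((mean(expm1 x_in)+1) / (mean(expm1
x_out)+1))` — the de-logged-mean convention of the Seurat-style toolchain,
isolated so it can be swapped.  The two-sided rank-sum p uses exact
enumeration when both groups have ≤10 cells and the gene is tie-free, and
the normal approximation with tie correction otherwise; an all-tied gene
gets p = 1 by convention.  Adjustment is over the genes actually tested;
Bonferroni is the default (the cited toolchain's default), Benjamini–
Hochberg is available — the original method is unstated, and the choice is
recorded in the DEG table's provenance.

A cluster is called lymph-node derived when strictly more than 90% of its
member cells carry the LN origin label.  The signature is the top 20
significant upregulated markers under the deterministic ranking (adjusted
p ↑, logFC ↓, gene id); fewer than 20 available yields all of them with a
warning.

## Bulk validation

For each covered signature gene the cohort median is computed (median of an
even count = mean of the two central order statistics, used consistently
everywhere); a sample votes +1 strictly above the median, −1 otherwise
(ties vote −1).  The per-sample sum is the signature score, so
`score + coverage` is always even and |score| ≤ coverage.

Scores are compared between LN-metastasis and non-LN samples with Welch's
t-test (the study's stated test family is the t-test; the figure caption
labelling that comparison "log-rank" is not reproducible as stated, so both
the t-test and the survival log-rank are computed and reported).  Survival
stratification splits samples at an empirical score quantile — samples at
or below the 20th percentile are "low", the rest "high"; a gene-level 25/75
split is the same operation at 0.25.  An alternative mode drops the middle
and compares bottom vs top quantile, selectable by flag, since the source's
"low (25%) and high (75%)" phrasing is ambiguous.  Kaplan–Meier curves and
the 1-df log-rank test come from lifelines, with the at-risk bookkeeping
exposed; ties at event times use the standard simultaneous-risk-set
convention.

## Synthetic data

The single-cell generator draws negative-binomial counts (dispersion θ = 2)
over log-normal gene baseline means (location −1.5, scale 1.0 on the log
scale, giving the typical low-mean heavy-tail profile) with log-normal
per-cell library factors (σ = 0.3) — the minimal generative model for
overdispersed scRNA-seq counts.  Planted structure is multiplicative: a
population or cluster over-expresses its designated gene block by
`exp(log_shift)`.  Shifted blocks are drawn from genes at or above the
median baseline expression, because a gene too lowly expressed to be
detected cannot carry a planted signal (or pass the detection-fraction
filter that defines markers).  Mitochondrial gene means are tuned to an
expected ~5% mito fraction.  Cluster origin compositions are apportioned
deterministically (largest remainder), so the >90% rule is exactly
controllable.  Everything is a pure function of config + seed.

The default end-to-end scenario: 300 malignant epithelial cells (50-gene
block, +2.5 log-units — a strong tumour program), 200 non-malignant
epithelial cells (own 50-gene block, +1.5), and three T-cell clusters of
200/200/150 cells with 20 marker genes each, one cluster 92% LN-derived
(markers +1.5).  The classifier-recovery benchmark uses the epithelial
compartment alone (500 cells, 1000 genes).

The bulk generator mirrors the validation design: 146 LN-metastasis vs 17
non-LN samples (the cohort imbalance of the original validation), Gaussian
log-expression (gene means ~N(5,1), noise SD 1), signature genes shifted +1
SD in the LN-metastasis group, and exponential survival under proportional
hazards — hazard `λ₀·exp(β·z)` with λ₀ = ln2/30 per month (median baseline
survival 30 months), β = ln 2.5 per SD of the latent signature burden, and
independent exponential censoring targeting ~30%.

What the generators do **not** emulate: batch effects, ambient RNA,
doublets, realistic cell-type proportions, gene–gene correlation beyond the
planted blocks, or non-proportional hazards.  Passing recovery tests
therefore demonstrate that the procedures are implemented correctly and
have power under their own assumptions, not that they are robust to the
artefacts of real data.

## Numerical and design notes

- Equal-frequency expression bins are contiguous chunks of the
  expression-ranked gene order, ties broken by index — deterministic for
  any input.
- The split threshold is always strictly inside the curve's range (it is a
  gap midpoint), so both classes are non-empty after every split.
- Quantile splits use the linear-interpolation empirical quantile with the
  ≤ rule, so heavy ties at the boundary are assigned deterministically.
- Degenerate inputs raise typed errors: constant growth curves, zero-total
  cells at normalization, all-equal values at stratification, <2 shared
  genes or zero-variance profiles at pseudobulk correlation.  Welch's test
  with zero variance in both groups and equal means reports p = 1.
- Gene-universe mismatches between matrices are resolved by intersection,
  with the shared-gene count reported.
- Benchmark problem sizes (500-cell classifier runs, 1000–2000 gene
  matrices, 20-seed power estimates, 200-seed null calibrations) were
  chosen as the smallest sizes at which the planted effects are
  comfortably identifiable; all complete in seconds to tens of seconds.

## Known limitations

- The classifier's threshold search assumes a two-class structure in the
  score-difference curve; strongly multi-modal curves may split off only
  the most extreme mode per iteration.
- Exact rank-sum enumeration is only used for tie-free small groups;
  heavily tied small-sample data falls back to the tie-corrected normal
  approximation.
- The ±1 scoring rule is median-anchored per cohort, so scores are not
  comparable across cohorts with different composition.
- `run_end_to_end` currently drives the synthetic generators; applying the
  pipeline to real data means calling the library components on matrices
  read with `metasig.io` (all stages accept them directly).
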