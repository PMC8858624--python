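# metasig

Tools for two linked questions in tumour single-cell transcriptomics,
modelled on the analysis of gastric-cancer primary tumours and their organ
metastases:

1. **Which epithelial cells are malignant?**  An iterative classifier
   scores every epithelial cell against a malignant and a non-malignant
   reference gene set, splits the cells on the sorted score difference, and
   refreshes the reference sets from the data until the labels stabilise.
2. **Does a metastasis-site-derived cell state predict outcome?**  A
   cluster in which >90% of cells originate from lymph nodes yields a
   20-gene marker signature, which is validated on bulk cohorts by a
   median-dichotomized ±1 score: group comparison against lymph-node
   metastasis status, and Kaplan–Meier / log-rank survival stratification.

The package is aimed at computational biologists who want these procedures
as tested, reusable components, exercised end-to-end on synthetic data with
planted ground truth (the original study's sequencing data are not public).

## The core procedures

**Malignancy division.** For cell *c* and gene set *G*, the module score is

    s(c, G) = mean_{g∈G} x_gc − mean_{g∈ctrl(G)} x_gc

where `x` is log-normalized expression `ln(1 + 10⁴·count/total)` and
`ctrl(G)` are control genes drawn from the average-expression bin of each
set gene (24 equal-frequency bins, 100 controls per gene).  The per-cell
difference `s(c, G_mal) − s(c, G_non)`, sorted ascending, forms a growth
curve; the split threshold is the midpoint of the largest consecutive gap
near the curve's inflection (maximum discrete second difference).  Cells
strictly above the threshold are malignant.  Reference sets are then
refreshed as each class's top-50 Wilcoxon rank-sum markers (adjusted
p < .01) and the loop repeats until zero labels change.

**±1 signature score.** For each signature gene, a bulk sample scores +1 if
its expression is strictly above the cohort median and −1 otherwise; the
per-sample sum over the 20 signature genes (range −20…+20) is compared
between metastasis groups (Welch t) and split at the 20th percentile for
log-rank survival analysis.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (outputs land in `results/`):

```bash
python analysis/01_simulate.py --seed 0
python analysis/02_qc_normalize.py
python analysis/03_classify_malignant.py
python analysis/04_ln_signature.py
python analysis/05_bulk_validation.py
```

which prints, for seed 0:

```
single-cell: 2000 genes x 1050 cells -> results/data/sc_counts
bulk: 2480 genes x 163 samples (146 LN-met) -> results/data
QC: 1050 cells in, 1050 retained (0 low-gene, 0 high-gene, 0 high-mito removed); median 479 genes/cell
converged=True in 2 iterations (label changes per iteration: [500, 0]); threshold -0.192; 300 malignant of 500 epithelial cells; accuracy vs planted truth 1.000
LN-derived subclusters (>90% LN): ['T0']
38 significant markers of T0; top-20 signature written to results/signature.txt; 20/20 planted markers recovered
signature coverage: 20/20 genes
group comparison: mean score 1.40 (LN-met, n=146) vs -13.18 (non-LN, n=17); Welch t = 13.47, p = 1.13e-11
survival split at the 20% score quantile (groups {'high': 123, 'low': 40}): log-rank chi2 = 20.60, p = 5.66e-06
```

Reading the output: the classifier recovered the 300 planted malignant
cells exactly and converged at the second pass; the lymph-node-derived
T-cell cluster was detected by the >90% composition rule; its extracted
20-gene signature matched the planted markers 20/20; and on the bulk cohort
the signature score was significantly higher in LN-metastasis samples and
stratified survival as planted (high-score samples carry a 2.5× hazard).

The same pipeline is available as one command (`metasig run-all --seed 0
--out results/run`) or from a config file (`metasig run-all --config
configs/demo.yaml --out results/run`); individual steps are exposed as
`metasig simulate | qc | classify-malignant | find-ln-subclusters | deg |
extract-signature | score-bulk | survival`.

## Layout

- `src/metasig/` — the library: containers and I/O (`matrix`, `io`), QC and
  normalization (`qc`, `normalize`), module scoring (`scoring`), the
  iterative classifier (`malignancy`), marker detection and signatures
  (`deg`), bulk validation (`bulk`, `survival`), generators (`simulate`),
  orchestration (`pipeline`, `cli`).
- `analysis/` — the numbered study drivers shown above.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
- `tests/` — unit, property and acceptance tests.
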