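seed: 0
outdir: null
qc:
  min_genes: 200
  max_genes: 5000
  max_mito_frac: 0.2
  mito_gene_prefix: MT-
score:
  n_bins: 24
  n_ctrl: 100
  seed: 0
division:
  top_n_refresh: 50
  alpha_refresh: 0.01
  max_iter: 20
  initial_threshold: null
  gap_window_frac: 0.2
  smooth_window: 5
  min_smooth_n: 25
  tail_trim_frac: 0.05
  adjust_method: bonferroni
deg:
  min_pct: 0.2
  logfc_threshold: 0.2
  alpha: 0.05
  adjust_method: bonferroni
  only_pos: false
  exact_max_n: 10
ln_origin: LN
ln_frac: 0.9
signature_top_n: 20
bulk_low_q: 0.2
bulk_drop_middle: false
histology_keep: null
sc_sim:
  populations:
  - name: malignant
    n_cells: 300
    shifted_gene_count: 50
    log_shift: 2.5
    lineage: epithelial
    malignant: true
    origin: PT
  - name: non_malignant
    n_cells: 200
    shifted_gene_count: 50
    log_shift: 1.5
    lineage: epithelial
    malignant: false
    origin: NT
  clusters:
  - cluster: T0
    size: 200
    origin_composition:
      LN: 0.92
      PT: 0.08
    n_marker_genes: 20
    log_shift: 1.5
    lineage: T
  - cluster: T1
    size: 200
    origin_composition:
      PT: 0.5
      Li: 0.3
      P: 0.2
    n_marker_genes: 20
    log_shift: 1.0
    lineage: T
  - cluster: T2
    size: 150
    origin_composition:
      PT: 0.4
      NT: 0.4
      O: 0.2
    n_marker_genes: 20
    log_shift: 1.0
    lineage: T
  n_genes: 2000
  baseline_loc: -1.5
  baseline_scale: 1.0
  dispersion: 2.0
  libsize_sigma: 0.3
  mito_gene_count: 10
  mito_mean_frac: 0.05
  marker_min_quantile: 0.5
  seed: 0
bulk_sim:
  n_samples_ln_met: 146
  n_samples_non_ln: 17
  n_background_genes: 480
  signature_gene_count: 20
  signature_genes: null
  gene_universe: null
  shift: 1.0
  noise_sd: 1.0
  baseline_hazard: 0.023104906018664842
  log_hr_per_sd: 0.9162907318741551
  censoring_rate: 0.3
  histology_fracs:
    intestinal: 0.7
    mixed: 0.3
  seed: 1
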