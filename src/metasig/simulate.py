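"""Synthetic single-cell and bulk cohorts with planted ground truth.

The single-cell generator draws negative-binomial counts over log-normal
gene baseline means with per-cell library-size factors — the minimal
generative model for overdispersed scRNA-seq counts.  Structure is planted
multiplicatively: a population or cluster over-expresses its designated gene
block by ``exp(log_shift)``.  Cluster origin compositions (the fraction of
cells from PT / NT / Li / LN / P / O) are assigned deterministically, so an
"LN-derived" cluster's LN fraction matches its configuration exactly.

The bulk generator emulates a primary-tumour cohort: Gaussian log-expression
with the signature genes mean-shifted in the lymph-node-metastasis group,
and exponential survival under proportional hazards tied to the latent
(planted) signature score, with independent exponential censoring.

Everything is a pure function of config + seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .bulk import LN_MET, NON_LN_MET, BulkCohort
from .matrix import ORIGIN_CLASSES, CellAnnotation, ExpressionMatrix, ValidationError


class ConfigError(ValueError):
    """Inconsistent simulation layout."""


@dataclass
class PlantedPopulation:
    """A cell population over-expressing a dedicated gene block."""

    name: str
    n_cells: int
    shifted_gene_count: int = 0
    log_shift: float = 0.0
    lineage: str = "epithelial"
    malignant: bool | None = None
    origin: str = "PT"

    def __post_init__(self) -> None:
        if self.log_shift < 0:
            raise ConfigError("log_shift must be >= 0")
        if self.origin not in ORIGIN_CLASSES:
            raise ConfigError(f"unknown origin {self.origin!r}")


@dataclass
class ClusterSpec:
    """An annotated cluster with a fixed origin composition."""

    cluster: str
    size: int
    origin_composition: dict[str, float]
    n_marker_genes: int = 0
    log_shift: float = 0.0
    lineage: str = "T"

    def __post_init__(self) -> None:
        bad = set(self.origin_composition) - set(ORIGIN_CLASSES)
        if bad:
            raise ConfigError(f"unknown origins {sorted(bad)}")
        if abs(sum(self.origin_composition.values()) - 1.0) > 1e-9:
            raise ConfigError("origin composition must sum to 1")


@dataclass
class ScSimConfig:
    populations: list[PlantedPopulation] = field(default_factory=list)
    clusters: list[ClusterSpec] = field(default_factory=list)
    n_genes: int = 2000
    baseline_loc: float = -1.5     # log-normal location of gene mean counts
    baseline_scale: float = 1.0    # log-normal scale
    dispersion: float = 2.0        # negative-binomial size (theta)
    libsize_sigma: float = 0.3     # log-normal sd of cell library factors
    mito_gene_count: int = 10
    mito_mean_frac: float = 0.05
    # planted marker/reference genes are drawn from genes at or above this
    # baseline-expression quantile: a gene too lowly expressed to be detected
    # cannot carry a planted signal
    marker_min_quantile: float = 0.5
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return (sum(p.n_cells for p in self.populations)
                + sum(c.size for c in self.clusters))


@dataclass
class SimTruth:
    """Ground truth: per-cell roles, per-gene roles, per-sample latents."""

    cells: pd.DataFrame | None = None        # cell_id, population/cluster, origin, malignant
    gene_roles: dict[str, list[str]] = field(default_factory=dict)
    samples: pd.DataFrame | None = None      # bulk: group, true_score, hazard

    def to_json(self, path: str | Path) -> None:
        obj = {
            "cells": None if self.cells is None else self.cells.to_dict("list"),
            "gene_roles": self.gene_roles,
            "samples": None if self.samples is None
            else self.samples.reset_index().to_dict("list"),
        }
        Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def _assign_origin_counts(comp: dict[str, float], size: int) -> list[str]:
    """Deterministic largest-remainder apportionment of origins."""
    return _largest_remainder(comp, size)


def generate_scrna(cfg: ScSimConfig):
    """Draw a raw count matrix, its annotation and the planted truth.

    Returns ``(ExpressionMatrix, CellAnnotation, SimTruth)``.
    """
    if not cfg.populations and not cfg.clusters:
        raise ConfigError("no populations or clusters configured")
    n_cells = cfg.n_cells
    n_shift = (sum(p.shifted_gene_count for p in cfg.populations)
               + sum(c.n_marker_genes for c in cfg.clusters))
    n_regular = cfg.n_genes - cfg.mito_gene_count
    if n_shift > n_regular:
        raise ConfigError("more shifted genes than available genes")

    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_genes)))
    genes = np.array(
        [f"G{i:0{width}d}" for i in range(1, n_regular + 1)]
        + [f"MT-{i}" for i in range(1, cfg.mito_gene_count + 1)],
        dtype=object,
    )
    base = rng.lognormal(cfg.baseline_loc, cfg.baseline_scale, size=n_regular)
    if cfg.mito_gene_count:
        # mitochondrial means tuned so the expected mito fraction is ~mito_mean_frac
        mito_total = cfg.mito_mean_frac / (1 - cfg.mito_mean_frac) * base.sum()
        mito_base = np.full(cfg.mito_gene_count,
                            mito_total / cfg.mito_gene_count)
        base = np.concatenate([base, mito_base])

    lib = rng.lognormal(0.0, cfg.libsize_sigma, size=n_cells)

    # allocate disjoint shifted-gene blocks, in declaration order, from the
    # adequately expressed part of the baseline distribution
    floor = np.quantile(base[:n_regular], cfg.marker_min_quantile)
    eligible = np.flatnonzero(base[:n_regular] >= floor)
    cursor = 0
    gene_roles: dict[str, list[str]] = {"mito": [str(g) for g in genes[n_regular:]]}
    shift_blocks: list[tuple[np.ndarray, float]] = []   # (gene rows, log_shift)
    units = [(p.name, p.shifted_gene_count, p.log_shift) for p in cfg.populations] \
        + [(c.cluster, c.n_marker_genes, c.log_shift) for c in cfg.clusters]
    if sum(k for _, k, _ in units) > len(eligible):
        raise ConfigError("more shifted genes than adequately expressed genes")
    for name, k, shift in units:
        rows = eligible[cursor:cursor + k]
        gene_roles[name] = [str(g) for g in genes[rows]]
        shift_blocks.append((rows, shift))
        cursor += k

    # per-cell bookkeeping
    records = []
    cell_pop: list[int] = []     # index into `units` per cell
    i = 0
    for u, p in enumerate(cfg.populations):
        for _ in range(p.n_cells):
            records.append({
                "cell_id": f"C{i + 1:05d}",
                "sample": f"{p.origin}1",
                "origin_class": p.origin,
                "patient": "P1",
                "lineage": p.lineage,
                "cluster": None,
                "truth_label": ("malignant" if p.malignant
                                else "non_malignant") if p.malignant is not None
                else p.name,
                "population": p.name,
            })
            cell_pop.append(u)
            i += 1
    for u, c in enumerate(cfg.clusters, start=len(cfg.populations)):
        origins = _assign_origin_counts(c.origin_composition, c.size)
        for o in origins:
            records.append({
                "cell_id": f"C{i + 1:05d}",
                "sample": f"{o}1",
                "origin_class": o,
                "patient": "P1",
                "lineage": c.lineage,
                "cluster": c.cluster,
                "truth_label": c.cluster,
                "population": c.cluster,
            })
            cell_pop.append(u)
            i += 1
    cell_pop = np.asarray(cell_pop)

    # draw counts population-block by population-block
    counts = np.empty((cfg.n_genes, n_cells), dtype=np.int64)
    theta = cfg.dispersion
    for u in range(len(units)):
        cols = np.flatnonzero(cell_pop == u)
        mu = np.outer(base, lib[cols])
        rows, shift = shift_blocks[u]
        if len(rows) and shift > 0:
            mu[rows, :] *= np.exp(shift)
        p_nb = theta / (theta + mu)
        counts[:, cols] = rng.negative_binomial(theta, p_nb)

    ann_df = pd.DataFrame.from_records(records)
    truth = SimTruth(
        cells=ann_df[["cell_id", "population", "cluster", "origin_class",
                      "truth_label", "lineage"]].copy(),
        gene_roles=gene_roles,
    )
    m = ExpressionMatrix(genes=genes,
                         cells=ann_df["cell_id"].to_numpy(dtype=object),
                         X=sp.csr_matrix(counts), layer="raw")
    ann = CellAnnotation(ann_df.drop(columns=["population"]))
    return m, ann, truth


@dataclass
class BulkSimConfig:
    n_samples_ln_met: int = 146
    n_samples_non_ln: int = 17
    n_background_genes: int = 480
    signature_gene_count: int = 20
    signature_genes: list[str] | None = None   # names; auto-generated if None
    gene_universe: list[str] | None = None     # extra genes to include
    shift: float = 1.0            # mean shift of signature genes in LN_met, in noise-SD units
    noise_sd: float = 1.0
    baseline_hazard: float = np.log(2) / 30.0  # per month; median survival ~30 months
    log_hr_per_sd: float = float(np.log(2.5))  # log hazard ratio per SD of true score
    censoring_rate: float = 0.3
    histology_fracs: dict[str, float] = field(
        default_factory=lambda: {"intestinal": 0.7, "mixed": 0.3})
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.censoring_rate < 1):
            raise ConfigError("censoring_rate must be in [0,1)")
        if self.n_samples_ln_met < 1 or self.n_samples_non_ln < 1:
            raise ConfigError("both metastasis groups need >= 1 sample")


def generate_bulk_cohort(cfg: BulkSimConfig):
    """Simulate a bulk validation cohort.

    Returns ``(BulkCohort, SimTruth)``; the truth records each sample's
    metastasis group, latent (pre-noise-free) signature burden and hazard.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples_ln_met + cfg.n_samples_non_ln

    sig_genes = cfg.signature_genes
    if sig_genes is None:
        sig_genes = [f"SIG{i:02d}" for i in range(1, cfg.signature_gene_count + 1)]
    if len(sig_genes) != cfg.signature_gene_count:
        raise ConfigError("signature_genes length != signature_gene_count")
    bg = [f"BG{i:04d}" for i in range(1, cfg.n_background_genes + 1)]
    extra = [g for g in (cfg.gene_universe or []) if g not in set(sig_genes)]
    genes = sig_genes + sorted(set(bg + extra))

    samples = [f"S{i:03d}" for i in range(1, n + 1)]
    group = np.array([LN_MET] * cfg.n_samples_ln_met
                     + [NON_LN_MET] * cfg.n_samples_non_ln)

    mu = rng.normal(5.0, 1.0, size=len(genes))
    expr = mu[:, None] + rng.normal(0.0, cfg.noise_sd, size=(len(genes), n))
    is_sig = np.isin(genes, sig_genes)
    expr[np.ix_(is_sig, group == LN_MET)] += cfg.shift * cfg.noise_sd

    # latent signature burden: standardized mean deviation over signature genes
    burden = (expr[is_sig, :] - mu[is_sig, None]).mean(axis=0)
    z = (burden - burden.mean()) / burden.std(ddof=0)

    hazard = cfg.baseline_hazard * np.exp(cfg.log_hr_per_sd * z)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        lam_c = cfg.baseline_hazard * cfg.censoring_rate / (1 - cfg.censoring_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    hist_labels = _assign_origin_like(cfg.histology_fracs, n)
    meta = pd.DataFrame({
        "sample": samples,
        "metastasis_group": group,
        "time": np.maximum(time, 1e-6),
        "event": event,
        "histology": hist_labels,
    })
    cohort = BulkCohort(
        expr=pd.DataFrame(expr, index=genes, columns=samples),
        meta=meta, time_unit="months",
    )
    truth = SimTruth(
        gene_roles={"signature": list(sig_genes)},
        samples=pd.DataFrame({
            "sample": samples, "group": group, "true_score": z,
            "hazard": hazard, "event": event,
        }).set_index("sample"),
    )
    return cohort, truth


def _assign_origin_like(fracs: dict[str, float], n: int) -> list[str]:
    total = sum(fracs.values())
    return _largest_remainder({k: v / total for k, v in fracs.items()}, n)


def _largest_remainder(fracs: dict[str, float], n: int) -> list[str]:
    items = sorted(fracs.items())
    raw = [(k, f * n) for k, f in items]
    counts = {k: int(np.floor(x)) for k, x in raw}
    short = n - sum(counts.values())
    for k, _ in sorted(raw, key=lambda t: t[1] - np.floor(t[1]), reverse=True)[:short]:
        counts[k] += 1
    out: list[str] = []
    for k, _ in items:
        out.extend([k] * counts[k])
    return out


def division_recovery_scenario(seed: int, n_malignant: int = 300,
                               n_non: int = 200, shift: float = 2.5,
                               nonmal_shift: float = 1.5,
                               n_genes: int = 1000):
    """A planted malignant / non-malignant epithelial matrix for
    classifier-recovery experiments.

    Returns ``(raw_matrix, annotation, truth, init_mal, init_nonmal)`` where
    the initial reference sets are the planted truth gene blocks.
    """
    from .matrix import GeneSet  # avoid import cycle at module load

    cfg = ScSimConfig(
        populations=[
            PlantedPopulation(name="malignant", n_cells=n_malignant,
                              shifted_gene_count=50, log_shift=shift,
                              malignant=True, origin="PT"),
            PlantedPopulation(name="non_malignant", n_cells=n_non,
                              shifted_gene_count=50, log_shift=nonmal_shift,
                              malignant=False, origin="NT"),
        ],
        n_genes=n_genes, seed=seed,
    )
    m, ann, truth = generate_scrna(cfg)
    init_mal = GeneSet("init_malignant", truth.gene_roles["malignant"])
    init_nonmal = GeneSet("init_non_malignant",
                          truth.gene_roles["non_malignant"])
    return m, ann, truth, init_mal, init_nonmal


# ---------------------------------------------------------------------------
# canonical small fixtures

def write_fixture_suite(outdir: str | Path) -> dict:
    """Write the small canonical fixtures with a checksum manifest.

    Emits: a QC fixture (MTX triplet, 100 cells with 4 low-gene, 2
    high-gene and 3 high-mito planted violations), the 4-sample x 3-gene
    ±1-scoring table with its expected scores, the 6-point split-curve
    vector with its expected threshold, and the 3-subject survival toy.
    """
    from .io import write_counts  # local import to avoid cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}

    # --- QC fixture -------------------------------------------------------
    m, expected = _qc_fixture()
    write_counts(m, outdir / "qc_fixture")
    for f in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
        manifest[f"qc_fixture/{f}"] = {"sha256": _sha256(outdir / "qc_fixture" / f)}
    (outdir / "qc_fixture" / "expected.json").write_text(
        json.dumps(expected, indent=2) + "\n")
    manifest["qc_fixture/expected.json"] = {
        "sha256": _sha256(outdir / "qc_fixture" / "expected.json")}

    # --- ±1 scoring table -------------------------------------------------
    tab = pd.DataFrame(
        [[1, 2, 3, 4], [5, 5, 5, 5], [0, 10, 0, 10]],
        index=["g1", "g2", "g3"], columns=["s1", "s2", "s3", "s4"],
    )
    tab.to_csv(outdir / "scoring_4x3.tsv", sep="\t")
    (outdir / "scoring_4x3_expected.json").write_text(
        json.dumps({"scores": {"s1": -3, "s2": -1, "s3": -1, "s4": 1}},
                   indent=2) + "\n")
    manifest["scoring_4x3.tsv"] = {"sha256": _sha256(outdir / "scoring_4x3.tsv")}
    manifest["scoring_4x3_expected.json"] = {
        "sha256": _sha256(outdir / "scoring_4x3_expected.json")}

    # --- split curve --------------------------------------------------------
    curve = [-0.50, -0.45, -0.40, 0.30, 0.35, 0.40]
    pd.Series(curve, name="diff").to_csv(outdir / "split_curve.tsv", sep="\t",
                                         index=False)
    (outdir / "split_curve_expected.json").write_text(
        json.dumps({"threshold": -0.05}) + "\n")
    manifest["split_curve.tsv"] = {"sha256": _sha256(outdir / "split_curve.tsv")}
    manifest["split_curve_expected.json"] = {
        "sha256": _sha256(outdir / "split_curve_expected.json")}

    # --- survival toy -------------------------------------------------------
    surv = pd.DataFrame({"time": [1, 2, 3], "event": [1, 0, 1]})
    surv.to_csv(outdir / "survival_toy.tsv", sep="\t", index=False)
    (outdir / "survival_toy_expected.json").write_text(
        json.dumps({"S": {"1": 2 / 3, "3": 0.0}}) + "\n")
    manifest["survival_toy.tsv"] = {"sha256": _sha256(outdir / "survival_toy.tsv")}
    manifest["survival_toy_expected.json"] = {
        "sha256": _sha256(outdir / "survival_toy_expected.json")}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _qc_fixture():
    """100 cells, 5200 genes; 4 low-gene, 2 high-gene, 3 high-mito planted
    violations (disjoint) under the default 200 / 5000 / 20% thresholds."""
    n_mt = 10
    n_reg = 5190
    genes = np.array([f"G{i:04d}" for i in range(1, n_reg + 1)]
                     + [f"MT-{i}" for i in range(1, n_mt + 1)], dtype=object)
    cells = np.array([f"C{i:03d}" for i in range(1, 101)], dtype=object)
    rows, cols, data = [], [], []

    def put(ci, gene_idx, vals):
        rows.extend(gene_idx)
        cols.extend([ci] * len(gene_idx))
        data.extend(vals)

    for ci in range(100):
        if ci < 4:       # low-gene: 150 detected
            idx = list(range(150))
            put(ci, idx, [1] * 150)
        elif ci < 6:     # high-gene: 5100 detected (incl. 10 MT)
            idx = list(range(5090)) + list(range(n_reg, n_reg + n_mt))
            put(ci, idx, [1] * 5100)
        elif ci < 9:     # high-mito: 230 detected, 100/320 counts on MT
            idx = list(range(220)) + list(range(n_reg, n_reg + n_mt))
            put(ci, idx, [1] * 220 + [10] * n_mt)
        else:            # clean: 250 detected, 5 MT counts of 1 (2%)
            idx = list(range(245)) + list(range(n_reg, n_reg + 5))
            put(ci, idx, [1] * 250)
    X = sp.csr_matrix((data, (rows, cols)), shape=(len(genes), len(cells)),
                      dtype=np.int64)
    m = ExpressionMatrix(genes=genes, cells=cells, X=X, layer="raw")
    expected = {"n_input_cells": 100, "n_removed_low_genes": 4,
                "n_removed_high_genes": 2, "n_removed_mito": 3,
                "n_retained": 91}
    return m, expected


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
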