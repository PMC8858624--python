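"""Wilcoxon rank-sum marker detection, p-value adjustment, organ-enriched
subcluster detection and top-N signature extraction.

The differential test compares one cell group against its complement on the
normalized layer.  Genes are pre-filtered on detection fraction
(``min_pct``, applied to the larger of the two groups' fractions) and
natural-log fold change before testing; p-values are adjusted over the genes
actually tested.  The log fold change is computed on de-logged means,
``ln((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1))``, the convention of
the Seurat-style single-cell toolchain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .matrix import CellAnnotation, ExpressionMatrix, GeneSet, ValidationError

DEG_COLUMNS = ["gene", "group", "log_fc", "pct_in", "pct_out",
               "p_raw", "p_adj", "direction", "significant"]


@dataclass
class DEGConfig:
    min_pct: float = 0.2
    logfc_threshold: float = 0.2
    alpha: float = 0.05
    adjust_method: str = "bonferroni"   # or "bh"
    only_pos: bool = False
    exact_max_n: int = 10               # exact enumeration when both groups <= this

    def __post_init__(self) -> None:
        if not (0 <= self.min_pct <= 1):
            raise ValidationError("min_pct must be in [0,1]")
        if self.logfc_threshold < 0:
            raise ValidationError("logfc_threshold must be >= 0")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0,1)")
        if self.adjust_method not in ("bonferroni", "bh"):
            raise ValidationError("adjust_method must be 'bonferroni' or 'bh'")


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni ``min(1, m*p)`` or
    Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0,1]")
    sm_method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    return multipletests(p, method=sm_method)[1]


def _wilcoxon_pvalues(x_in: np.ndarray, x_out: np.ndarray,
                      exact_max_n: int) -> np.ndarray:
    """Two-sided rank-sum p per gene (rows).

    Exact enumeration when both groups are small and the gene's values are
    tie-free; normal approximation with tie correction otherwise.  A gene
    with all values identical gets p = 1 by convention.
    """
    n_genes = x_in.shape[0]
    n1, n2 = x_in.shape[1], x_out.shape[1]
    p = np.ones(n_genes)

    combined = np.concatenate([x_in, x_out], axis=1)
    constant = np.ptp(combined, axis=1) == 0
    live = np.flatnonzero(~constant)
    if live.size == 0:
        return p

    if n1 <= exact_max_n and n2 <= exact_max_n:
        for g in live:
            vals = combined[g]
            has_ties = len(np.unique(vals)) < len(vals)
            method = "asymptotic" if has_ties else "exact"
            p[g] = mannwhitneyu(x_in[g], x_out[g], alternative="two-sided",
                                method=method).pvalue
    else:
        res = mannwhitneyu(x_in[live], x_out[live], alternative="two-sided",
                           method="asymptotic", axis=1)
        p[live] = np.minimum(np.atleast_1d(res.pvalue), 1.0)
    return p


def wilcoxon_deg(m: ExpressionMatrix, labels: pd.Series | dict,
                 target, cfg: DEGConfig | None = None) -> pd.DataFrame:
    """Markers of ``target`` cells versus all other labelled cells.

    ``labels`` maps cell_id -> group label; cells absent from it are ignored.
    Returns a :data:`DEG_COLUMNS` DataFrame sorted by adjusted p.
    """
    cfg = cfg or DEGConfig()
    if m.layer != "normalized":
        raise ValidationError("wilcoxon_deg expects a normalized matrix")
    labels = pd.Series(labels)
    labels = labels[labels.index.isin(m.cells)]
    in_cells = labels.index[labels == target]
    out_cells = labels.index[labels != target]
    if len(in_cells) == 0 or len(out_cells) == 0:
        raise ValidationError(f"group {target!r} or its complement is empty")
    if len(in_cells) < 3 or len(out_cells) < 3:
        raise ValidationError("each group needs at least 3 cells")

    x_in = m.X[:, m.cell_index(in_cells)].toarray()
    x_out = m.X[:, m.cell_index(out_cells)].toarray()

    pct_in = (x_in > 0).mean(axis=1)
    pct_out = (x_out > 0).mean(axis=1)
    log_fc = np.log((np.expm1(x_in).mean(axis=1) + 1.0)
                    / (np.expm1(x_out).mean(axis=1) + 1.0))

    tested = (np.maximum(pct_in, pct_out) >= cfg.min_pct) \
        & (np.abs(log_fc) >= cfg.logfc_threshold)
    idx = np.flatnonzero(tested)
    if idx.size == 0:
        return pd.DataFrame(columns=DEG_COLUMNS)

    p_raw = _wilcoxon_pvalues(x_in[idx], x_out[idx], cfg.exact_max_n)
    p_adj = adjust_pvalues(p_raw, cfg.adjust_method)

    out = pd.DataFrame({
        "gene": m.genes[idx],
        "group": target,
        "log_fc": log_fc[idx],
        "pct_in": pct_in[idx],
        "pct_out": pct_out[idx],
        "p_raw": p_raw,
        "p_adj": p_adj,
        "direction": np.where(log_fc[idx] > 0, "up", "down"),
        "significant": p_adj < cfg.alpha,
    })
    if cfg.only_pos:
        out = out[out["direction"] == "up"]
    return out.sort_values(
        ["p_adj", "log_fc", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)


def detect_origin_subclusters(ann: CellAnnotation, origin: str,
                              frac: float = 0.9) -> list:
    """Clusters in which strictly more than ``frac`` of cells carry ``origin``.

    With the default 0.9 this is the "more than 90% of cells came from LN"
    rule for calling a cluster lymph-node derived.
    """
    tab = ann.table
    if "cluster" not in tab.columns or tab["cluster"].isna().all():
        raise ValidationError("annotation carries no cluster labels")
    sub = tab.dropna(subset=["cluster"])
    hits = []
    for cluster, grp in sub.groupby("cluster", sort=True):
        if (grp["origin_class"] == origin).mean() > frac:
            hits.append(cluster)
    return hits


def extract_signature(deg: pd.DataFrame, top_n: int = 20,
                      name: str = "signature") -> GeneSet:
    """Top ``top_n`` significant upregulated markers.

    Ranked by adjusted p ascending, then log fold change descending, then
    gene id, for a fully deterministic ordering.
    """
    up = deg[(deg["significant"]) & (deg["direction"] == "up")]
    if len(up) == 0:
        raise ValidationError("no significant upregulated gene to extract")
    up = up.sort_values(["p_adj", "log_fc", "gene"],
                        ascending=[True, False, True])
    if len(up) < top_n:
        warnings.warn(
            f"only {len(up)} significant upregulated genes available "
            f"(requested {top_n})",
            stacklevel=2,
        )
    return GeneSet(name=name, genes=list(up["gene"].head(top_n)))
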