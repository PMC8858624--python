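"""Global-scaling log-normalization and pseudobulk correlation."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.stats import pearsonr

from .matrix import ExpressionMatrix, ValidationError


def lognormalize(m: ExpressionMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """``ln(1 + count / cell_total * scale_factor)`` per entry.

    Every cell must have a positive total count; run QC first to drop empty
    cells.
    """
    if m.layer != "raw":
        raise ValidationError("lognormalize expects the raw layer")
    if scale_factor <= 0:
        raise ValidationError("scale_factor must be positive")
    totals = m.counts_per_cell().astype(float)
    if (totals <= 0).any():
        raise ValidationError(
            "cells with zero total count present; apply qc_filter before "
            "normalization"
        )
    X = m.X.tocsc().astype(float)
    X = X.multiply(sp.csr_matrix(scale_factor / totals))  # broadcast over cells
    X = X.tocsr()
    X.data = np.log1p(X.data)
    return ExpressionMatrix(genes=m.genes.copy(), cells=m.cells.copy(),
                            X=X, layer="normalized")


def pseudobulk_profile(m: ExpressionMatrix) -> np.ndarray:
    """log1p of per-gene count sums across all cells."""
    return np.log1p(np.asarray(m.X.sum(axis=1)).ravel().astype(float))


def pseudobulk_correlation(a: ExpressionMatrix, b: ExpressionMatrix):
    """Pearson correlation of the two matrices' log1p gene-sum profiles.

    The gene universes are intersected; the number of shared genes is
    returned alongside the coefficient.

    Returns
    -------
    (r, n_shared_genes)
    """
    shared = [g for g in a.genes if g in set(b.genes)]
    if len(shared) < 2:
        raise ValidationError(
            f"only {len(shared)} shared genes; need at least 2"
        )
    pa = pseudobulk_profile(a.subset_genes(shared))
    pb = pseudobulk_profile(b.subset_genes(shared))
    if np.ptp(pa) == 0 or np.ptp(pb) == 0:
        raise ValidationError("zero variance in a pseudobulk profile; "
                              "correlation undefined")
    r = pearsonr(pa, pb).statistic
    return float(r), len(shared)
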