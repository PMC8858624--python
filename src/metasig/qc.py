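"""Cell-level quality control.

Cells are excluded when they express fewer than ``min_genes`` unique genes,
more than ``max_genes`` unique genes, or when more than ``max_mito_frac`` of
their reads map to mitochondrial genes.  All three exclusions use strict
inequalities, so a cell sitting exactly on a threshold is retained.

A cell failing several rules is counted once, under the first failing rule in
the order low-genes, high-genes, mito, so the report's removal counts always
sum to the number of input cells minus the retained cells.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .matrix import CellAnnotation, ExpressionMatrix, ValidationError


@dataclass
class QCConfig:
    min_genes: int = 200
    max_genes: int = 5000
    max_mito_frac: float = 0.20
    mito_gene_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not (0 < self.min_genes < self.max_genes):
            raise ValidationError("require 0 < min_genes < max_genes")
        if not (0 < self.max_mito_frac <= 1):
            raise ValidationError("require 0 < max_mito_frac <= 1")


@dataclass
class QCReport:
    n_input_cells: int
    n_removed_low_genes: int
    n_removed_high_genes: int
    n_removed_mito: int
    n_retained: int
    median_genes_per_cell: float

    def to_dict(self) -> dict:
        return asdict(self)


class EmptyResultError(RuntimeError):
    """Every cell was removed by QC."""


def mito_fraction(m: ExpressionMatrix, prefix: str = "MT-") -> np.ndarray:
    """Fraction of each cell's counts on genes whose name starts with ``prefix``."""
    is_mito = np.array([str(g).startswith(prefix) for g in m.genes])
    totals = m.counts_per_cell().astype(float)
    if not is_mito.any():
        return np.zeros(m.n_cells)
    mito = np.asarray(m.X[is_mito, :].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1e-300), 0.0)
    return frac


def qc_filter(m: ExpressionMatrix, cfg: QCConfig | None = None,
              annotation: CellAnnotation | None = None):
    """Apply the three exclusion rules to a raw count matrix.

    Returns ``(filtered_matrix, report)`` or, when an annotation is supplied,
    ``(filtered_matrix, filtered_annotation, report)``.
    """
    cfg = cfg or QCConfig()
    if m.layer != "raw":
        raise ValidationError("qc_filter expects the raw layer")

    detected = m.genes_detected_per_cell()
    mito = mito_fraction(m, cfg.mito_gene_prefix)

    low = detected < cfg.min_genes
    high = detected > cfg.max_genes
    hi_mito = mito > cfg.max_mito_frac
    keep = ~(low | high | hi_mito)

    # precedence: low-genes, then high-genes, then mito
    n_low = int(low.sum())
    n_high = int((high & ~low).sum())
    n_mito = int((hi_mito & ~low & ~high).sum())

    if not keep.any():
        raise EmptyResultError("QC removed every cell; check thresholds")

    kept_cells = m.cells[keep]
    out = m.subset_cells(list(kept_cells))
    report = QCReport(
        n_input_cells=m.n_cells,
        n_removed_low_genes=n_low,
        n_removed_high_genes=n_high,
        n_removed_mito=n_mito,
        n_retained=int(keep.sum()),
        median_genes_per_cell=float(np.median(detected[keep])),
    )
    if annotation is not None:
        return out, annotation.subset(list(kept_cells)), report
    return out, report
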