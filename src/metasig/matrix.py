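"""Core in-memory containers for single-cell expression data.

The central object is :class:`ExpressionMatrix`, a gene x cell matrix with an
explicit ``layer`` tag distinguishing raw integer counts from log-normalized
expression.  Keeping the orientation gene x cell mirrors the on-disk 10x
triplet layout and makes per-gene operations (marker tests, module scoring)
row-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

ORIGIN_CLASSES = ("PT", "NT", "Li", "LN", "P", "O")


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass
class ExpressionMatrix:
    """Gene x cell expression matrix.

    Parameters
    ----------
    genes, cells
        Ordered, unique identifiers for rows and columns.
    X
        ``scipy.sparse`` matrix (or dense ndarray, converted to CSR) of shape
        ``(len(genes), len(cells))``.  Raw layers must hold non-negative
        integers; normalized layers hold ``ln(1 + cpX)`` values.
    layer
        ``"raw"`` or ``"normalized"``.
    """

    genes: np.ndarray
    cells: np.ndarray
    X: sp.csr_matrix
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.cells = np.asarray(self.cells, dtype=object)
        if not sp.issparse(self.X):
            self.X = sp.csr_matrix(np.asarray(self.X))
        else:
            self.X = self.X.tocsr()
        if self.layer not in ("raw", "normalized"):
            raise ValidationError(f"unknown layer {self.layer!r}")
        if self.X.shape != (len(self.genes), len(self.cells)):
            raise ValidationError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("duplicate cell identifiers")
        if self.X.nnz and self.X.data.min() < 0:
            raise ValidationError("negative entries in expression matrix")
        if self.layer == "raw" and self.X.nnz:
            if not np.allclose(self.X.data, np.round(self.X.data)):
                raise ValidationError("raw layer must be integer-valued")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices of ``genes`` that are present, in their given order."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def cell_index(self, cells: Iterable[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cells)}
        missing = [c for c in cells if c not in lookup]
        if missing:
            raise KeyError(f"unknown cells: {missing[:5]}")
        return np.array([lookup[c] for c in cells], dtype=int)

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        idx = self.cell_index(cells)
        return ExpressionMatrix(
            genes=self.genes.copy(),
            cells=np.asarray(cells, dtype=object),
            X=self.X[:, idx],
            layer=self.layer,
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            genes=self.genes[idx],
            cells=self.cells.copy(),
            X=self.X[idx, :],
            layer=self.layer,
        )

    def dense(self) -> np.ndarray:
        return np.asarray(self.X.todense())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.genes, columns=self.cells)

    def counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=0)).ravel()

    def genes_detected_per_cell(self) -> np.ndarray:
        """Number of genes with count > 0 per cell."""
        return np.asarray((self.X > 0).sum(axis=0)).ravel()


@dataclass
class CellAnnotation:
    """Per-cell metadata table.

    Required columns: ``cell_id``, ``sample``, ``origin_class``.  Optional:
    ``patient``, ``lineage``, ``cluster``, ``truth_label``.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("cell_id", "sample", "origin_class")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing columns {missing}")
        if self.table["cell_id"].duplicated().any():
            raise ValidationError("duplicate cell_id in annotation")
        bad = set(self.table["origin_class"]) - set(ORIGIN_CLASSES)
        if bad:
            raise ValidationError(f"unknown origin_class values {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.table["cell_id"].to_numpy()

    def column(self, name: str) -> pd.Series:
        return self.table.set_index("cell_id")[name]

    def subset(self, cell_ids: Sequence[str]) -> "CellAnnotation":
        sub = self.table.set_index("cell_id").loc[list(cell_ids)].reset_index()
        return CellAnnotation(sub)


@dataclass
class GeneSet:
    """Named, ordered, duplicate-free list of gene identifiers."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def present_in(self, m: ExpressionMatrix) -> list[str]:
        have = set(m.genes)
        return [g for g in self.genes if g in have]
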