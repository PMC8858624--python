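"""Gene-set scoring on normalized single-cell matrices.

Two scorers live here:

``module_score``
    The control-matched scheme used throughout for malignant / non-malignant
    reference sets: all genes are binned into equal-frequency bins by their
    average expression, ``n_ctrl`` control genes are drawn from the bin of
    each set gene, and a cell's score is the mean expression of the set genes
    minus the mean expression of the drawn controls.  Subtracting bin-matched
    controls removes the component of the set mean explained by overall
    expression level, so an uninformative set scores ~0.

``mean_expression_score``
    The plain average of normalized expression over a set, used for the
    proliferation / migration and M1 / M2 functional scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, GeneSet, ValidationError

# functional score gene lists (editable defaults)
PROLIFERATION_GENES = ["MKI67", "IGF1", "ITGB2", "PDGFC", "JAG1", "PHGDH"]
MIGRATION_GENES = ["VIM", "SNAI1", "MMP9", "AREG", "ARID5B", "FAT1"]
M1_GENES = ["TNF", "CXCL9", "CXCL10", "IL12A"]
M2_GENES = ["TGFB1", "CD163", "CCL18", "MRC1"]


@dataclass
class ModuleScoreConfig:
    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
        if self.n_ctrl < 1:
            raise ValidationError("n_ctrl must be >= 1")


def _require_normalized(m: ExpressionMatrix) -> None:
    if m.layer != "normalized":
        raise ValidationError("scoring expects a normalized matrix")


def _present_genes(m: ExpressionMatrix, gs: GeneSet) -> list[str]:
    present = gs.present_in(m)
    if not present:
        raise ValidationError(f"no gene of set {gs.name!r} present in matrix")
    if len(present) < len(gs):
        warnings.warn(
            f"gene set {gs.name!r}: {len(gs) - len(present)} of {len(gs)} "
            "genes absent from matrix; dropped",
            stacklevel=3,
        )
    return present


def module_score(m: ExpressionMatrix, gs: GeneSet,
                 cfg: ModuleScoreConfig | None = None) -> pd.Series:
    """Control-matched module score, one value per cell.

    Controls are drawn per set gene from that gene's average-expression bin
    (``n_bins`` equal-frequency bins over all genes), without replacement
    when the bin is large enough, reproducibly under ``cfg.seed``.
    """
    cfg = cfg or ModuleScoreConfig()
    _require_normalized(m)
    present = _present_genes(m, gs)

    n_bins = cfg.n_bins
    if m.n_genes < n_bins:
        n_bins = max(2, m.n_genes)
        warnings.warn(
            f"only {m.n_genes} genes; reducing n_bins to {n_bins}",
            stacklevel=2,
        )

    gene_means = np.asarray(m.X.mean(axis=1)).ravel()
    # equal-frequency bins: split the expression-ranked gene order into
    # n_bins contiguous chunks (ties broken by index for determinism)
    order = np.argsort(gene_means, kind="stable")
    bin_of = np.empty(m.n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b

    rng = np.random.default_rng(cfg.seed)
    set_idx = m.gene_index(present)
    in_set = np.zeros(m.n_genes, dtype=bool)
    in_set[set_idx] = True
    ctrl_idx: list[np.ndarray] = []
    for gi in set_idx:
        # controls are non-set genes from the same expression bin; if the bin
        # is exhausted by set genes, fall back to the nearest non-set genes
        # by average expression
        members = np.flatnonzero((bin_of == bin_of[gi]) & ~in_set)
        if len(members) == 0:
            nonset = np.flatnonzero(~in_set)
            if len(nonset) == 0:
                continue
            members = nonset[np.argsort(np.abs(gene_means[nonset]
                                               - gene_means[gi]),
                                        kind="stable")[:cfg.n_ctrl]]
        replace = len(members) < cfg.n_ctrl
        ctrl_idx.append(rng.choice(members, size=cfg.n_ctrl, replace=replace))
    if not ctrl_idx:
        raise ValidationError("no control genes available for any set gene")
    ctrl = np.concatenate(ctrl_idx)

    set_mean = np.asarray(m.X[set_idx, :].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(m.X[ctrl, :].mean(axis=0)).ravel()
    return pd.Series(set_mean - ctrl_mean, index=m.cells, name=gs.name)


def mean_expression_score(m: ExpressionMatrix, gs: GeneSet) -> pd.Series:
    """Arithmetic mean of normalized expression over the present set genes."""
    _require_normalized(m)
    present = _present_genes(m, gs)
    idx = m.gene_index(present)
    vals = np.asarray(m.X[idx, :].mean(axis=0)).ravel()
    return pd.Series(vals, index=m.cells, name=gs.name)


def functional_scores(m: ExpressionMatrix) -> dict[str, pd.Series]:
    """Proliferation, migration, M1 and M2 mean-expression scores.

    A score whose gene list is entirely absent from the matrix is omitted
    with a warning rather than raising.
    """
    lists = {
        "proliferation": PROLIFERATION_GENES,
        "migration": MIGRATION_GENES,
        "M1": M1_GENES,
        "M2": M2_GENES,
    }
    out: dict[str, pd.Series] = {}
    for name, genes in lists.items():
        gs = GeneSet(name=name, genes=genes)
        try:
            out[name] = mean_expression_score(m, gs)
        except ValidationError:
            warnings.warn(f"no {name} gene present; score omitted",
                          stacklevel=2)
    return out


def write_score_vector(scores: pd.Series, path) -> None:
    """Two-column TSV (cell_id, score)."""
    df = pd.DataFrame({"cell_id": scores.index, "score": scores.to_numpy()})
    df.to_csv(path, sep="\t", index=False)
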