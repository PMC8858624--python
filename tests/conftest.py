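import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from metasig import BulkCohort, CellAnnotation, ExpressionMatrix, GeneSet


def make_matrix(counts, genes=None, cells=None, layer="raw"):
    counts = np.asarray(counts)
    n_g, n_c = counts.shape
    genes = genes or [f"g{i}" for i in range(n_g)]
    cells = cells or [f"c{i}" for i in range(n_c)]
    return ExpressionMatrix(genes=np.array(genes, dtype=object),
                            cells=np.array(cells, dtype=object),
                            X=sp.csr_matrix(counts), layer=layer)


def make_normalized(values, genes=None, cells=None):
    return make_matrix(values, genes, cells, layer="normalized")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_raw():
    """5 genes x 4 cells deterministic raw counts."""
    counts = np.array([
        [1, 0, 3, 2],
        [0, 2, 0, 1],
        [4, 1, 1, 0],
        [0, 0, 5, 3],
        [2, 3, 0, 1],
    ])
    return make_matrix(counts)


def random_normalized(rng, n_genes=200, n_cells=60):
    """Log-normal-ish normalized matrix with no planted structure."""
    vals = np.log1p(rng.gamma(0.5, 2.0, size=(n_genes, n_cells)))
    return make_normalized(vals)


def make_cohort(expr: pd.DataFrame, groups=None, times=None, events=None):
    n = expr.shape[1]
    meta = pd.DataFrame({
        "sample": list(expr.columns),
        "metastasis_group": groups if groups is not None
        else ["LN_met"] * (n // 2) + ["non_LN_met"] * (n - n // 2),
        "time": times if times is not None else np.arange(1, n + 1, dtype=float),
        "event": events if events is not None else np.ones(n, dtype=int),
    })
    return BulkCohort(expr=expr, meta=meta)
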