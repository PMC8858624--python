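"""Readers and writers for the supported on-disk formats.

Matrix Market triplets follow the 10x convention: ``matrix.mtx`` holds the
gene x cell coordinate matrix, ``genes.tsv`` one gene id per line,
``barcodes.tsv`` one cell barcode per line.  Dense TSVs carry genes as rows
with a header row of cell ids.  A sidecar ``annotation.tsv`` (columns
``cell_id``, ``sample``, ``origin_class``, plus optional extras) is picked up
automatically when present next to the matrix.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .matrix import CellAnnotation, ExpressionMatrix, GeneSet, ValidationError


class FormatError(ValueError):
    """Malformed or inconsistent input files."""


def _read_lines(path: Path) -> list[str]:
    # tolerate 10x-style multi-column gene files (id \t symbol); first column wins
    return [ln.split("\t")[0] for ln in path.read_text().splitlines() if ln]


def read_counts(path: str | Path, fmt: str = "mtx_triplet"):
    """Read a raw count matrix.

    Parameters
    ----------
    path
        For ``mtx_triplet``: directory containing ``matrix.mtx``, ``genes.tsv``
        and ``barcodes.tsv``.  For ``dense_tsv``: the TSV file itself.

    Returns
    -------
    (ExpressionMatrix, CellAnnotation | None)
    """
    path = Path(path)
    if fmt == "mtx_triplet":
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise FormatError(f"missing {mtx}")
        X = sp.csr_matrix(scipy.io.mmread(mtx))
        genes = _read_lines(path / "genes.tsv")
        cells = _read_lines(path / "barcodes.tsv")
        if X.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix declares {X.shape} but gene/barcode files list "
                f"{len(genes)} x {len(cells)}"
            )
        ann_path = path / "annotation.tsv"
    elif fmt == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
        X = sp.csr_matrix(df.to_numpy())
        ann_path = path.with_name("annotation.tsv")
    else:
        raise FormatError(f"unknown format {fmt!r}")

    if X.nnz and (X.data < 0).any():
        raise ValidationError("negative entries in raw counts")
    if X.nnz and not np.allclose(X.data, np.round(X.data)):
        raise ValidationError("non-integer entries in raw counts")

    m = ExpressionMatrix(genes=np.array(genes, dtype=object),
                         cells=np.array(cells, dtype=object),
                         X=X, layer="raw")
    ann = read_annotation(ann_path) if ann_path.exists() else None
    return m, ann


def write_counts(m: ExpressionMatrix, path: str | Path,
                 fmt: str = "mtx_triplet",
                 annotation: CellAnnotation | None = None) -> None:
    path = Path(path)
    if fmt == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(m.X), field="integer"
                         if m.layer == "raw" else "real")
        (path / "genes.tsv").write_text("\n".join(map(str, m.genes)) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(map(str, m.cells)) + "\n")
        if annotation is not None:
            write_annotation(annotation, path / "annotation.tsv")
    elif fmt == "dense_tsv":
        path.parent.mkdir(parents=True, exist_ok=True)
        df = m.to_frame()
        if m.layer == "raw":
            df = df.astype(int)
        df.to_csv(path, sep="\t")
        if annotation is not None:
            write_annotation(annotation, path.with_name("annotation.tsv"))
    else:
        raise FormatError(f"unknown format {fmt!r}")


def read_annotation(path: str | Path) -> CellAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "sample": str})
    return CellAnnotation(df)


def write_annotation(ann: CellAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Plain text gene list, one identifier per line."""
    path = Path(path)
    genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    return GeneSet(name=name or path.stem, genes=genes)


def write_gene_list(gs: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(gs.genes) + "\n")


def read_bulk_expression(path: str | Path) -> pd.DataFrame:
    """Bulk expression TSV, genes as rows, samples as columns."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_bulk_metadata(path: str | Path) -> pd.DataFrame:
    """Bulk metadata TSV: sample, metastasis_group, time, event[, histology]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "metastasis_group", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"bulk metadata missing columns {sorted(missing)}")
    return df


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
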