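"""Readers and writers for the pipeline's tabular artifacts.

Cell maps and survival tables travel as plain CSV; expression travels
either as a MatrixMarket triplet (matrix + cell list + gene list) or as a
single dense CSV with cells as rows. All writers round-trip exactly
through the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core import (
    CellMap,
    ExpressionMatrix,
    SchemaError,
    SurvivalTable,
    ValidationError,
)

__all__ = [
    "read_cell_map",
    "write_cell_map",
    "read_expression",
    "write_expression_mtx",
    "read_survival",
    "write_survival",
    "write_json",
]

#: Fixed float format used by every CSV writer so that rerunning the
#: pipeline with the same seed produces byte-identical files.
FLOAT_FORMAT = "%.10g"


def read_cell_map(path, label_set=None) -> CellMap:
    """Read one sample's typed cell table from CSV.

    Columns are matched by header name (order-free): ``cell_id, x, y,
    cell_type, sample_id``. When ``label_set`` is given, labels outside it
    are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"cell_id": str, "sample_id": str, "cell_type": str})
    for col in CellMap.REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.where(bad)[0][0]) + 2  # 1-based, after header
            raise ValidationError(
                f"{path.name}: non-numeric {col} coordinate at line {row}"
            )
        df[col] = coerced
    if label_set is None:
        # no declared label universe: accept the observed labels
        label_set = tuple(sorted(df["cell_type"].astype(str).unique()))
    return CellMap(df[list(CellMap.REQUIRED_COLUMNS)], label_set=tuple(label_set))


def write_cell_map(cm: CellMap, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cm.cells.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_expression(path_matrix, path_cells=None, path_genes=None) -> ExpressionMatrix:
    """Read an expression matrix.

    Two layouts are accepted:

    * MatrixMarket triplet: ``path_matrix`` is an ``.mtx`` file with cells
      as rows, plus one-id-per-line cell and gene lists.
    * Dense CSV: ``path_matrix`` alone, first column cell ids, remaining
      column headers gene names.
    """
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        if path_cells is None or path_genes is None:
            raise SchemaError("MTX input needs cell and gene list files")
        mat = scipy.io.mmread(path_matrix)
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        cells = Path(path_cells).read_text().split()
        genes = Path(path_genes).read_text().split()
        if dense.shape != (len(cells), len(genes)):
            raise ValidationError(
                f"matrix is {dense.shape} but lists declare "
                f"{len(cells)} cells x {len(genes)} genes"
            )
        return ExpressionMatrix(dense, np.array(cells, dtype=object), np.array(genes, dtype=object))
    df = pd.read_csv(path_matrix, index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        df.index.astype(str).to_numpy(dtype=object),
        df.columns.astype(str).to_numpy(dtype=object),
    )


def write_expression_mtx(em: ExpressionMatrix, path_matrix, path_cells, path_genes):
    """Write an ExpressionMatrix as a MatrixMarket triplet."""
    path_matrix = Path(path_matrix)
    path_matrix.parent.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(np.asarray(em.values))
    scipy.io.mmwrite(str(path_matrix), sparse)
    Path(path_cells).write_text("\n".join(map(str, em.cell_ids)) + "\n")
    Path(path_genes).write_text("\n".join(map(str, em.genes)) + "\n")
    return path_matrix


def read_survival(path) -> SurvivalTable:
    df = pd.read_csv(path, dtype={"patient_id": str})
    return SurvivalTable(df)


def write_survival(st: SurvivalTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    st.table.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_json(obj, path) -> Path:
    """Write a JSON summary with sorted keys (stable across reruns)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
    return path
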