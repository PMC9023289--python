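"""Reading and writing matrices, label tables, coordinate tables and results.

Supported matrix formats: MatrixMarket triplets with companion ``genes.tsv`` /
``barcodes.tsv`` files (10x convention, genes x cells by default), and dense
TSV/CSV with gene ids in the first column and column ids in the header.  All
result tables are written as TSV with a header row and floats at six
significant digits, so outputs diff cleanly across platforms.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CellTypeLabels, ExpressionMatrix, SpotCoordinates

log = logging.getLogger("topicspot")

FLOAT_FORMAT = "%.6g"


def _sep_for(fmt: str) -> str:
    return "," if fmt == "csv" else "\t"


def read_matrix(
    path: str | Path,
    format: str | None = None,
    genes_file: str | Path | None = None,
    barcodes_file: str | Path | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from MTX or dense TSV/CSV.

    For MTX the companion gene and barcode files default to ``genes.tsv`` and
    ``barcodes.tsv`` next to the matrix.  ``transpose=True`` accepts the
    cells x genes dialect (the stored matrix is transposed after reading).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = suffix if suffix in ("mtx", "tsv", "csv") else "tsv"
    if format == "mtx":
        genes_file = Path(genes_file) if genes_file else path.parent / "genes.tsv"
        barcodes_file = (
            Path(barcodes_file) if barcodes_file else path.parent / "barcodes.tsv"
        )
        mat = scipy.io.mmread(str(path))
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        gene_ids = pd.read_csv(genes_file, sep="\t", header=None)[0].astype(str).tolist()
        column_ids = (
            pd.read_csv(barcodes_file, sep="\t", header=None)[0].astype(str).tolist()
        )
    elif format in ("tsv", "csv"):
        df = pd.read_csv(path, sep=_sep_for(format), index_col=0)
        values = df.to_numpy()
        gene_ids = [str(g) for g in df.index]
        column_ids = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    if transpose:
        values = values.T
        gene_ids, column_ids = column_ids, gene_ids
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("matrix contains non-numeric values")
    is_integer = bool(np.issubdtype(values.dtype, np.integer)) or bool(
        np.all(np.equal(np.mod(values, 1), 0))
    )
    return ExpressionMatrix(values, gene_ids, column_ids, is_integer=is_integer)


def write_matrix(matrix: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a matrix as MTX (+ genes.tsv/barcodes.tsv) or dense TSV/CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        sp = scipy.sparse.coo_matrix(matrix.values)
        scipy.io.mmwrite(str(path), sp)
        pd.Series(matrix.gene_ids).to_csv(
            path.parent / "genes.tsv", sep="\t", header=False, index=False
        )
        pd.Series(matrix.column_ids).to_csv(
            path.parent / "barcodes.tsv", sep="\t", header=False, index=False
        )
    elif format in ("tsv", "csv"):
        df = matrix.to_frame()
        if matrix.is_integer:
            df = df.astype(np.int64)
            df.to_csv(path, sep=_sep_for(format))
        else:
            df.to_csv(path, sep=_sep_for(format), float_format=FLOAT_FORMAT)
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def read_labels(path: str | Path, matrix: ExpressionMatrix | None = None) -> CellTypeLabels:
    """Read a (cell_id, cell_type) table; optionally validate against a matrix."""
    path = Path(path)
    sep = _sep_for(path.suffix.lower().lstrip("."))
    df = pd.read_csv(path, sep=sep)
    missing = {"cell_id", "cell_type"} - set(df.columns)
    if missing:
        raise ValueError(f"label table is missing columns: {sorted(missing)}")
    labels = CellTypeLabels(
        dict(zip(df["cell_id"].astype(str), df["cell_type"].astype(str)))
    )
    if len(labels.assignments) != len(df):
        dup = df["cell_id"][df["cell_id"].duplicated()].astype(str).tolist()
        raise ValueError(f"duplicate cell ids in label table: {dup[:10]}")
    if matrix is not None:
        labels.validate_against(matrix)
        unknown = [c for c in labels.cell_ids if c not in set(matrix.column_ids)]
        if unknown:
            log.warning("%d labeled cells are not in the matrix, e.g. %s",
                        len(unknown), unknown[:5])
    return labels


def write_labels(labels: CellTypeLabels, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"cell_id": list(labels.assignments), "cell_type": list(labels.assignments.values())}
    ).to_csv(path, sep=_sep_for(path.suffix.lower().lstrip(".")), index=False)


def read_coordinates(path: str | Path, matrix: ExpressionMatrix | None = None) -> SpotCoordinates:
    """Read a (spot_id, x, y) table; optionally validate against a matrix."""
    path = Path(path)
    sep = _sep_for(path.suffix.lower().lstrip("."))
    df = pd.read_csv(path, sep=sep)
    missing = {"spot_id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"coordinate table is missing columns: {sorted(missing)}")
    coords = SpotCoordinates(df)
    if matrix is not None:
        coords.validate_against(matrix)
    return coords


def write_coordinates(coords: SpotCoordinates, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    coords.table.to_csv(
        path, sep=_sep_for(path.suffix.lower().lstrip(".")),
        index=False, float_format=FLOAT_FORMAT,
    )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a result table as TSV with the package-wide float format."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
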