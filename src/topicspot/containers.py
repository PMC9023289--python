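"""Core in-memory containers shared by every analysis module.

The package works on three kinds of tabular objects: a genes-by-columns
expression matrix (columns are cells for a single-cell reference, spots for a
spatial slide), a per-cell cell-type label table, and a per-spot coordinate
table.  All three are thin, validated wrappers around numpy/pandas objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CellTypeLabels",
    "SpotCoordinates",
]


def _check_unique(ids, what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen[i] = 1
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))[:10]}")


@dataclass
class ExpressionMatrix:
    """Non-negative genes x columns expression matrix.

    Parameters
    ----------
    values
        Dense ``(n_genes, n_columns)`` array of non-negative values.
    gene_ids
        Row identifiers (unique, ordered).
    column_ids
        Column identifiers — cell barcodes or spot ids (unique, ordered).
    is_integer
        True when the matrix holds raw counts.
    """

    values: np.ndarray
    gene_ids: list[str]
    column_ids: list[str]
    is_integer: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.column_ids = [str(c) for c in self.column_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.column_ids)} columns"
            )
        if self.values.size and self.values.min() < 0:
            raise ValueError("expression matrix contains negative entries")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.column_ids, "column ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_columns(self) -> int:
        return len(self.column_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` in the given order (all must be present)."""
        idx = self.gene_index()
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            self.values[rows, :], list(genes), list(self.column_ids), self.is_integer
        )

    def subset_columns(self, columns: list[str]) -> "ExpressionMatrix":
        idx = {c: i for i, c in enumerate(self.column_ids)}
        missing = [c for c in columns if c not in idx]
        if missing:
            raise KeyError(f"columns absent from matrix: {missing[:10]}")
        cols = [idx[c] for c in columns]
        return ExpressionMatrix(
            self.values[:, cols], list(self.gene_ids), list(columns), self.is_integer
        )

    def column_totals(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)


@dataclass
class CellTypeLabels:
    """One cell-type label per cell; the implied one-hot matrix A is (M x N)."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        _check_unique(list(self.assignments), "cell ids")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.assignments)

    @property
    def cell_types(self) -> list[str]:
        """Sorted unique cell-type names."""
        return sorted(set(self.assignments.values()))

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Every matrix column must be labeled; extra labels are reported."""
        unlabeled = [c for c in matrix.column_ids if c not in self.assignments]
        if unlabeled:
            raise ValueError(
                f"{len(unlabeled)} matrix columns have no cell-type label, "
                f"e.g. {unlabeled[:10]}"
            )

    def onehot(self, column_ids: list[str], cell_types: list[str] | None = None) -> np.ndarray:
        """One-hot matrix A (len(column_ids) x N), row order = column_ids."""
        types = cell_types if cell_types is not None else self.cell_types
        t_idx = {t: j for j, t in enumerate(types)}
        a = np.zeros((len(column_ids), len(types)))
        for i, c in enumerate(column_ids):
            if c not in self.assignments:
                raise KeyError(f"cell {c!r} has no label")
            a[i, t_idx[self.assignments[c]]] = 1.0
        return a

    def type_frequencies(self, column_ids: list[str] | None = None) -> pd.Series:
        """Cell-type frequencies Q (sums to 1), over all labels or a subset."""
        ids = column_ids if column_ids is not None else self.cell_ids
        counts = pd.Series([self.assignments[c] for c in ids]).value_counts()
        q = counts.reindex(self.cell_types).fillna(0).astype(float)
        return q / q.sum()


@dataclass
class SpotCoordinates:
    """Array coordinates (x, y) per spot."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"spot_id", "x", "y"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"coordinate table must have columns {sorted(required)}")
        self.table = self.table.loc[:, ["spot_id", "x", "y"]].copy()
        self.table["spot_id"] = self.table["spot_id"].astype(str)
        for c in ("x", "y"):
            self.table[c] = pd.to_numeric(self.table[c], errors="raise")
        if not np.isfinite(self.table[["x", "y"]].to_numpy()).all():
            raise ValueError("coordinates contain non-finite values")
        _check_unique(self.table["spot_id"].tolist(), "spot ids")

    @property
    def spot_ids(self) -> list[str]:
        return self.table["spot_id"].tolist()

    def xy(self, spot_ids: list[str] | None = None) -> np.ndarray:
        """(n, 2) coordinate array, optionally reordered to ``spot_ids``."""
        t = self.table.set_index("spot_id")
        if spot_ids is not None:
            missing = [s for s in spot_ids if s not in t.index]
            if missing:
                raise KeyError(f"spots without coordinates: {missing[:10]}")
            t = t.loc[spot_ids]
        return t[["x", "y"]].to_numpy(dtype=float)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = [c for c in matrix.column_ids if c not in set(self.spot_ids)]
        if missing:
            raise ValueError(f"spots without coordinates: {missing[:10]}")
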