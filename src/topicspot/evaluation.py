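"""Deconvolution accuracy metrics and marker-based signature scores.

Against a known ground truth: per-spot and per-cell-type Pearson correlation,
and the presence/absence split RMSE — per spot, cell types are divided by
whether their true proportion is strictly positive, and the RMSE within the
present group measures sensitivity while the RMSE within the absent group
measures specificity.  Without ground truth, marker-gene signature scores
provide a qualitative check.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .deconvolution import SpotComposition

log = logging.getLogger("topicspot")

__all__ = [
    "align_pred_truth",
    "spot_correlation",
    "celltype_correlation",
    "presence_split_rmse",
    "signature_score",
    "summary_table",
]


def align_pred_truth(
    pred: SpotComposition, truth: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Align a prediction with a truth table (cell types x spots) by name."""
    common_types = [t for t in pred.cell_types if t in truth.index]
    if len(common_types) != len(pred.cell_types) or len(common_types) != len(truth.index):
        missing = set(pred.cell_types) ^ set(truth.index)
        raise ValueError(f"cell-type sets differ between prediction and truth: "
                         f"{sorted(missing)[:10]}")
    if set(pred.spot_ids) != set(truth.columns.astype(str)):
        raise ValueError("spot sets differ between prediction and truth")
    truth = truth.astype(float)
    truth.columns = truth.columns.astype(str)
    t = truth.loc[common_types, pred.spot_ids].to_numpy()
    p = pred.to_frame().loc[common_types].to_numpy()
    return p, t, common_types, list(pred.spot_ids)


def _pearson_cols(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r with NaN for zero-variance columns."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    num = (ac * bc).sum(axis=0)
    den = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    return r


def spot_correlation(pred: SpotComposition, truth: pd.DataFrame) -> pd.Series:
    """Per-spot Pearson r between predicted and true proportions (over types)."""
    p, t, _, spots = align_pred_truth(pred, truth)
    r = _pearson_cols(p, t)
    n_nan = int(np.isnan(r).sum())
    if n_nan:
        log.warning("%d spots have undefined correlation (zero-variance truth)",
                    n_nan)
    return pd.Series(r, index=spots, name="pearson_r")


def celltype_correlation(pred: SpotComposition, truth: pd.DataFrame) -> pd.Series:
    """Per-cell-type Pearson r between prediction and truth (across spots)."""
    p, t, types, _ = align_pred_truth(pred, truth)
    r = _pearson_cols(p.T, t.T)
    for i in np.flatnonzero(np.isnan(r)):
        log.warning("cell type %r has undefined correlation "
                    "(absent everywhere or constant)", types[i])
    return pd.Series(r, index=types, name="pearson_r")


def presence_split_rmse(pred: SpotComposition, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-spot RMSE over truly present (truth > 0) and absent cell types."""
    p, t, _, spots = align_pred_truth(pred, truth)
    err2 = (p - t) ** 2
    present = t > 0
    out = np.full((len(spots), 2), np.nan)
    for j in range(len(spots)):
        pj = present[:, j]
        if pj.any():
            out[j, 0] = np.sqrt(err2[pj, j].mean())
        if (~pj).any():
            out[j, 1] = np.sqrt(err2[~pj, j].mean())
    return pd.DataFrame(out, index=spots, columns=["rmse_present", "rmse_absent"])


def signature_score(
    st: ExpressionMatrix,
    markers: dict[str, list[str]],
    method: str = "sum",
    n_bins: int = 24,
    n_controls: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-spot signature score for each cell type's marker list.

    ``st`` is used as given (pass normalized expression for comparable
    scores).  ``sum`` adds up the marker rows; ``bin_controlled`` subtracts
    the mean of expression-matched control genes drawn from ``n_bins``
    mean-expression bins (``n_controls`` controls per marker gene), in the
    style of single-cell module scores; genes of the scored marker list are
    excluded from its own control pools.
    """
    if method not in ("sum", "bin_controlled"):
        raise ValueError(f"unknown method {method!r}")
    gene_idx = st.gene_index()
    x = np.asarray(st.values, dtype=float)
    scores: dict[str, np.ndarray] = {}
    if method == "bin_controlled":
        mean_expr = x.mean(axis=1)
        order = np.argsort(mean_expr, kind="stable")
        bin_of = np.empty(st.n_genes, dtype=int)
        bin_of[order] = np.minimum(
            np.arange(st.n_genes) * n_bins // max(1, st.n_genes), n_bins - 1
        )
        bins: dict[int, np.ndarray] = {
            b: np.flatnonzero(bin_of == b) for b in range(n_bins)
        }
        rng = np.random.default_rng(seed)
    for ctype, genes in markers.items():
        kept = [g for g in genes if g in gene_idx]
        dropped = len(genes) - len(kept)
        if dropped:
            log.warning("cell type %r: %d marker genes absent from the matrix",
                        ctype, dropped)
        if not kept:
            raise ValueError(f"no marker genes of {ctype!r} found in the matrix")
        rows = np.array([gene_idx[g] for g in kept])
        if method == "sum":
            scores[ctype] = x[rows, :].sum(axis=0)
        else:
            ctrl_rows: list[np.ndarray] = []
            in_set = np.zeros(st.n_genes, dtype=bool)
            in_set[rows] = True
            for r in rows:
                pool = bins[bin_of[r]]
                pool = pool[~in_set[pool]]
                if pool.size == 0:
                    pool = np.flatnonzero(~in_set)
                ctrl_rows.append(rng.choice(pool, size=n_controls,
                                            replace=pool.size < n_controls))
            ctrl = np.concatenate(ctrl_rows)
            scores[ctype] = x[rows, :].mean(axis=0) - x[ctrl, :].mean(axis=0)
    return pd.DataFrame(scores, index=st.column_ids)


def summary_table(per_spot_r: pd.Series, rmse: pd.DataFrame) -> pd.DataFrame:
    """Medians and quartiles of the per-spot metrics."""
    rows = {}
    for name, s in [("pearson_r", per_spot_r),
                    ("rmse_present", rmse["rmse_present"]),
                    ("rmse_absent", rmse["rmse_absent"])]:
        s = s.dropna()
        rows[name] = {
            "q25": s.quantile(0.25), "median": s.median(), "q75": s.quantile(0.75),
        }
    return pd.DataFrame(rows).T
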