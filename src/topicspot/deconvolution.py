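"""Spot deconvolution with a pre-trained topic model.

The gene-by-topic distribution learned on the single-cell reference is
frozen, and each spatial location is folded in as a new document to obtain
its topic distribution Y (K x J).  The cell-type-by-topic table then converts
topics to per-spot cell-type proportions:

    ST_nj = sum_k C_nk Y_kj

Each ST column is renormalized to sum exactly to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .preprocessing import normalize_matrix
from .topic_model import CellTypeTopicTables, TrainedTopicModel, fold_in

log = logging.getLogger("topicspot")

__all__ = [
    "SpotTopicDistribution",
    "SpotComposition",
    "infer_spot_topics",
    "deconvolve",
    "assign_dominant_celltype",
    "topic_signature_map",
    "topic_celltype_association",
    "deconvolve_matrix",
]


@dataclass
class SpotTopicDistribution:
    """Per-spot topic distribution Y (K x J); columns sum to 1."""

    Y: np.ndarray
    spot_ids: list[str]

    def __post_init__(self) -> None:
        if self.Y.shape[1] != len(self.spot_ids):
            raise ValueError("Y column count does not match spot ids")

    def to_frame(self) -> pd.DataFrame:
        topics = [f"topic_{k}" for k in range(self.Y.shape[0])]
        return pd.DataFrame(self.Y, index=topics, columns=self.spot_ids)


@dataclass
class SpotComposition:
    """Cell-type proportions per spot, ST (N x J); columns sum to 1."""

    proportions: np.ndarray
    cell_types: list[str]
    spot_ids: list[str]

    def __post_init__(self) -> None:
        if self.proportions.shape != (len(self.cell_types), len(self.spot_ids)):
            raise ValueError("proportions shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.cell_types,
                            columns=self.spot_ids)


def infer_spot_topics(
    model: TrainedTopicModel,
    st: ExpressionMatrix,
    normalized: bool = False,
    gene_sd: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> SpotTopicDistribution:
    """Fold spatial locations into the trained topic space (phi frozen).

    By default the spatial matrix is normalized with the same two-step scheme
    used for cells, with gene SDs recomputed on the spatial matrix; pass
    ``gene_sd`` to reuse the reference SDs, or ``normalized=True`` if ``st``
    is already normalized.  Spots with zero total feature expression receive
    the uniform topic distribution and are reported.
    """
    missing = set(model.feature_genes) - set(st.gene_ids)
    if missing:
        raise KeyError(
            f"spatial matrix lacks {len(missing)} model feature genes, "
            f"e.g. {sorted(missing)[:5]}"
        )
    sub = st.subset_genes(model.feature_genes)
    if not normalized:
        sub = normalize_matrix(sub, gene_sd=gene_sd)
    doc_term = np.asarray(sub.values, dtype=float).T
    zero = np.flatnonzero(doc_term.sum(axis=1) == 0)
    if zero.size:
        names = [sub.column_ids[i] for i in zero]
        log.warning("spots with zero feature expression get uniform topics: %s",
                    names[:10])
    y = fold_in(model.gene_by_topic, doc_term, model.params.alpha,
                max_iter=max_iter, tol=tol)
    return SpotTopicDistribution(Y=y, spot_ids=list(sub.column_ids))


def deconvolve(
    C: np.ndarray,
    y: SpotTopicDistribution,
    cell_types: list[str],
) -> SpotComposition:
    """Convert topic distributions to cell-type proportions: ST = C Y."""
    if C.shape[1] != y.Y.shape[0]:
        raise ValueError("C and Y disagree on the number of topics")
    st = C @ y.Y
    st = st / st.sum(axis=0, keepdims=True)
    return SpotComposition(proportions=st, cell_types=list(cell_types),
                           spot_ids=list(y.spot_ids))


def assign_dominant_celltype(comp: SpotComposition) -> pd.Series:
    """Per-spot argmax cell type; ties broken by lexicographic name."""
    order = np.argsort(np.array(comp.cell_types, dtype=object), kind="stable")
    winners = order[np.argmax(comp.proportions[order, :], axis=0)]
    return pd.Series([comp.cell_types[i] for i in winners],
                     index=comp.spot_ids, name="dominant_celltype")


def topic_signature_map(y: SpotTopicDistribution, topic_subset: list[int]) -> pd.Series:
    """Per-spot summed probability of a set of topics (a cell-type signature)."""
    if not topic_subset:
        raise ValueError("topic_subset must be non-empty")
    k = y.Y.shape[0]
    bad = [t for t in topic_subset if t < 0 or t >= k]
    if bad:
        raise KeyError(f"unknown topic ids: {bad}")
    return pd.Series(y.Y[list(topic_subset), :].sum(axis=0), index=y.spot_ids,
                     name="signature")


def topic_celltype_association(tables: CellTypeTopicTables) -> dict[str, list[int]]:
    """Associate each topic with its argmax cell type in C; returns
    cell type -> list of associated topic indices."""
    owner = np.argmax(tables.C, axis=0)
    assoc: dict[str, list[int]] = {t: [] for t in tables.cell_types}
    for k, n in enumerate(owner):
        assoc[tables.cell_types[n]].append(int(k))
    return assoc


def deconvolve_matrix(
    model: TrainedTopicModel,
    tables: CellTypeTopicTables,
    st: ExpressionMatrix,
    gene_sd: np.ndarray | None = None,
) -> tuple[SpotTopicDistribution, SpotComposition]:
    """Convenience wrapper: fold in spots, then convert to proportions."""
    y = infer_spot_topics(model, st, gene_sd=gene_sd)
    comp = deconvolve(tables.C, y, tables.cell_types)
    return y, comp
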