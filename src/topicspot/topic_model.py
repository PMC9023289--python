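"""LDA topic training on single-cell references and cell-type topic tables.

Cells are treated as documents and genes as words.  A latent Dirichlet
allocation model is fitted with the online variational Bayes algorithm
(scikit-learn's implementation), yielding the gene-by-topic distribution phi
(K x V) and, through a variational fold-in E-step with phi frozen, the
topic-by-cell distribution Z (K x M).  Normalized, non-integer expression is
accepted as fractional token weights.

With user-provided labels the topic-by-cell-type table T averages Z within
each cell type:

    T_kn = sum_m Z_km A_mn / sum_m A_mn

and Bayes' theorem inverts it to the cell-type-by-topic table

    C_nk = T_kn Q_n / P_k,   P_k = sum_n T_kn Q_n,

where Q_n is the cell-type prior (reference label frequencies by default).
Re-annotating the reference cells through SC = C Z gives a re-annotation
accuracy used to pick the topic number: the model with the highest accuracy
wins, and ties go to the smallest K.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import psi
from sklearn.decomposition import LatentDirichletAllocation

from .containers import CellTypeLabels, ExpressionMatrix
from . import io as tio

log = logging.getLogger("topicspot")

__all__ = [
    "TopicModelParams",
    "TrainedTopicModel",
    "CellTypeTopicTables",
    "train_lda",
    "fold_in",
    "compute_T",
    "compute_C",
    "annotate_cells",
    "pick_best_k",
    "select_topic_number",
    "save_model",
    "load_model",
]


@dataclass
class TopicModelParams:
    """Hyper-parameters of the LDA model.

    alpha is the symmetric Dirichlet prior weight on the K topic proportions
    of a cell (default 1/K); beta the symmetric prior weight on the V gene
    probabilities of a topic (default 0.01).
    """

    n_topics: int
    alpha: float | None = None
    beta: float = 0.01
    passes: int = 20
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 2:
            raise ValueError("n_topics must be >= 2")
        if self.alpha is None:
            self.alpha = 1.0 / self.n_topics
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


@dataclass
class TrainedTopicModel:
    """Fitted topic model: phi (K x V) plus topic weights of the training cells."""

    gene_by_topic: np.ndarray  # phi, rows sum to 1
    topic_by_cell: np.ndarray  # Z, columns sum to 1
    params: TopicModelParams
    feature_genes: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        k, v = self.gene_by_topic.shape
        if k != self.params.n_topics or v != len(self.feature_genes):
            raise ValueError("gene_by_topic shape does not match params/genes")
        if self.topic_by_cell.shape != (k, len(self.cell_ids)):
            raise ValueError("topic_by_cell shape mismatch")

    @property
    def n_topics(self) -> int:
        return self.params.n_topics


@dataclass
class CellTypeTopicTables:
    """Topic/cell-type tables T (K x N), C (N x K), prior Q (N), marginal P (K)."""

    T: np.ndarray
    C: np.ndarray
    Q: np.ndarray
    P: np.ndarray
    cell_types: list[str]


def _doc_term(m: ExpressionMatrix, feature_genes: list[str]) -> np.ndarray:
    """Documents-by-terms view (columns become rows) on the feature space."""
    sub = m.subset_genes(feature_genes)
    return np.asarray(sub.values, dtype=float).T


def fold_in(
    phi: np.ndarray,
    doc_term: np.ndarray,
    alpha: float,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> np.ndarray:
    """Variational E-step with frozen topics: per-document topic weights.

    Standard coordinate-ascent fold-in: gamma_k = alpha + sum_v n_v phi_kv
    exp(psi(gamma_k)) / sum_k' phi_k'v exp(psi(gamma_k')), iterated until the
    mean absolute change in the normalized distribution falls below ``tol``.
    Documents with zero total weight get the uniform distribution.

    Returns a (K x n_docs) matrix with columns summing to 1.
    """
    n_docs, n_terms = doc_term.shape
    k = phi.shape[0]
    if phi.shape[1] != n_terms:
        raise ValueError("phi and document matrix disagree on vocabulary size")
    phi = np.maximum(phi, 1e-12)
    gamma = np.full((n_docs, k), alpha + doc_term.sum(axis=1, keepdims=True) / k)
    empty = doc_term.sum(axis=1) == 0
    theta = gamma / gamma.sum(axis=1, keepdims=True)
    for _ in range(max_iter):
        exp_elog = np.exp(psi(gamma) - psi(gamma.sum(axis=1, keepdims=True)))
        denom = exp_elog @ phi  # (n_docs, V)
        np.maximum(denom, 1e-100, out=denom)
        gamma = alpha + exp_elog * ((doc_term / denom) @ phi.T)
        theta_new = gamma / gamma.sum(axis=1, keepdims=True)
        change = np.abs(theta_new - theta).mean()
        theta = theta_new
        if change < tol:
            break
    if empty.any():
        theta[empty, :] = 1.0 / k
    return theta.T


def train_lda(m: ExpressionMatrix, params: TopicModelParams) -> TrainedTopicModel:
    """Fit LDA by online variational Bayes on a normalized feature matrix.

    ``m`` must already be restricted to the feature gene set.  Training is
    deterministic for a fixed seed.
    """
    if m.n_columns == 0 or m.n_genes == 0:
        raise ValueError("cannot train on an empty matrix")
    if params.n_topics >= m.n_columns:
        raise ValueError(
            f"n_topics={params.n_topics} must be smaller than the number of "
            f"cells ({m.n_columns})"
        )
    doc_term = np.asarray(m.values, dtype=float).T  # cells x genes
    lda = LatentDirichletAllocation(
        n_components=params.n_topics,
        doc_topic_prior=params.alpha,
        topic_word_prior=params.beta,
        learning_method="online",
        batch_size=params.batch_size,
        max_iter=params.passes,
        random_state=params.seed,
    )
    lda.fit(doc_term)
    phi = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    z = fold_in(phi, doc_term, params.alpha)
    return TrainedTopicModel(
        gene_by_topic=phi,
        topic_by_cell=z,
        params=params,
        feature_genes=list(m.gene_ids),
        cell_ids=list(m.column_ids),
    )


def compute_T(
    Z: np.ndarray, labels: CellTypeLabels, cell_ids: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Topic-by-cell-type table: mean topic weight over the cells of each type."""
    types = labels.cell_types
    a = labels.onehot(cell_ids, types)  # M x N
    counts = a.sum(axis=0)
    empty = [types[i] for i in np.flatnonzero(counts == 0)]
    if empty:
        raise ValueError(f"cell types with zero cells: {empty}")
    t = (Z @ a) / counts  # K x N
    return t, types


def compute_Q(labels: CellTypeLabels, cell_ids: list[str] | None = None) -> np.ndarray:
    """Cell-type prior from reference label frequencies (sums to 1)."""
    return labels.type_frequencies(cell_ids).to_numpy()


def compute_C(T: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bayes inversion: C_nk = T_kn Q_n / P_k with P_k = sum_n T_kn Q_n."""
    Q = np.asarray(Q, dtype=float)
    if not np.isclose(Q.sum(), 1.0):
        raise ValueError("Q must sum to 1")
    if (Q <= 0).any():
        raise ValueError("Q must be strictly positive")
    P = T @ Q  # (K,)
    if (P <= 0).any():
        bad = np.flatnonzero(P <= 0).tolist()
        raise ValueError(f"topics unused by every cell type: {bad}")
    C = (T * Q[None, :]).T / P[None, :]  # N x K
    return C, P


def make_tables(
    model: TrainedTopicModel,
    labels: CellTypeLabels,
    Q: np.ndarray | None = None,
) -> CellTypeTopicTables:
    """Compute T, C, Q, P from a trained model and reference labels."""
    T, types = compute_T(model.topic_by_cell, labels, model.cell_ids)
    q = compute_Q(labels, model.cell_ids) if Q is None else np.asarray(Q, dtype=float)
    C, P = compute_C(T, q)
    return CellTypeTopicTables(T=T, C=C, Q=q, P=P, cell_types=types)


def annotate_cells(
    C: np.ndarray, Z: np.ndarray, cell_types: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Per-cell type probabilities SC = C Z and argmax labels.

    Argmax ties are broken by lexicographic cell-type name.
    """
    if C.shape[1] != Z.shape[0]:
        raise ValueError("C and Z disagree on the number of topics")
    sc = C @ Z  # N x M
    order = np.argsort(np.array(cell_types, dtype=object), kind="stable")
    winners = order[np.argmax(sc[order, :], axis=0)]
    labels = [cell_types[i] for i in winners]
    return sc, labels


def reannotation_accuracy(
    model: TrainedTopicModel, labels: CellTypeLabels, tables: CellTypeTopicTables
) -> float:
    """Fraction of reference cells whose re-annotation matches their label."""
    _, predicted = annotate_cells(tables.C, model.topic_by_cell, tables.cell_types)
    truth = [labels.assignments[c] for c in model.cell_ids]
    return float(np.mean([p == t for p, t in zip(predicted, truth)]))


def pick_best_k(accuracies: dict[int, float]) -> int:
    """Highest accuracy wins; exact ties go to the smallest topic number."""
    finite = {k: a for k, a in accuracies.items() if np.isfinite(a)}
    if not finite:
        raise ValueError("no candidate topic number produced a finite accuracy")
    best = max(finite.values())
    return min(k for k, a in finite.items() if a == best)


def select_topic_number(
    m: ExpressionMatrix,
    labels: CellTypeLabels,
    candidate_Ks: list[int],
    alpha: float | None = None,
    beta: float = 0.01,
    passes: int = 20,
    batch_size: int = 256,
    seed: int = 0,
) -> tuple[TrainedTopicModel, CellTypeTopicTables, pd.DataFrame]:
    """Train one model per candidate K and keep the best re-annotating one."""
    if not candidate_Ks:
        raise ValueError("candidate_Ks must be non-empty")
    models: dict[int, tuple[TrainedTopicModel, CellTypeTopicTables]] = {}
    accuracies: dict[int, float] = {}
    for k in sorted(set(candidate_Ks)):
        params = TopicModelParams(n_topics=k, alpha=alpha, beta=beta,
                                  passes=passes, batch_size=batch_size, seed=seed)
        model = train_lda(m, params)
        tables = make_tables(model, labels)
        acc = reannotation_accuracy(model, labels, tables)
        models[k] = (model, tables)
        accuracies[k] = acc
        log.info("topic number K=%d: re-annotation accuracy %.4f (seed=%d)",
                 k, acc, seed)
    best_k = pick_best_k(accuracies)
    table = pd.DataFrame(
        {"n_topics": list(accuracies), "accuracy": list(accuracies.values())}
    ).set_index("n_topics")
    table["selected"] = [k == best_k for k in table.index]
    model, tables = models[best_k]
    return model, tables, table


def default_candidate_ks(n_cell_types: int) -> list[int]:
    """Default topic-number grid: N, ceil(1.5N), 2N, 3N (deduplicated)."""
    n = n_cell_types
    ks = sorted({max(2, n), max(2, int(np.ceil(1.5 * n))), max(2, 2 * n), max(2, 3 * n)})
    return ks


def save_model(
    model: TrainedTopicModel,
    tables: CellTypeTopicTables | None,
    outdir: str | Path,
) -> None:
    """Write phi, Z (and T, C, Q, P when available) as TSV plus params.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    topics = [f"topic_{k}" for k in range(model.n_topics)]
    tio.write_table(
        pd.DataFrame(model.gene_by_topic, index=topics, columns=model.feature_genes),
        outdir / "gene_by_topic.tsv",
    )
    tio.write_table(
        pd.DataFrame(model.topic_by_cell, index=topics, columns=model.cell_ids),
        outdir / "topic_by_cell.tsv",
    )
    meta = {
        "n_topics": model.params.n_topics,
        "alpha": model.params.alpha,
        "beta": model.params.beta,
        "passes": model.params.passes,
        "batch_size": model.params.batch_size,
        "seed": model.params.seed,
    }
    (outdir / "params.json").write_text(json.dumps(meta, indent=1))
    if tables is not None:
        tio.write_table(
            pd.DataFrame(tables.T, index=topics, columns=tables.cell_types),
            outdir / "topic_by_celltype.tsv",
        )
        tio.write_table(
            pd.DataFrame(tables.C, index=tables.cell_types, columns=topics),
            outdir / "celltype_by_topic.tsv",
        )
        tio.write_table(
            pd.DataFrame({"Q": tables.Q}, index=tables.cell_types),
            outdir / "celltype_prior.tsv",
        )
        tio.write_table(
            pd.DataFrame({"P": tables.P}, index=topics), outdir / "topic_marginal.tsv"
        )


def load_model(outdir: str | Path) -> tuple[TrainedTopicModel, CellTypeTopicTables | None]:
    """Reload a model directory written by :func:`save_model`."""
    outdir = Path(outdir)
    meta = json.loads((outdir / "params.json").read_text())
    phi = tio.read_table(outdir / "gene_by_topic.tsv")
    z = tio.read_table(outdir / "topic_by_cell.tsv")
    params = TopicModelParams(
        n_topics=meta["n_topics"], alpha=meta["alpha"], beta=meta["beta"],
        passes=meta["passes"], batch_size=meta["batch_size"], seed=meta["seed"],
    )
    model = TrainedTopicModel(
        gene_by_topic=phi.to_numpy(),
        topic_by_cell=z.to_numpy(),
        params=params,
        feature_genes=[str(g) for g in phi.columns],
        cell_ids=[str(c) for c in z.columns],
    )
    tables = None
    tpath = outdir / "topic_by_celltype.tsv"
    if tpath.exists():
        t = tio.read_table(tpath)
        c = tio.read_table(outdir / "celltype_by_topic.tsv")
        q = tio.read_table(outdir / "celltype_prior.tsv")["Q"].to_numpy()
        p = tio.read_table(outdir / "topic_marginal.tsv")["P"].to_numpy()
        tables = CellTypeTopicTables(
            T=t.to_numpy(), C=c.to_numpy(), Q=q, P=p,
            cell_types=[str(x) for x in t.columns],
        )
    return model, tables
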