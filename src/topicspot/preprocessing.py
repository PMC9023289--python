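"""Feature-space construction and normalization.

Topic training and spot inference share one feature space: the genes common
to the single-cell reference and the spatial slide, optionally narrowed to
cell-type marker genes (one-vs-rest Wilcoxon rank-sum), highly variable
genes, or their union.  Counts are normalized in two steps: per-column depth
scaling to a fixed total (counts-per-10k by default) followed by per-gene
division by the population standard deviation.  No centering is applied, so
the normalized matrix stays non-negative and can be fed to the topic model
as fractional token weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import CellTypeLabels, ExpressionMatrix

log = logging.getLogger("topicspot")

__all__ = [
    "FeatureGeneSet",
    "intersect_genes",
    "normalize_matrix",
    "select_marker_genes",
    "select_hvgs",
    "build_feature_set",
]


@dataclass
class FeatureGeneSet:
    """An ordered gene list selected for topic training.

    ``markers`` maps each cell type to its ranked marker list when the mode
    includes marker selection.
    """

    mode: str
    genes: list[str]
    markers: dict[str, list[str]] | None = None
    n_top: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("all", "markers", "hvg", "markers_plus_hvg"):
            raise ValueError(f"unknown feature mode {self.mode!r}")
        if not self.genes:
            raise ValueError("feature gene set is empty")


def intersect_genes(sc: ExpressionMatrix, st: ExpressionMatrix) -> list[str]:
    """Sorted list of genes shared by the reference and the spatial matrix."""
    common = sorted(set(sc.gene_ids) & set(st.gene_ids))
    if not common:
        raise ValueError(
            "no genes shared between single-cell and spatial matrices "
            "(species or annotation mismatch?)"
        )
    return common


def _depth_scale(values: np.ndarray, column_ids: list[str], scale_factor: float) -> np.ndarray:
    totals = values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [column_ids[i] for i in zero]
        raise ValueError(f"columns with zero total count: {names[:10]}")
    return values / totals * scale_factor


def normalize_matrix(
    m: ExpressionMatrix,
    scale_factor: float = 1e4,
    gene_sd: np.ndarray | None = None,
    return_sd: bool = False,
):
    """Depth-scale each column, then divide each gene row by its SD.

    The per-gene standard deviation is the population SD (ddof=0) of the
    depth-scaled values; rows with zero variance are set to zero.  Pass
    ``gene_sd`` (e.g. the SDs estimated on the single-cell reference) to
    reuse scaling factors across matrices.
    """
    x = _depth_scale(np.asarray(m.values, dtype=float), m.column_ids, scale_factor)
    if gene_sd is None:
        sd = x.std(axis=1, ddof=0)
    else:
        sd = np.asarray(gene_sd, dtype=float)
        if sd.shape != (m.n_genes,):
            raise ValueError("gene_sd length does not match number of genes")
    out = np.zeros_like(x)
    nz = sd > 0
    out[nz, :] = x[nz, :] / sd[nz, None]
    result = ExpressionMatrix(out, list(m.gene_ids), list(m.column_ids), is_integer=False)
    if return_sd:
        return result, sd
    return result


def _rank_genes(
    x_in: np.ndarray, x_out: np.ndarray, gene_ids: list[str]
) -> list[tuple[str, float, float]]:
    """Rank genes up-regulated in ``x_in`` vs ``x_out`` by one-sided Wilcoxon
    rank-sum p-value; ties broken by descending log2 fold change, then id."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant rows yield exact-tie warnings
        res = stats.mannwhitneyu(x_in, x_out, axis=1, alternative="greater",
                                 method="asymptotic")
    pvals = np.asarray(res.pvalue)
    eps = 1e-9
    lfc = np.log2((x_in.mean(axis=1) + eps) / (x_out.mean(axis=1) + eps))
    order = sorted(
        range(len(gene_ids)), key=lambda i: (pvals[i], -lfc[i], gene_ids[i])
    )
    return [(gene_ids[i], float(pvals[i]), float(lfc[i])) for i in order]


def select_marker_genes(
    sc: ExpressionMatrix,
    labels: CellTypeLabels,
    n_top: int = 100,
    contrasts: dict[str, list[str]] | None = None,
    scale_factor: float = 1e4,
    min_cells: int = 3,
) -> FeatureGeneSet:
    """Per-cell-type marker genes by one-vs-rest Wilcoxon rank-sum test.

    ``contrasts`` optionally restricts the background of a cell type to a
    stated subset of other types (useful for transcriptionally similar types
    that should be contrasted only against each other).
    """
    labels.validate_against(sc)
    types = labels.cell_types
    if len(types) < 2:
        raise ValueError("marker selection needs at least two cell types")
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top > sc.n_genes:
        log.warning("n_top=%d exceeds gene count %d; returning full rankings",
                    n_top, sc.n_genes)
        n_top = sc.n_genes
    norm = normalize_matrix(sc, scale_factor=scale_factor)
    col_types = np.array([labels.assignments[c] for c in sc.column_ids])
    markers: dict[str, list[str]] = {}
    for t in types:
        in_mask = col_types == t
        if in_mask.sum() < min_cells:
            log.warning("cell type %r has fewer than %d cells; skipped", t, min_cells)
            continue
        if contrasts and t in contrasts:
            bg = set(contrasts[t])
            out_mask = np.isin(col_types, list(bg)) & ~in_mask
            if not out_mask.any():
                raise ValueError(f"contrast set for {t!r} matches no cells")
        else:
            out_mask = ~in_mask
        ranking = _rank_genes(norm.values[:, in_mask], norm.values[:, out_mask],
                              norm.gene_ids)
        markers[t] = [g for g, _, _ in ranking[:n_top]]
    if not markers:
        raise ValueError("no cell type had enough cells for marker selection")
    union = sorted(set().union(*markers.values()))
    return FeatureGeneSet(mode="markers", genes=union, markers=markers, n_top=n_top)


def select_hvgs(
    sc: ExpressionMatrix, n_top: int = 2000, scale_factor: float = 1e4
) -> FeatureGeneSet:
    """Highly variable genes ranked by variance-to-mean dispersion of
    depth-scaled counts."""
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top > sc.n_genes:
        log.warning("n_top=%d exceeds gene count %d; clamped", n_top, sc.n_genes)
        n_top = sc.n_genes
    x = _depth_scale(np.asarray(sc.values, dtype=float), sc.column_ids, scale_factor)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = sorted(range(sc.n_genes), key=lambda i: (-disp[i], sc.gene_ids[i]))
    genes = sorted(sc.gene_ids[i] for i in order[:n_top])
    return FeatureGeneSet(mode="hvg", genes=genes, n_top=n_top)


def build_feature_set(
    sc: ExpressionMatrix,
    st: ExpressionMatrix,
    labels: CellTypeLabels | None = None,
    mode: str = "markers",
    n_top_markers: int = 100,
    n_top_hvgs: int = 2000,
    contrasts: dict[str, list[str]] | None = None,
) -> FeatureGeneSet:
    """Build the training feature set restricted to the shared gene space."""
    common = intersect_genes(sc, st)
    sc_common = sc.subset_genes(common)
    if mode == "all":
        return FeatureGeneSet(mode="all", genes=common)
    if mode == "hvg":
        fs = select_hvgs(sc_common, n_top=n_top_hvgs)
        return fs
    if labels is None:
        raise ValueError("marker modes require cell-type labels")
    mk = select_marker_genes(sc_common, labels, n_top=n_top_markers, contrasts=contrasts)
    if mode == "markers":
        return mk
    if mode == "markers_plus_hvg":
        hv = select_hvgs(sc_common, n_top=n_top_hvgs)
        genes = sorted(set(mk.genes) | set(hv.genes))
        return FeatureGeneSet(mode="markers_plus_hvg", genes=genes,
                              markers=mk.markers, n_top=n_top_markers)
    raise ValueError(f"unknown feature mode {mode!r}")
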