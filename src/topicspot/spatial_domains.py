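"""Deconvolution-driven spatial domains and cell-to-spot mapping.

Spatial domains are found by k-means on the concatenation of each spot's own
cell-type composition and the mean composition of its neighborhood, with a
weight balancing the two.  Given a tumor-core cluster, the remaining spots
are split by their Euclidean distance (array units) to the nearest core spot
into an edge ring, a border band, and stroma.  Single cells can be mapped
back into spots by cosine similarity of topic profiles, in proportion to the
deconvolved composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .containers import ExpressionMatrix, SpotCoordinates
from .deconvolution import SpotComposition, SpotTopicDistribution

log = logging.getLogger("topicspot")

__all__ = [
    "CellMapping",
    "neighborhood_composition",
    "cluster_domains",
    "define_regions",
    "largest_remainder_quota",
    "map_cells_to_spots",
]


def neighborhood_composition(
    comp: SpotComposition,
    coords: SpotCoordinates,
    k_neighbors: int = 6,
    radius: float | None = None,
) -> np.ndarray:
    """Mean composition over each spot's neighbors (self excluded).

    Neighbors are the ``k_neighbors`` nearest spots (hex-grid degree 6 by
    default) or, if ``radius`` is given, all spots within that distance.
    A spot with no neighbors keeps its own composition.
    """
    xy = coords.xy(comp.spot_ids)
    n = len(comp.spot_ids)
    out = np.empty_like(comp.proportions)
    if n == 1:
        return comp.proportions.copy()
    tree = cKDTree(xy)
    if radius is not None:
        neighbor_lists = tree.query_ball_point(xy, r=radius)
        for j, nb in enumerate(neighbor_lists):
            nb = [i for i in nb if i != j]
            out[:, j] = (comp.proportions[:, nb].mean(axis=1) if nb
                         else comp.proportions[:, j])
    else:
        k = min(k_neighbors + 1, n)
        _, idx = tree.query(xy, k=k)
        for j in range(n):
            nb = [i for i in np.atleast_1d(idx[j]) if i != j][: k_neighbors]
            out[:, j] = (comp.proportions[:, nb].mean(axis=1) if nb
                         else comp.proportions[:, j])
    return out


def cluster_domains(
    comp: SpotComposition,
    coords: SpotCoordinates,
    k_clusters: int = 6,
    weight: float = 0.5,
    k_neighbors: int = 6,
    radius: float | None = None,
    seed: int = 0,
) -> pd.Series:
    """K-means spatial domains on [weight * own, (1-weight) * neighborhood].

    ``weight=0.5`` gives the two factors equal weight; ``weight=1`` reduces to
    clustering on composition alone.  Deterministic for a fixed seed.
    """
    if k_clusters < 2:
        raise ValueError("k_clusters must be >= 2")
    if k_clusters > len(comp.spot_ids):
        raise ValueError("k_clusters exceeds the number of spots")
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    neigh = neighborhood_composition(comp, coords, k_neighbors=k_neighbors,
                                     radius=radius)
    feats = np.vstack([weight * comp.proportions, (1.0 - weight) * neigh]).T
    km = KMeans(n_clusters=k_clusters, random_state=seed, n_init=10)
    ids = km.fit_predict(feats)
    return pd.Series(ids, index=comp.spot_ids, name="cluster")


def define_regions(
    clusters: pd.Series,
    coords: SpotCoordinates,
    core_cluster: int,
    threshold: float = 4.0,
    edge_radius: float = 2.0,
) -> pd.DataFrame:
    """Label spots core / edge / border / stroma by distance to the core.

    Non-core spots within ``edge_radius`` of the nearest core spot form the
    edge ring; beyond that, spots at distance <= ``threshold`` are border
    (distance exactly at the threshold counts as border) and the rest stroma.
    """
    spot_ids = list(clusters.index)
    xy = coords.xy(spot_ids)
    core_mask = (clusters == core_cluster).to_numpy()
    if not core_mask.any():
        raise ValueError(f"core cluster {core_cluster} is empty")
    tree = cKDTree(xy[core_mask])
    dist, _ = tree.query(xy)
    dist = np.where(core_mask, 0.0, dist)
    region = np.where(
        core_mask, "core",
        np.where(dist <= edge_radius, "edge",
                 np.where(dist <= threshold, "border", "stroma")),
    )
    return pd.DataFrame(
        {"cluster": clusters.to_numpy(), "region": region, "distance_to_core": dist},
        index=spot_ids,
    )


def largest_remainder_quota(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer quotas proportional to ``proportions`` summing to ``total``."""
    p = np.asarray(proportions, dtype=float)
    if p.sum() <= 0:
        raise ValueError("proportions must have positive sum")
    quota = p / p.sum() * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    if short > 0:
        remainder = quota - counts
        order = np.lexsort((np.arange(len(p)), -remainder))
        counts[order[:short]] += 1
    return counts


@dataclass
class CellMapping:
    """Cells selected for each spot and optional pooled per-type expression."""

    selected: dict[str, list[str]]  # spot id -> cell ids (with multiplicity)
    pooled: dict[str, pd.DataFrame] | None = None  # cell type -> genes x spots


def map_cells_to_spots(
    cell_Z: np.ndarray,
    cell_ids: list[str],
    cell_types_of: dict[str, str],
    spot_Y: SpotTopicDistribution,
    comp: SpotComposition,
    sc: ExpressionMatrix | None = None,
    n_cells: int = 10,
    seed: int = 0,
) -> CellMapping:
    """Select the most similar reference cells for each spot.

    Per spot, each cell type receives a quota of ``round(n_cells x
    proportion)`` cells (largest-remainder corrected to sum to ``n_cells``);
    within a type, cells are ranked by cosine similarity between their topic
    profile and the spot's, ties broken by cell id.  If a quota exceeds the
    available cells the ranked list is recycled (sampling with replacement).
    When ``sc`` is provided, the raw counts of the selected cells are pooled
    per cell type.
    """
    if cell_Z.shape[0] != spot_Y.Y.shape[0]:
        raise ValueError("cell and spot topic spaces differ (different model?)")
    if cell_Z.shape[1] != len(cell_ids):
        raise ValueError("cell_Z column count does not match cell ids")
    norms = np.linalg.norm(cell_Z, axis=0)
    norms[norms == 0] = 1.0
    zn = cell_Z / norms
    by_type: dict[str, list[int]] = {}
    for i, c in enumerate(cell_ids):
        by_type.setdefault(cell_types_of[c], []).append(i)
    selected: dict[str, list[str]] = {}
    pooled_acc: dict[str, np.ndarray] = {}
    if sc is not None:
        col_of = {c: i for i, c in enumerate(sc.column_ids)}
    for j, spot in enumerate(comp.spot_ids):
        quotas = largest_remainder_quota(comp.proportions[:, j], n_cells)
        yv = spot_Y.Y[:, j]
        yn = yv / (np.linalg.norm(yv) or 1.0)
        picks: list[str] = []
        for t, q in zip(comp.cell_types, quotas):
            if q == 0:
                continue
            pool = by_type.get(t, [])
            if not pool:
                log.warning("no reference cells of type %r; quota dropped", t)
                continue
            sims = zn[:, pool].T @ yn
            order = sorted(range(len(pool)),
                           key=lambda i: (-sims[i], cell_ids[pool[i]]))
            if q > len(pool):
                log.warning("type %r quota %d exceeds %d available cells; "
                            "recycling ranked cells", t, q, len(pool))
            ranked = [cell_ids[pool[i]] for i in order]
            picks_t = [ranked[i % len(ranked)] for i in range(q)]
            picks.extend(picks_t)
            if sc is not None:
                acc = pooled_acc.setdefault(
                    t, np.zeros((sc.n_genes, len(comp.spot_ids))))
                for cid in picks_t:
                    acc[:, j] += sc.values[:, col_of[cid]]
        selected[spot] = picks
    pooled = None
    if sc is not None:
        pooled = {
            t: pd.DataFrame(v, index=sc.gene_ids, columns=comp.spot_ids)
            for t, v in pooled_acc.items()
        }
    return CellMapping(selected=selected, pooled=pooled)
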