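"""Serial-section alignment from topic profiles and 3D stacking.

Two adjacent slides are coupled by fused Gromov–Wasserstein optimal
transport: with topic profiles X (p x n), X' (p x n'), intra-slide distance
matrices D, D' and a balance parameter lambda in [0, 1], the coupling Pi
with uniform marginals minimizes

    F(Pi) = (1 - lambda) * sum_ij c(X_.i, X'_.j) Pi_ij
          + lambda * sum_ijkl (D_ik - D'_jl)^2 Pi_ij Pi_kl.

lambda = 0 considers only topic similarity (plain linear OT); lambda = 1
only the preservation of intra-slide spot distances.  The problem is solved
by conditional-gradient (Frank–Wolfe) iterations whose linearized subproblem
is an exact linear-programming optimal transport solve.

A coupling between matched slides then yields the rigid transform (rotation
R with det(R) = +1 and translation v) minimizing the coupling-weighted
squared distances between matched spots, in closed form via SVD (weighted
Procrustes).  Chaining pairwise transforms stacks an ordered series of
slides into one coordinate frame with a z step per section.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

log = logging.getLogger("topicspot")

__all__ = [
    "SlideLayer",
    "LayerMapping",
    "RigidTransform",
    "fgw_cost",
    "pairwise_align",
    "procrustes_pair",
    "stack_layers",
]


@dataclass
class SlideLayer:
    """One slide: topic profiles X (p x n), 2D coordinates (2 x n), ids."""

    topic_profiles: np.ndarray
    coords: np.ndarray
    spot_ids: list[str]
    slide_id: str = ""
    z_index: int = 0

    def __post_init__(self) -> None:
        self.topic_profiles = np.asarray(self.topic_profiles, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.spot_ids)
        if self.topic_profiles.shape[1] != n:
            raise ValueError("topic profile column count != number of spots")
        if self.coords.shape != (2, n):
            raise ValueError("coords must be 2 x n")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def distance_matrix(self) -> np.ndarray:
        """Intra-slide Euclidean spot-distance matrix (symmetric, zero diag)."""
        return cdist(self.coords.T, self.coords.T)


@dataclass
class LayerMapping:
    """Coupling between two slides with the achieved transport cost."""

    coupling: np.ndarray
    cost: float
    balance: float
    converged: bool = True


@dataclass
class RigidTransform:
    """Proper rotation + translation mapping one slide into another's frame."""

    R: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.R.T @ self.R, np.eye(2), atol=1e-10):
            raise ValueError("R is not orthogonal")
        if np.linalg.det(self.R) < 0:
            raise ValueError("R is a reflection, not a rotation")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform a 2 x n coordinate matrix."""
        return self.R @ coords + self.v[:, None]


def _feature_cost(x: np.ndarray, y: np.ndarray, kind: str) -> np.ndarray:
    """Pairwise topic-profile dissimilarity matrix (n x n')."""
    if kind == "sqeuclidean":
        return cdist(x.T, y.T, metric="sqeuclidean")
    if kind == "cosine":
        return cdist(x.T, y.T, metric="cosine")
    if kind == "kl":
        eps = 1e-12
        xs = np.clip(x, eps, None)
        ys = np.clip(y, eps, None)
        # KL(col_i || col_j), smoothed
        return (xs * np.log(xs)).sum(axis=0)[:, None] - xs.T @ np.log(ys)
    raise ValueError(f"unknown topic cost {kind!r}")


def _emd(p: np.ndarray, q: np.ndarray, cost: np.ndarray) -> np.ndarray:
    """Exact linear-OT solve: min <cost, Pi> s.t. Pi 1 = p, Pi^T 1 = q."""
    n, m = cost.shape
    a_rows = scipy.sparse.kron(scipy.sparse.eye(n), np.ones((1, m))).tocsr()
    a_cols = scipy.sparse.kron(np.ones((1, n)), scipy.sparse.eye(m)).tocsr()
    # drop the last column constraint (redundant given the row constraints)
    a_eq = scipy.sparse.vstack([a_rows, a_cols[:-1]]).tocsr()
    b_eq = np.concatenate([p, q[:-1]])
    res = linprog(cost.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None),
                  method="highs")
    if not res.success:
        raise RuntimeError(f"linear OT subproblem failed: {res.message}")
    return res.x.reshape(n, m)


def _gw_const(d1: np.ndarray, d2: np.ndarray,
              p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Constant part of the squared-loss Gromov tensor product."""
    return (d1**2 @ p)[:, None] + (q @ d2.T**2)[None, :]


def fgw_cost(
    coupling: np.ndarray,
    feature_cost: np.ndarray,
    d1: np.ndarray,
    d2: np.ndarray,
    balance: float,
) -> float:
    """Evaluate the fused transport cost F for a given coupling."""
    p = coupling.sum(axis=1)
    q = coupling.sum(axis=0)
    gw = _gw_const(d1, d2, p, q) - 2.0 * d1 @ coupling @ d2.T
    return float((1.0 - balance) * (feature_cost * coupling).sum()
                 + balance * (gw * coupling).sum())


def pairwise_align(
    a: SlideLayer,
    b: SlideLayer,
    balance: float = 0.1,
    topic_cost: str = "sqeuclidean",
    max_iter: int = 100,
    tol: float = 1e-9,
) -> LayerMapping:
    """Fused Gromov–Wasserstein coupling between two slides.

    Uniform marginals (every spot carries equal mass).  Conditional-gradient
    iterations with exact line search; stops when the relative cost decrease
    falls below ``tol``.  If the iteration cap is hit, the best iterate is
    returned with ``converged=False`` and a warning.
    """
    if a.topic_profiles.shape[0] != b.topic_profiles.shape[0]:
        raise ValueError("slides have different topic spaces")
    if not 0.0 <= balance <= 1.0:
        raise ValueError("balance must lie in [0, 1]")
    n, m = a.n_spots, b.n_spots
    p = np.full(n, 1.0 / n)
    q = np.full(m, 1.0 / m)
    mcost = _feature_cost(a.topic_profiles, b.topic_profiles, topic_cost)
    d1, d2 = a.distance_matrix(), b.distance_matrix()
    const = _gw_const(d1, d2, p, q)
    pi = np.outer(p, q)
    cost = fgw_cost(pi, mcost, d1, d2, balance)
    converged = False
    for _ in range(max_iter):
        grad = (1.0 - balance) * mcost + 2.0 * balance * (const - 2.0 * d1 @ pi @ d2.T)
        direction = _emd(p, q, grad) - pi
        # exact line search: the objective is quadratic in the step size
        cross = d1 @ direction @ d2.T
        a2 = -2.0 * balance * float((cross * direction).sum())
        b1 = float((1.0 - balance) * (mcost * direction).sum()
                   + balance * ((const * direction).sum()
                                - 4.0 * float((d1 @ pi @ d2.T * direction).sum())))
        if a2 > 0:
            t = float(np.clip(-b1 / (2.0 * a2), 0.0, 1.0))
        else:
            t = 1.0 if a2 + b1 < 0 else 0.0
        if t <= 0:
            converged = True
            break
        pi = pi + t * direction
        new_cost = fgw_cost(pi, mcost, d1, d2, balance)
        if abs(cost - new_cost) <= tol * max(abs(cost), 1e-16):
            cost = new_cost
            converged = True
            break
        cost = new_cost
    if not converged:
        log.warning("FGW alignment stopped at the iteration cap (%d); "
                    "returning the best iterate", max_iter)
    return LayerMapping(coupling=pi, cost=cost, balance=balance,
                        converged=converged)


def procrustes_pair(
    z_a: np.ndarray, z_b: np.ndarray, coupling: np.ndarray
) -> RigidTransform:
    """Closed-form weighted Procrustes: map slide b into slide a's frame.

    Minimizes sum_ij Pi_ij ||z_a_.i - R z_b_.j - v||^2 over proper rotations
    R and translations v, via SVD of the coupling-weighted cross-covariance.
    """
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    if z_a.shape[0] != 2 or z_b.shape[0] != 2:
        raise ValueError("coordinate matrices must be 2 x n")
    if coupling.shape != (z_a.shape[1], z_b.shape[1]):
        raise ValueError("coupling shape does not match coordinate matrices")
    mass = coupling.sum()
    if mass <= 0:
        raise ValueError("coupling carries no mass")
    wa = coupling.sum(axis=1) / mass
    wb = coupling.sum(axis=0) / mass
    mu_a = z_a @ wa
    mu_b = z_b @ wb
    h = (z_a - mu_a[:, None]) @ (coupling / mass) @ (z_b - mu_b[:, None]).T
    u, s, vt = np.linalg.svd(h)
    if s[-1] < 1e-12 * max(s[0], 1e-300) or s[0] == 0:
        raise ValueError("degenerate weighted covariance (mass concentrated "
                         "on too few spots)")
    r = u @ np.diag([1.0, np.linalg.det(u @ vt)]) @ vt
    v = mu_a - r @ mu_b
    return RigidTransform(R=r, v=v)


def stack_layers(
    layers: list[SlideLayer],
    balance: float = 0.1,
    z_spacing: float = 1.0,
    topic_cost: str = "sqeuclidean",
    dominant_types: list[list[str]] | None = None,
    max_iter: int = 100,
) -> tuple[pd.DataFrame, list[LayerMapping]]:
    """Sequentially align an ordered slide series into one 3D frame.

    Each adjacent pair is coupled by FGW and the resulting rigid transforms
    accumulated so every layer lands in the first layer's frame; the section
    index times ``z_spacing`` gives the z coordinate.  Returns the per-spot
    3D table and the pairwise couplings.
    """
    if len(layers) < 2:
        raise ValueError("need at least two layers in section order")
    mappings: list[LayerMapping] = []
    frames: list[np.ndarray] = [layers[0].coords]
    for k in range(len(layers) - 1):
        a, b = layers[k], layers[k + 1]
        try:
            mapping = pairwise_align(a, b, balance=balance,
                                     topic_cost=topic_cost, max_iter=max_iter)
            transform = procrustes_pair(frames[k], b.coords, mapping.coupling)
        except Exception as exc:
            raise RuntimeError(
                f"alignment failed between layers "
                f"{a.slide_id or k} and {b.slide_id or k + 1}: {exc}"
            ) from exc
        mappings.append(mapping)
        frames.append(transform.apply(b.coords))
    rows = []
    for k, (layer, xy) in enumerate(zip(layers, frames)):
        z = (layer.z_index if layer.z_index else k) * z_spacing
        for i, sid in enumerate(layer.spot_ids):
            row = {
                "spot_id": sid,
                "slide_id": layer.slide_id or str(k),
                "x": xy[0, i], "y": xy[1, i], "z": z,
            }
            if dominant_types is not None:
                row["dominant_celltype"] = dominant_types[k][i]
            rows.append(row)
    return pd.DataFrame(rows), mappings
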