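"""Soft and hard clustering of standardized expression profiles.

Fuzzy c-means is implemented here directly (it is the statistic of interest,
and its membership matrix — not just hard labels — is what downstream
figures color by).  Hierarchical linkage and PCA wrap scipy/numpy.

The FCM objective is J = sum_i sum_k u(i,k)^m * ||x_i - c_k||^2 with the
classic alternating updates:

- centers:    c_k = sum_i u(i,k)^m x_i / sum_i u(i,k)^m
- membership: u(i,k) = 1 / sum_j (d(i,k)/d(i,j))^(2/(m-1))

A point at exactly zero distance from a center gets membership 1 there.
Each update decreases J, so the per-iteration objective trace is
non-increasing; this is asserted at run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import pdist

from .errors import ValidationError


@dataclass
class ClusterModel:
    """Fitted fuzzy c-means model.

    ``membership[i, k]`` is protein i's degree of belonging to cluster k;
    every row sums to 1.  ``objective_trace`` holds the per-iteration value
    of the weighted within-cluster sum of squares and is non-increasing.
    """

    c: int
    m: float
    centers: np.ndarray
    membership: np.ndarray
    objective_trace: list[float]
    seed: int
    protein_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        sums = self.membership.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("membership rows must sum to 1")
        diffs = np.diff(self.objective_trace)
        if len(diffs) and diffs.max() > 1e-9:
            raise ValidationError("objective trace must be non-increasing")

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]


def _fcm_memberships(dist_sq: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances; zero distance → membership 1."""
    n, c = dist_sq.shape
    u = np.zeros((n, c))
    zero_rows = (dist_sq <= 1e-300).any(axis=1)
    if zero_rows.any():
        hits = dist_sq[zero_rows] <= 1e-300
        u[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
    ok = ~zero_rows
    if ok.any():
        power = dist_sq[ok] ** (-1.0 / (m - 1.0))
        u[ok] = power / power.sum(axis=1, keepdims=True)
    return u


def _fcm_single(
    X: np.ndarray, c: int, m: float, max_iter: int, tol: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    n = X.shape[0]
    u = rng.random((n, c))
    u /= u.sum(axis=1, keepdims=True)
    trace: list[float] = []
    centers = np.empty((c, X.shape[1]))
    for _ in range(max_iter):
        um = u**m
        centers = (um.T @ X) / um.sum(axis=0)[:, None]
        dist_sq = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        u = _fcm_memberships(dist_sq, m)
        objective = float((u**m * dist_sq).sum())
        if trace and trace[-1] - objective < tol:
            trace.append(min(objective, trace[-1]))
            break
        trace.append(objective)
    return centers, u, trace


def fuzzy_cmeans(
    X: np.ndarray,
    c: int,
    m: float = 2.0,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
    n_init: int = 5,
    protein_ids: list[str] | None = None,
) -> ClusterModel:
    """Fit fuzzy c-means to complete standardized profiles.

    ``X`` is an (N, S) matrix with no missing values.  The membership matrix
    is initialized at random (rows normalized); ``n_init`` restarts are run
    from the given seed and the fit with the lowest final objective is kept,
    since FCM is sensitive to initialization.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValidationError("input must be a non-empty 2-D matrix")
    if not np.isfinite(X).all():
        raise ValidationError("profiles must have no missing values; filter or impute first")
    if c < 2:
        raise ValidationError("cluster count c must be >= 2")
    if c > X.shape[0]:
        raise ValidationError(f"c={c} exceeds the number of profiles ({X.shape[0]})")
    if m <= 1:
        raise ValidationError("fuzzifier m must be > 1")
    if protein_ids is not None and len(protein_ids) != X.shape[0]:
        raise ValidationError("protein_ids length must match the number of profiles")

    best: tuple[np.ndarray, np.ndarray, list[float]] | None = None
    for child in np.random.SeedSequence(seed).spawn(n_init):
        fit = _fcm_single(X, c, m, max_iter, tol, np.random.default_rng(child))
        if best is None or fit[2][-1] < best[2][-1]:
            best = fit
    centers, u, trace = best  # type: ignore[misc]
    return ClusterModel(
        c=c,
        m=m,
        centers=centers,
        membership=u,
        objective_trace=trace,
        seed=seed,
        protein_ids=list(protein_ids or [f"profile{i}" for i in range(X.shape[0])]),
    )


def assign_clusters(model: ClusterModel, membership_cutoff: float = 0.5) -> pd.DataFrame:
    """Hard assignments: argmax membership, ties to the lowest cluster index.

    ``passes_cutoff`` is true only when the top membership is *strictly*
    above the cutoff, matching the convention of coloring only memberships
    above 0.5.
    """
    if not 0 < membership_cutoff <= 1:
        raise ValidationError("membership cutoff must be in (0, 1]")
    top = model.membership.argmax(axis=1)
    top_val = model.membership[np.arange(len(top)), top]
    return pd.DataFrame(
        {
            "protein_id": model.protein_ids,
            "cluster": top,
            "membership": top_val,
            "passes_cutoff": top_val > membership_cutoff,
        }
    )


def hierarchical_linkage(
    X: np.ndarray,
    distance: str = "euclidean",
    method: str = "average",
) -> np.ndarray:
    """Agglomerative merge sequence (scipy linkage matrix) over the rows of X.

    ``distance`` is ``euclidean`` or ``one_minus_pearson``; ``method`` is
    ``average``, ``complete`` or ``ward`` (ward requires euclidean).  To
    cluster stages rather than proteins, pass the transposed profile matrix.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 items to cluster")
    if method not in ("average", "complete", "ward"):
        raise ValidationError(f"unknown linkage method {method!r}")
    if distance == "euclidean":
        d = pdist(X, metric="euclidean")
    elif distance == "one_minus_pearson":
        if method == "ward":
            raise ValidationError("ward linkage requires euclidean distance")
        d = pdist(X, metric="correlation")
    else:
        raise ValidationError(f"unknown distance {distance!r}")
    return _scipy_linkage(d, method=method)


def pca_embed(X: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Project rows of X onto the top principal axes of the centered data.

    Returns (coordinates of shape (N, n_components), explained-variance
    fractions).  Fractions are non-increasing and sum to <= 1; for an input
    with zero total variance they are all 0.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("input must be 2-D")
    if n_components > min(X.shape):
        raise ValidationError(f"n_components={n_components} exceeds min(data dimensions)")
    centered = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    total = var.sum()
    fractions = var[:n_components] / total if total > 0 else np.zeros(n_components)
    return centered @ vt[:n_components].T, fractions


__all__ = [
    "ClusterModel",
    "fuzzy_cmeans",
    "assign_clusters",
    "hierarchical_linkage",
    "pca_embed",
]
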