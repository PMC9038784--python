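"""Variance-sensitive fuzzy clustering of temporal profiles.

Features (Z-scored temporal profiles, replicates averaged per timepoint)
are grouped by fuzzy c-means with a per-feature weight that down-weights
noisy features: ``w_i = 1 / (1 + s_i²)`` with ``s_i²`` the mean
within-timepoint replicate variance on the Z scale.  Weights enter the
objective and the centroid update; the membership update is unchanged.

The number of clusters is chosen over a candidate range using the Xie-Beni
validity index (compactness over separation; lower is better)::

    XB = Σ_i Σ_j u_ij^m ‖x_i − v_j‖² / (n · min_{j≠j'} ‖v_j − v_j'‖²)

with the minimum centroid distance computed alongside as a degeneracy
guard: candidates whose best solution contains near-duplicate centroids are
discarded rather than allowed to win on a vanishing denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureMatrix
from .quantitation import znormalize

__all__ = ["ClusterModel", "fuzzy_cmeans", "xie_beni", "min_centroid_distance",
           "vs_cluster", "assign_members", "replicate_variance_weights"]


@dataclass
class ClusterModel:
    """Fitted fuzzy partition with its selection diagnostics."""

    c: int
    centroids: np.ndarray        # (c, d)
    membership: pd.DataFrame     # features x c, rows sum to 1
    fuzzifier: float
    xie_beni: float
    min_centroid_distance: float
    candidates: pd.DataFrame | None = None  # per-candidate diagnostics
    weights: np.ndarray | None = None


def _distances_sq(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - V[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def fuzzy_cmeans(X: np.ndarray, c: int, m: float = 2.0,
                 weights: np.ndarray | None = None,
                 n_init: int = 5, max_iter: int = 300, tol: float = 1e-9,
                 rng: np.random.Generator | None = None):
    """Weighted fuzzy c-means; best of ``n_init`` restarts by objective.

    Returns ``(centroids, membership, objective)``.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if not 2 <= c < n:
        raise ValueError(f"need 2 <= c < n_features, got c={c}, n={n}")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    rng = rng or np.random.default_rng(0)

    best = None
    for _ in range(n_init):
        # random memberships init
        U = rng.dirichlet(np.ones(c), size=n)
        prev_obj = np.inf
        for _ in range(max_iter):
            Um = (w[:, None] * U**m)
            V = (Um.T @ X) / Um.sum(axis=0)[:, None]
            D = _distances_sq(X, V)
            obj = float(np.sum(Um * D))
            D = np.maximum(D, 1e-300)
            inv = D ** (-1.0 / (m - 1.0))
            U = inv / inv.sum(axis=1, keepdims=True)
            if abs(prev_obj - obj) <= tol * max(abs(obj), 1.0):
                break
            prev_obj = obj
        if best is None or obj < best[2]:
            best = (V, U, obj)
    return best


def xie_beni(X: np.ndarray, centroids: np.ndarray, U: np.ndarray,
             m: float = 2.0) -> float:
    """Xie-Beni validity index of a fuzzy partition (lower is better)."""
    D = _distances_sq(np.asarray(X, float), np.asarray(centroids, float))
    sep = min_centroid_distance(centroids) ** 2
    n = len(X)
    if sep == 0:
        return np.inf
    return float(np.sum(np.asarray(U) ** m * D) / (n * sep))


def min_centroid_distance(centroids: np.ndarray) -> float:
    V = np.asarray(centroids, dtype=float)
    d = np.sqrt(_distances_sq(V, V))
    iu = np.triu_indices(len(V), k=1)
    return float(d[iu].min())


def replicate_variance_weights(matrix: FeatureMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Z-scored per-timepoint profiles and variance-sensitive weights.

    Normalises to per-cell values, Z-scores across all samples, averages
    replicates per timepoint, and computes ``w_i = 1/(1 + s_i²)`` from the
    mean within-timepoint replicate variance of the Z values.
    """
    z, _ = znormalize(matrix.per_cell())
    times = matrix.sample_times
    groups = z.T.groupby(times)
    profile = groups.mean().T
    profile.columns = [f"t{int(round(t)):02d}" for t in profile.columns]
    within_var = groups.var(ddof=1).T.mean(axis=1).fillna(0.0)
    weights = 1.0 / (1.0 + within_var.to_numpy())
    return profile, weights


def vs_cluster(profiles, c_candidates=range(2, 9), m: float = 2.0,
               weights: np.ndarray | None = None, n_init: int = 5,
               seed=0) -> ClusterModel:
    """Cluster temporal profiles and select the cluster number.

    ``profiles`` is a features × timepoints frame (replicates already
    averaged; see :func:`replicate_variance_weights`).  For each candidate
    ``c`` the best-of-restarts partition is scored by the Xie-Beni index and
    its minimum centroid distance; degenerate candidates (collapsed
    centroids) are skipped, and the remaining candidate with the smallest
    Xie-Beni index is selected (ties toward smaller c).
    """
    profiles = pd.DataFrame(profiles)
    X = profiles.to_numpy(dtype=float)
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 features to cluster")
    rng = np.random.default_rng(seed)
    scale = np.linalg.norm(X - X.mean(axis=0), axis=1).mean()

    rows = []
    fits = {}
    for c in c_candidates:
        if c >= n:
            warnings.warn(f"candidate c={c} >= n_features={n}; skipped", stacklevel=2)
            continue
        V, U, obj = fuzzy_cmeans(X, c, m=m, weights=weights, n_init=n_init, rng=rng)
        xb = xie_beni(X, V, U, m)
        mcd = min_centroid_distance(V)
        degenerate = mcd < 1e-6 * max(scale, 1e-12)
        rows.append({"c": c, "objective": obj, "xie_beni": xb,
                     "min_centroid_distance": mcd, "degenerate": degenerate})
        if not degenerate:
            fits[c] = (V, U, xb, mcd)
    if not fits:
        raise ValueError("no non-degenerate clustering found over the candidates")
    diag = pd.DataFrame(rows)
    c_best = min(fits, key=lambda c: (fits[c][2], c))
    V, U, xb, mcd = fits[c_best]
    membership = pd.DataFrame(U, index=profiles.index,
                              columns=[f"cluster_{j + 1}" for j in range(c_best)])
    return ClusterModel(c=c_best, centroids=V, membership=membership,
                        fuzzifier=m, xie_beni=xb, min_centroid_distance=mcd,
                        candidates=diag, weights=weights)


def assign_members(model: ClusterModel, threshold: float = 0.5) -> pd.Series:
    """Hard labels: argmax cluster when its membership exceeds ``threshold``,
    else ``"n.a."`` (unassigned)."""
    U = model.membership.to_numpy()
    arg = U.argmax(axis=1)
    top = U.max(axis=1)
    labels = np.where(top > threshold,
                      model.membership.columns.to_numpy()[arg], "n.a.")
    return pd.Series(labels, index=model.membership.index, name="cluster")
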