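"""Supervised Locality Preserving Projections (SLPP).

A linear embedding that preserves *within-class* neighborhood structure:
an adjacency graph connects sample pairs that share a class label and are
mutual-or-either k-nearest neighbors, with heat-kernel weights
``W_ij = exp(-||x_i - x_j||^2 / t)``. With degree matrix ``D = diag(W 1)``
and Laplacian ``L = D - W``, the projection directions ``a`` minimize
``a' X L X' a`` subject to ``a' X D X' a = 1`` — the smallest-eigenvalue
solutions of the generalized eigenproblem ``X L X' a = λ X D X' a``.

Features are standardized and pre-projected by a variance-retaining PCA
before the eigenproblem, which keeps ``X D X'`` well-conditioned when the
raw dimensionality exceeds the sample count (as it does for all four
facial feature streams).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.decomposition import PCA

__all__ = ["SlppModel", "fit_slpp", "transform", "build_adjacency"]


@dataclass
class SlppModel:
    """Fitted SLPP map: standardization -> PCA pre-projection -> projection."""

    mean_: np.ndarray
    scale_: np.ndarray
    pca_mean_: np.ndarray
    pca_components_: np.ndarray  # (rank, d_in_std)
    projection_: np.ndarray      # (rank, d_out)
    eigenvalues_: np.ndarray     # ascending, length d_out
    k: int
    t: float
    d_out: int

    @property
    def rank(self) -> int:
        return self.pca_components_.shape[0]

    @property
    def linear_map(self) -> np.ndarray:
        """Combined (d_in, d_out) map applied after centering/scaling the input."""
        return (self.pca_components_.T / self.scale_[:, None]) @ self.projection_


def build_adjacency(Z: np.ndarray, y: np.ndarray, k: int, t: float) -> np.ndarray:
    """Supervised heat-kernel adjacency on pre-projected data.

    ``W_ij = exp(-||z_i - z_j||^2 / t)`` iff i and j share a class and j is
    among i's k nearest neighbors (or vice versa: symmetrized by max);
    otherwise 0. The diagonal is 0.
    """
    n = Z.shape[0]
    sq = np.sum(Z**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T), 0.0)
    np.fill_diagonal(d2, np.inf)
    knn = np.zeros((n, n), dtype=bool)
    k_eff = min(k, n - 1)
    order = np.argsort(d2, axis=1, kind="stable")[:, :k_eff]
    rows = np.repeat(np.arange(n), k_eff)
    knn[rows, order.ravel()] = True
    knn |= knn.T  # symmetrize by max
    same = y[:, None] == y[None, :]
    W = np.where(knn & same, np.exp(-d2 / t), 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def fit_slpp(
    X: np.ndarray,
    y: np.ndarray,
    d_out: int | None = None,
    k: int = 5,
    t_mode: str | float = "auto",
    pca_variance: float = 0.98,
    max_d_out: int = 30,
) -> SlppModel:
    """Fit the supervised LPP embedding.

    Parameters
    ----------
    X : (n, d) training vectors; n >= 4 and both classes present.
    y : binary labels.
    d_out : target dimensionality. ``None`` picks ``min(max_d_out, rank)``;
        an explicit value above the achievable rank is an error.
    k : neighbor count of the adjacency graph.
    t_mode : ``"auto"`` sets the heat-kernel width to the mean squared
        pairwise distance of the (standardized, pre-projected) training
        data; a float fixes it directly.
    pca_variance : fraction of variance the PCA pre-projection retains.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    if n < 4:
        raise ValueError(f"SLPP needs at least 4 samples, got {n}")
    if len(np.unique(y)) < 2:
        raise ValueError("SLPP needs samples from both classes")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale

    pca = PCA(n_components=min(n - 1, d), svd_solver="full").fit(Xs)
    ratios = np.cumsum(pca.explained_variance_ratio_)
    rank = max(1, int(np.searchsorted(ratios, pca_variance) + 1))
    rank = min(rank, pca.components_.shape[0])
    components = pca.components_[:rank]
    Z = (Xs - pca.mean_) @ components.T

    if d_out is None:
        d_out = min(max_d_out, rank)
    if d_out < 1:
        raise ValueError("d_out must be at least 1")
    if d_out > rank:
        raise ValueError(f"d_out={d_out} exceeds the achievable rank {rank}")

    if t_mode == "auto":
        diff2 = (
            np.sum(Z**2, axis=1)[:, None]
            + np.sum(Z**2, axis=1)[None, :]
            - 2.0 * (Z @ Z.T)
        )
        t = float(np.sum(np.maximum(diff2, 0.0)) / (n * (n - 1)))
        t = max(t, np.finfo(float).tiny)
    else:
        t = float(t_mode)
        if t <= 0:
            raise ValueError("heat-kernel width t must be positive")

    W = build_adjacency(Z, y, k, t)
    Dvec = W.sum(axis=1)
    L = np.diag(Dvec) - W
    A = Z.T @ L @ Z
    B = Z.T @ (Z * Dvec[:, None])
    # tiny ridge keeps B positive definite when some samples are isolated
    B = B + 1e-10 * (np.trace(B) / rank + 1.0) * np.eye(rank)
    eigvals, eigvecs = linalg.eigh(A, B)
    return SlppModel(
        mean_=mean,
        scale_=scale,
        pca_mean_=pca.mean_,
        pca_components_=components,
        projection_=eigvecs[:, :d_out],
        eigenvalues_=eigvals[:d_out],
        k=k,
        t=t,
        d_out=d_out,
    )


def transform(model: SlppModel, X: np.ndarray) -> np.ndarray:
    """Apply the fitted linear map; rows of X must match the training dimension."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean_.shape[0]:
        raise ValueError(
            f"input dimension {X.shape[1]} does not match training dimension {model.mean_.shape[0]}"
        )
    Xs = (X - model.mean_) / model.scale_
    Z = (Xs - model.pca_mean_) @ model.pca_components_.T
    return Z @ model.projection_
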