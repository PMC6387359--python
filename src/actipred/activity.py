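"""Context identification: locality preserving projections + k-means.

The activity cluster function maps context-sensor features (by default the
21 ankle-accelerometer window features) to a discrete activity index.  The
features are projected to 3 dimensions with locality preserving projections
(LPP) — a linear map that preserves a k-NN heat-kernel neighbourhood graph
via a generalized eigenproblem — and clustered with k-means (K = 4 by
default, matching the four protocol activity states).  Cluster ids are
relabelled in descending training-cluster size so reports are deterministic;
semantic names (walking/running/...) are annotations only.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LocalityPreservingProjection",
    "ActivityClusterModel",
    "fit_lpp",
    "fit_clusters",
    "assign",
]

_EPS = 1e-12


class LocalityPreservingProjection(TransformerMixin, BaseEstimator):
    """Linear embedding minimizing ``Σ_ij W_ij ‖a'x_i − a'x_j‖²``.

    Solves the generalized eigenproblem ``X'LX a = λ X'DX a`` on the
    symmetrized k-NN heat-kernel graph (W_ij = exp(−d²_ij/σ²)) and keeps the
    ``n_components`` eigenvectors with smallest eigenvalue.

    Parameters
    ----------
    n_components : int, default 3
    n_neighbors : int, default 10
    bandwidth : float or None
        Heat-kernel σ²; ``None`` uses the mean squared k-NN distance
        (robust when rows are strongly-overlapping sliding windows, whose
        near-duplicate neighbours drive the median toward zero).
    ridge : float, default 1e-8
        Relative Tikhonov term added to both matrices (rank-deficient
        scatter matrices are regularized rather than rejected).
    standardize : bool, default True
        Center/scale features with training statistics before embedding.
    """

    def __init__(self, n_components=3, n_neighbors=10, bandwidth=None,
                 ridge=1e-8, standardize=True):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.bandwidth = bandwidth
        self.ridge = ridge
        self.standardize = standardize

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        n, p = X.shape
        if n <= self.n_neighbors:
            raise ValueError("need more samples than n_neighbors")
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_ = np.where(sd > _EPS, sd, 1.0)
        else:
            self.mean_ = np.zeros(p)
            self.scale_ = np.ones(p)
        Xs = (X - self.mean_) / self.scale_

        nn = NearestNeighbors(n_neighbors=self.n_neighbors + 1).fit(Xs)
        dist, idx = nn.kneighbors(Xs)
        dist, idx = dist[:, 1:], idx[:, 1:]  # drop self-edges
        d2 = dist ** 2
        sigma2 = self.bandwidth if self.bandwidth is not None else float(
            np.mean(d2)
        )
        sigma2 = max(sigma2, _EPS)
        self.bandwidth_ = sigma2
        w = np.exp(-d2 / sigma2)
        rows = np.repeat(np.arange(n), self.n_neighbors)
        W = sp.csr_matrix((w.ravel(), (rows, idx.ravel())), shape=(n, n))
        W = W.maximum(W.T)  # symmetrize
        deg = np.asarray(W.sum(axis=1)).ravel()
        XtDX = (Xs * deg[:, None]).T @ Xs
        XtWX = Xs.T @ (W @ Xs)
        A = XtDX - XtWX  # = X' L X
        B = XtDX
        # identical ridge on both sides: directions outside the data span get
        # generalized eigenvalue 1 and rank below any genuine structure
        eps = self.ridge * max(np.trace(B) / p, _EPS)
        if np.linalg.matrix_rank(B, tol=1e-8 * np.trace(B)) < p:
            warnings.warn("rank-deficient scatter matrix; using ridge-regularized solve")
        A = A + eps * np.eye(p)
        B = B + eps * np.eye(p)
        evals, evecs = scipy.linalg.eigh(A, B)
        k = min(self.n_components, p)
        V = evecs[:, :k]
        # deterministic sign: largest-|entry| component positive
        for j in range(k):
            i = np.argmax(np.abs(V[:, j]))
            if V[i, j] < 0:
                V[:, j] = -V[:, j]
        self.components_ = V
        self.eigenvalues_ = evals[:k]
        self.embedding_ = Xs @ V
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, float)
        return (X - self.mean_) / self.scale_ @ self.components_


def fit_lpp(features, out_dim=3, knn=10, bandwidth=None) -> LocalityPreservingProjection:
    """Fit an LPP projection on (standardized) context features."""
    return LocalityPreservingProjection(
        n_components=out_dim, n_neighbors=knn, bandwidth=bandwidth
    ).fit(features)


def _relabel_by_size(labels, centers):
    counts = np.bincount(labels, minlength=len(centers))
    order = np.argsort(-counts, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    return remap[labels], centers[order], counts[order]


def fit_clusters(embedded, n_clusters=4, seed=0, n_init=20):
    """k-means on embedded rows; returns (centroids, labels, sizes) with
    cluster ids relabelled in descending size."""
    embedded = np.asarray(embedded, float)
    if len(embedded) < n_clusters:
        raise ValueError("fewer rows than clusters")
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    labels = km.fit_predict(embedded)
    labels, centers, sizes = _relabel_by_size(labels, km.cluster_centers_)
    return centers, labels, sizes


class ActivityClusterModel(ClusterMixin, BaseEstimator):
    """LPP embedding + k-means centroids: the activity cluster function.

    ``fit`` takes the context feature rows (N × 21 by default); ``predict``
    assigns new rows to the nearest centroid in embedded space, ties broken
    toward the lowest cluster index.
    """

    def __init__(self, n_clusters=4, n_components=3, n_neighbors=10,
                 bandwidth=None, n_init=20, random_state=0):
        self.n_clusters = n_clusters
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.bandwidth = bandwidth
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        self.lpp_ = LocalityPreservingProjection(
            n_components=self.n_components, n_neighbors=self.n_neighbors,
            bandwidth=self.bandwidth,
        ).fit(X)
        E = self.lpp_.embedding_
        self.centroids_, self.labels_, self.cluster_sizes_ = fit_clusters(
            E, self.n_clusters, seed=self.random_state, n_init=self.n_init
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "centroids_")
        E = self.lpp_.transform(np.asarray(X, float))
        d2 = ((E[:, None, :] - self.centroids_[None]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)  # argmin → lowest index on ties

    def to_json(self, path) -> None:
        payload = {
            "params": self.get_params(),
            "lpp": {
                "mean": self.lpp_.mean_.tolist(),
                "scale": self.lpp_.scale_.tolist(),
                "components": self.lpp_.components_.tolist(),
                "bandwidth": self.lpp_.bandwidth_,
            },
            "centroids": self.centroids_.tolist(),
            "cluster_sizes": self.cluster_sizes_.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "ActivityClusterModel":
        d = json.loads(Path(path).read_text())
        m = cls(**d["params"])
        lpp = LocalityPreservingProjection(
            n_components=m.n_components, n_neighbors=m.n_neighbors)
        lpp.mean_ = np.asarray(d["lpp"]["mean"])
        lpp.scale_ = np.asarray(d["lpp"]["scale"])
        lpp.components_ = np.asarray(d["lpp"]["components"])
        lpp.bandwidth_ = d["lpp"]["bandwidth"]
        lpp.eigenvalues_ = None
        m.lpp_ = lpp
        m.centroids_ = np.asarray(d["centroids"])
        m.cluster_sizes_ = np.asarray(d["cluster_sizes"])
        return m


def assign(model: ActivityClusterModel, rows) -> np.ndarray:
    """Nearest-centroid cluster index for context feature rows."""
    rows = np.atleast_2d(np.asarray(rows, float))
    return model.predict(rows)
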