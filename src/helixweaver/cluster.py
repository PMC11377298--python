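"""Density-peak clustering (Rodriguez–Laio) as a scikit-learn estimator.

For every point the local density ``rho_i = Σ_{j≠i} exp(−(d_ij/d_c)²)``
and the separation ``delta_i`` (distance to the nearest higher-density
point; for the global density maximum, the largest pairwise distance) are
computed.  Cluster centers are the points with the largest ``rho·delta``
product (or a requested count), and every remaining point joins the
cluster of its nearest higher-density neighbour, propagated in order of
decreasing density.  Ties in density and in ``rho·delta`` are broken by
point index so the partition is permutation-stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class ClusterResult:
    """Summary of one density-peak clustering run."""

    rho: np.ndarray
    delta: np.ndarray
    labels: np.ndarray
    center_indices: np.ndarray
    member_counts: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.center_indices)


class DensityPeakClustering(ClusterMixin, BaseEstimator):
    """Cluster points by finding density peaks.

    Parameters
    ----------
    n_clusters : int or None
        Number of centers to select (the top points by ``rho * delta``).
        If None, centers are the points with ``rho > rho_cut`` and
        ``delta > delta_cut``.
    d_c : float or None
        Gaussian kernel scale of the density estimate.  If None it is set
        to the ``d_c_percentile`` percentile of the pairwise distances.
    d_c_percentile : float
        Percentile (0–100) used when ``d_c`` is None.
    standardize : bool
        Z-score each feature column before computing distances.
    rho_cut, delta_cut : float
        Cutoffs used only when ``n_clusters`` is None.

    Attributes
    ----------
    rho_, delta_ : ndarray of shape (n_samples,)
    labels_ : ndarray of shape (n_samples,)
        Cluster id of each point, ``0..n_clusters_-1`` in decreasing order
        of center density.
    center_indices_ : ndarray
        Index of each cluster's density-peak center.
    d_c_ : float
        Kernel scale actually used.
    """

    def __init__(self, n_clusters: int | None = None, d_c: float | None = None,
                 d_c_percentile: float = 2.0, standardize: bool = True,
                 rho_cut: float = 0.0, delta_cut: float = 0.0):
        self.n_clusters = n_clusters
        self.d_c = d_c
        self.d_c_percentile = d_c_percentile
        self.standardize = standardize
        self.rho_cut = rho_cut
        self.delta_cut = delta_cut

    def fit(self, X, y=None) -> "DensityPeakClustering":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) < 1:
            raise ValueError("X must be a non-empty 2-D array")
        n = len(X)
        if self.n_clusters is not None and self.n_clusters > n:
            raise ValueError(f"n_clusters={self.n_clusters} exceeds n_points={n}")
        if self.standardize:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            X = (X - mu) / sd

        if n == 1:
            self.rho_ = np.zeros(1)
            self.delta_ = np.zeros(1)
            self.labels_ = np.zeros(1, dtype=int)
            self.center_indices_ = np.array([0])
            self.d_c_ = self.d_c if self.d_c is not None else 1.0
            return self

        D = squareform(pdist(X))
        if self.d_c is not None:
            d_c = float(self.d_c)
        else:
            d_c = float(np.percentile(pdist(X), self.d_c_percentile))
            if d_c <= 0:
                d_c = max(float(np.max(D)), 1.0) * 1e-3
        rho = np.exp(-(D / d_c) ** 2).sum(axis=1) - 1.0

        # higher density: strictly larger rho, ties broken by lower index
        order = np.lexsort((np.arange(n), -rho))  # decreasing rho, index-stable
        delta = np.empty(n)
        nn_higher = np.full(n, -1, dtype=int)
        delta[order[0]] = float(np.max(D))
        for k in range(1, n):
            i = order[k]
            prev = order[:k]
            d = D[i, prev]
            j = int(np.argmin(d))
            delta[i] = float(d[j])
            nn_higher[i] = int(prev[j])

        gamma = rho * delta
        if self.n_clusters is not None:
            cand = np.lexsort((np.arange(n), -gamma))
            centers = np.sort(cand[: self.n_clusters])
        else:
            centers = np.where((rho > self.rho_cut) & (delta > self.delta_cut))[0]
            if len(centers) == 0:
                centers = np.array([int(order[0])])
        # label clusters 0.. by decreasing center density (index tie-break)
        centers = centers[np.lexsort((centers, -rho[centers]))]
        labels = np.full(n, -1, dtype=int)
        for cid, c in enumerate(centers):
            labels[c] = cid
        for i in order:
            if labels[i] < 0:
                if nn_higher[i] >= 0:
                    labels[i] = labels[nn_higher[i]]
                else:  # global density max not selected as a center
                    labels[i] = labels[centers[int(np.argmin(D[i, centers]))]]

        self.rho_ = rho
        self.delta_ = delta
        self.labels_ = labels
        self.center_indices_ = centers
        self.d_c_ = d_c
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def result_(self) -> ClusterResult:
        check_is_fitted(self, "labels_")
        counts = np.bincount(self.labels_, minlength=len(self.center_indices_))
        return ClusterResult(rho=self.rho_, delta=self.delta_, labels=self.labels_,
                             center_indices=self.center_indices_, member_counts=counts)


def density_peak_cluster(points, n_centers: int | None = None,
                         d_c: float | None = None,
                         d_c_percentile: float = 2.0,
                         standardize: bool = True) -> ClusterResult:
    """Functional wrapper over :class:`DensityPeakClustering`.

    ``points`` may be an (n, k) array or a list of objects with a
    ``values`` array attribute (feature vectors).
    """
    X = _as_matrix(points)
    est = DensityPeakClustering(n_clusters=n_centers, d_c=d_c,
                                d_c_percentile=d_c_percentile,
                                standardize=standardize)
    est.fit(X)
    return est.result_()


def _as_matrix(points) -> np.ndarray:
    if hasattr(points, "ndim"):
        return np.asarray(points, dtype=float)
    rows = [np.asarray(getattr(p, "values", p), dtype=float) for p in points]
    return np.stack(rows)
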