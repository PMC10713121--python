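"""Kernel k-means over a precomputed read-read similarity kernel.

Clusters the n reads into k groups (one per haplotype) in the implicit
feature space of a positive semi-definite kernel: the squared distance of
point i to the centroid of cluster c expands as

    d(i, c) = K_ii - 2/|c| * sum_{j in c} K_ij + 1/|c|^2 * sum_{j,j' in c} K_jj'

All restarts are iterated simultaneously (vectorised over the restart axis),
which keeps the per-epoch clustering refresh of the assembler cheap.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = ["KernelKMeans", "kernel_kmeans", "psd_clip"]


def psd_clip(K: np.ndarray, rel_tol: float = 1e-6) -> np.ndarray:
    """Repair a numerically indefinite kernel by clipping eigenvalues at 0.

    Returns K unchanged when its minimum eigenvalue is above
    ``-rel_tol * max_eigenvalue``.
    """
    K = np.asarray(K, dtype=np.float64)
    K = 0.5 * (K + K.T)
    w, V = np.linalg.eigh(K)
    if w[0] >= -rel_tol * max(w[-1], 1.0):
        return K
    return (V * np.maximum(w, 0.0)) @ V.T


class KernelKMeans(ClusterMixin, BaseEstimator):
    """Kernel k-means on a precomputed kernel matrix.

    Parameters
    ----------
    n_clusters : int
        Number of clusters (the ploidy, for haplotype assembly).
    n_init : int
        Random restarts; the assignment with the lowest within-cluster
        kernel distance objective is kept.
    max_iter : int
        Iteration cap per restart.
    random_state : int, Generator or None
        Seeds the restart initialisations.

    Attributes
    ----------
    labels_ : (n,) int array of cluster assignments in {0..k-1}.
    inertia_ : float, the kernel k-means objective of ``labels_``.
    n_iter_ : int, iterations used by the winning restart batch.
    """

    def __init__(self, n_clusters: int = 2, n_init: int = 10,
                 max_iter: int = 100, random_state=None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None, init_labels: np.ndarray | None = None):
        """Cluster using the precomputed kernel ``X`` (n x n).

        ``init_labels`` optionally warm-starts one restart from an existing
        assignment (the remaining ``n_init - 1`` start randomly).
        """
        K = np.asarray(X, dtype=np.float64)
        n = K.shape[0]
        k = self.n_clusters
        if K.ndim != 2 or K.shape[1] != n:
            raise ValueError("kernel matrix must be square")
        if k > n:
            raise ValueError(f"n_clusters={k} exceeds number of points n={n}")
        rng = (self.random_state if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        if k == 1:
            self.labels_ = np.zeros(n, dtype=np.int64)
            self.inertia_ = float(np.trace(K) - K.sum() / n)
            self.n_iter_ = 0
            return self

        R = self.n_init
        labels = np.empty((R, n), dtype=np.int64)
        for r in range(R):
            if r == 0 and init_labels is not None:
                labels[r] = np.asarray(init_labels, dtype=np.int64)
            else:
                # random init with every cluster represented
                lab = rng.integers(0, k, size=n)
                lab[rng.permutation(n)[:k]] = np.arange(k)
                labels[r] = lab
        diag = np.diag(K)
        eye_k = np.eye(k)
        n_iter = 0
        for it in range(self.max_iter):
            n_iter = it + 1
            M = eye_k[labels]                                # (R, n, k)
            sizes = M.sum(axis=1)                            # (R, k)
            KM = np.einsum("ij,rjk->rik", K, M)              # (R, n, k)
            quad = np.einsum("rik,rik->rk", M, KM)           # (R, k)
            safe = np.maximum(sizes, 1.0)
            dist = (diag[None, :, None]
                    - 2.0 * KM / safe[:, None, :]
                    + (quad / safe**2)[:, None, :])
            dist[:, :, :][np.broadcast_to((sizes == 0)[:, None, :], dist.shape)] = np.inf
            new_labels = dist.argmin(axis=2)
            # reseed empty clusters with the point farthest from its centroid
            M_new = eye_k[new_labels]
            empty = M_new.sum(axis=1) == 0                   # (R, k)
            if empty.any():
                cur = np.take_along_axis(dist, new_labels[:, :, None], axis=2)[:, :, 0]
                for r, c in zip(*np.nonzero(empty)):
                    far = int(np.argmax(cur[r]))
                    new_labels[r, far] = c
                    cur[r, far] = -np.inf
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        # final objective per restart
        M = eye_k[labels]
        sizes = np.maximum(M.sum(axis=1), 1.0)
        KM = np.einsum("ij,rjk->rik", K, M)
        quad = np.einsum("rik,rik->rk", M, KM)
        dist = (diag[None, :, None] - 2.0 * KM / sizes[:, None, :]
                + (quad / sizes**2)[:, None, :])
        obj = np.take_along_axis(dist, labels[:, :, None], axis=2)[:, :, 0].sum(axis=1)
        best = int(np.argmin(obj))
        self.labels_ = labels[best].copy()
        self.inertia_ = float(obj[best])
        self.n_iter_ = n_iter
        return self

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, **kwargs).labels_


def kernel_kmeans(sigma: np.ndarray, k: int, seed=None, n_init: int = 10,
                  init_labels: np.ndarray | None = None) -> np.ndarray:
    """Cluster reads with kernel k-means; returns labels in {0..k-1}.

    Indefinite kernels are repaired by eigenvalue clipping first.
    """
    K = psd_clip(sigma)
    km = KernelKMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit(K, init_labels=init_labels).labels_
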