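"""Mean-centred PCA and Kennard-Stone representative ranking.

PCA here is deliberately minimal: an SVD of the mean-centred matrix with a
fixed sign convention (each loading column oriented so its largest-magnitude
entry is positive) so scores are reproducible across platforms.  The
Kennard-Stone ranking is the classical maximin procedure used in chemometrics
to pick calibration samples: start from the most distant pair, then repeatedly
add the sample farthest (in minimum Euclidean distance) from everything
already selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCAModel", "KSRanking", "pca_fit", "pca_transform", "kennard_stone_rank"]


@dataclass
class PCAModel:
    """Fitted principal-component model.

    Attributes
    ----------
    mean : ndarray, shape (n_points,)
        Training mean, subtracted before projection.
    loadings : ndarray, shape (n_points, n_components)
        Orthonormal loading columns.
    explained_variance : ndarray, shape (n_components,)
        Per-component variance (divisor n - 1).
    explained_variance_ratio : ndarray, shape (n_components,)
        Fractions of total variance, non-increasing.
    """

    mean: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project rows of ``X`` with the training-era mean and loadings."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean.size:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {self.mean.size}"
            )
        return (X - self.mean) @ self.loadings

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        return scores @ self.loadings.T + self.mean


def pca_fit(X: np.ndarray, n_components: int) -> PCAModel:
    """Fit mean-centred PCA by SVD.

    ``n_components`` must not exceed ``min(n_samples - 1, n_points)``.  With
    all components kept, ``inverse_transform(transform(X))`` reconstructs
    ``X`` to numerical precision.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    max_comp = min(n - 1, p)
    if not (1 <= n_components <= max_comp):
        raise ValueError(
            f"n_components={n_components} not in [1, {max_comp}] for shape {X.shape}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (n - 1)
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    loadings = Vt[:n_components].T.copy()
    # sign convention: largest-magnitude entry of each loading positive
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCAModel(
        mean=mean,
        loadings=loadings,
        explained_variance=var[:n_components].copy(),
        explained_variance_ratio=ratio[:n_components].copy(),
    )


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`PCAModel.transform`."""
    return model.transform(X)


@dataclass
class KSRanking:
    """Permutation of sample indices, most representative first."""

    order: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        n = self.order.size
        if not np.array_equal(np.sort(self.order), np.arange(n)):
            raise ValueError("order must be a permutation of 0..n-1")

    def head(self, m: int) -> np.ndarray:
        return self.order[:m]


def kennard_stone_rank(X: np.ndarray) -> KSRanking:
    """Rank all samples by the Kennard-Stone maximin criterion.

    The first two indices are the maximum-distance pair (ordered ascending);
    each further index maximizes the minimum Euclidean distance to all
    previously selected samples.  Ties are broken toward the lowest index, so
    the ranking is deterministic.  The ranking has the prefix property: the
    first ``m`` selections are independent of how far the ranking is read.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("Kennard-Stone ranking requires at least 2 samples")
    sq = np.sum(X**2, axis=1)
    D = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0))
    # initial pair: maximum distance, lexicographically lowest on ties
    iu = np.triu_indices(n, k=1)
    flat = D[iu]
    best = np.argmax(flat)  # argmax returns first (lowest i, then lowest j)
    i0, j0 = iu[0][best], iu[1][best]
    order = [int(i0), int(j0)]
    remaining = np.ones(n, dtype=bool)
    remaining[[i0, j0]] = False
    mindist = np.minimum(D[i0], D[j0])
    while remaining.any():
        cand = np.flatnonzero(remaining)
        nxt = cand[np.argmax(mindist[cand])]  # first max -> lowest index tie-break
        order.append(int(nxt))
        remaining[nxt] = False
        mindist = np.minimum(mindist, D[nxt])
    return KSRanking(order=np.array(order))
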