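"""k-nearest-neighbour data description.

A test point ``z`` is compared with the local density of the training set via
a distance ratio: the distance from ``z`` to its k-th nearest training
neighbour, divided by that neighbour's own k-th nearest-neighbour distance
(searched excluding itself).  A ratio <= threshold (default 1) means the local
density at ``z`` is at least that at its neighbour, so ``z`` is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["KNNDD", "KNNDDResults", "knndd_fit"]


class KNNDD:
    """k-NN data description model.

    Parameters
    ----------
    X : ndarray, shape (n_samples, n_features)
        Target-class training data.
    k : int
        Neighbour order (>= 1, < n_samples); default 1, the first neighbour.
    threshold : float
        Acceptance bound on the distance ratio; default 1.0.
    """

    def __init__(self, X: np.ndarray, k: int = 1, threshold: float = 1.0) -> None:
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        n = self.X.shape[0]
        if not 1 <= k < n:
            raise ValueError(f"k must satisfy 1 <= k < n_training (k={k}, n={n})")
        if not threshold > 0:
            raise ValueError("threshold must be positive")
        self.k = int(k)
        self.threshold = float(threshold)

    def fit(self) -> "KNNDDResults":
        tree = cKDTree(self.X)
        # k-th neighbour distance of each training point, excluding itself
        d, _ = tree.query(self.X, k=self.k + 1)
        own_kdist = d[:, self.k]
        return KNNDDResults(model=self, tree=tree, train_kdist=own_kdist)


@dataclass
class KNNDDResults:
    """Fitted KNNDD: stored training set and per-point k-NN distances."""

    model: KNNDD
    tree: cKDTree
    train_kdist: np.ndarray

    def score(self, Z: np.ndarray) -> np.ndarray:
        """Distance-ratio novelty score (low = target-like).

        ``||z - NN_k(z)|| / ||NN_k(z) - NN_k(NN_k(z))||``; a zero denominator
        yields 0 when the numerator is also zero (duplicate of a duplicated
        training point: accept) and +inf otherwise (reject).
        """
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.model.X.shape[1]:
            raise ValueError(
                f"dimension mismatch: {Z.shape[1]} vs {self.model.X.shape[1]}"
            )
        k = self.model.k
        d, idx = self.tree.query(Z, k=k)
        if k == 1:
            num, nbr = d.ravel(), idx.ravel()
        else:
            num, nbr = d[:, k - 1], idx[:, k - 1]
        den = self.train_kdist[nbr]
        with np.errstate(divide="ignore", invalid="ignore"):
            s = num / den
        s = np.where(den == 0, np.where(num == 0, 0.0, np.inf), s)
        return s

    def predict(self, Z: np.ndarray) -> np.ndarray:
        """Boolean acceptance per row: score <= threshold."""
        return self.score(Z) <= self.model.threshold

    def summary(self) -> str:
        return "\n".join(
            [
                "k-Nearest-Neighbour Data Description",
                "=" * 39,
                f"n training samples     {self.model.X.shape[0]:>8d}",
                f"neighbour order k      {self.model.k:>8d}",
                f"acceptance threshold   {self.model.threshold:>8.3f}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "type": "knndd",
            "k": self.model.k,
            "threshold": self.model.threshold,
            "training": self.model.X.tolist(),
        }


def knndd_fit(X: np.ndarray, k: int = 1, threshold: float = 1.0) -> KNNDDResults:
    """Convenience constructor+fit; see :class:`KNNDD`."""
    return KNNDD(X, k=k, threshold=threshold).fit()
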