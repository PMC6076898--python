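"""Kernel functions for the hypersphere data description.

The RBF kernel is ``exp(-||a - b||^2 / sigma^2)``.  Note the convention:
there is **no factor 2** in the denominator, so sigma here equals
``sqrt(2) * sigma`` of the common ``exp(-||.||^2 / (2 sigma^2))`` form and
maps to scikit-learn's ``gamma = 1 / sigma^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KernelSpec", "rbf_kernel", "kernel_matrix"]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice: ``kind`` in {"rbf", "linear"}; ``sigma`` (rbf width) > 0."""

    kind: str = "rbf"
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("rbf", "linear"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "rbf":
            if self.sigma is None or not self.sigma > 0:
                raise ValueError("rbf kernel requires sigma > 0")


def rbf_kernel(a: np.ndarray, b: np.ndarray, sigma: float) -> float:
    """RBF similarity ``exp(-||a-b||^2 / sigma^2)`` of two vectors, in (0, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"vector length mismatch: {a.size} vs {b.size}")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    return float(np.exp(-np.sum((a - b) ** 2) / sigma**2))


def kernel_matrix(kernel: KernelSpec, A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    """Gram matrix K[i, j] = K(A[i], B[j]) (B defaults to A)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = A if B is None else np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    if kernel.kind == "linear":
        return A @ B.T
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.exp(-np.maximum(d2, 0.0) / kernel.sigma**2)


def kernel_diag(kernel: KernelSpec, A: np.ndarray) -> np.ndarray:
    """Diagonal K(x, x) for each row of A."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if kernel.kind == "linear":
        return np.sum(A**2, axis=1)
    return np.ones(A.shape[0])
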