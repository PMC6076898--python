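"""Support vector data description: minimum enclosing hypersphere in kernel space.

The model seeks the smallest sphere (center ``a``, radius ``R``) that contains
the target training set, softened by slack variables with penalty ``C``:

    min  R^2 + C * sum_i xi_i    s.t.  ||phi(x_i) - a||^2 <= R^2 + xi_i

``C`` is parameterized through the user-facing rejection fraction ``f`` as
``C = 1 / (N f)``, so at most a fraction ``f`` of training samples can end up
outside the sphere (bounded support vectors).  The Lagrangian dual is the box-
and simplex-constrained quadratic program

    max  sum_i alpha_i K(x_i, x_i) - sum_ij alpha_i alpha_j K(x_i, x_j)
    s.t. sum_i alpha_i = 1,  0 <= alpha_i <= C,

solved here by a pairwise coordinate-ascent (SMO-style) scheme: at each step
the most KKT-violating pair exchanges mass along the equality constraint.
Unbounded support vectors (0 < alpha < C) lie exactly on the sphere and define
R^2; bounded ones (alpha = C) lie outside and are the rejected training
samples.  A test point is accepted when its squared kernel distance to the
center does not exceed R^2 (boundary points are accepted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kernels import KernelSpec, kernel_diag, kernel_matrix

__all__ = ["SVDD", "SVDDResults", "svdd_fit"]


class SVDDConvergenceWarning(UserWarning):
    pass


class SVDD:
    """Support vector data description model.

    Parameters
    ----------
    X : ndarray, shape (n_samples, n_features)
        Target-class training data.
    kernel : KernelSpec
        Kernel; RBF with width sigma (``exp(-||.||^2 / sigma^2)``) or linear.
    rejection_fraction : float
        Target-class error rate f in (0, 1); penalty ``C = 1 / (N f)``.
    """

    def __init__(
        self,
        X: np.ndarray,
        kernel: KernelSpec | None = None,
        rejection_fraction: float = 0.1,
    ) -> None:
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] < 1:
            raise ValueError("need at least one training sample")
        if not 0 < rejection_fraction < 1:
            raise ValueError("rejection_fraction must be in (0, 1)")
        self.kernel = kernel if kernel is not None else KernelSpec("rbf", 1.0)
        self.rejection_fraction = float(rejection_fraction)
        self.n = self.X.shape[0]
        self.C = 1.0 / (self.n * self.rejection_fraction)

    def fit(self, tol: float = 1e-8, max_iter: int = 100_000) -> "SVDDResults":
        """Solve the dual by pairwise coordinate ascent.

        Stops when the maximum KKT violation falls below ``tol`` (scaled by
        the kernel magnitude) or after ``max_iter`` pair updates.
        """
        n, C = self.n, self.C
        K = kernel_matrix(self.kernel, self.X)
        diag = np.diag(K).copy()
        if n == 1:
            alpha = np.array([1.0])
            return self._package(alpha, K, diag, kkt_violation=0.0, n_iter=0)

        alpha = np.full(n, 1.0 / n)
        Ka = K @ alpha
        # dual gradient along alpha_i: g_i = K_ii - 2 (K alpha)_i
        g = diag - 2.0 * Ka
        scale = max(1.0, float(np.max(np.abs(diag))))
        eps = 1e-12 * C
        viol = np.inf
        it = 0
        for it in range(1, max_iter + 1):
            up = alpha < C - eps
            down = alpha > eps
            gi_masked = np.where(up, g, -np.inf)
            gj_masked = np.where(down, g, np.inf)
            i = int(np.argmax(gi_masked))
            j = int(np.argmin(gj_masked))
            viol = g[i] - g[j]
            if viol < tol * scale:
                break
            eta = 2.0 * (K[i, i] - 2.0 * K[i, j] + K[j, j])
            t_max = min(C - alpha[i], alpha[j])
            t = t_max if eta <= 0 else min(viol / eta, t_max)
            if t <= 0:
                break
            alpha[i] += t
            alpha[j] -= t
            dK = K[:, i] - K[:, j]
            g -= 2.0 * t * dK
        else:
            warnings.warn(
                f"SVDD SMO did not reach tolerance after {max_iter} updates "
                f"(violation {viol:.3e})",
                SVDDConvergenceWarning,
            )
        return self._package(alpha, K, diag, kkt_violation=float(viol), n_iter=it)

    def _package(self, alpha, K, diag, kkt_violation, n_iter) -> "SVDDResults":
        C = self.C
        sv_mask = alpha > 1e-10 * C
        bounded = alpha > C * (1.0 - 1e-8)
        unbounded = sv_mask & ~bounded
        offset = float(alpha @ K @ alpha)
        dist2_train = diag - 2.0 * (K @ alpha) + offset
        boundary_tol = 1e-9
        if self.n == 1:
            radius2 = 0.0
        elif unbounded.any():
            radius2 = float(np.mean(dist2_train[unbounded]))
            # the solver stops at a small KKT residual, so unbounded SVs sit
            # within that residual of the sphere; widen the acceptance band
            # accordingly so boundary points are never rejected by round-off
            boundary_tol = max(
                boundary_tol, float(np.max(dist2_train[unbounded]) - radius2)
            )
        else:
            radius2 = float(np.max(dist2_train[sv_mask]))
            warnings.warn(
                "no unbounded support vector: radius set to the largest "
                "support-vector distance",
                SVDDConvergenceWarning,
            )
        radius2 = max(radius2, 0.0)
        return SVDDResults(
            model=self,
            alphas=alpha,
            support_mask=sv_mask,
            bounded_mask=bounded,
            radius2=radius2,
            offset=offset,
            dist2_train=dist2_train,
            kkt_violation=kkt_violation,
            n_iter=n_iter,
            boundary_tol=boundary_tol,
        )


@dataclass
class SVDDResults:
    """Fitted SVDD: support coefficients, squared radius and decision rule."""

    model: SVDD
    alphas: np.ndarray
    support_mask: np.ndarray
    bounded_mask: np.ndarray
    radius2: float
    offset: float
    dist2_train: np.ndarray
    kkt_violation: float
    n_iter: int
    #: acceptance band: points with dist2 <= radius2 + boundary_tol accepted
    #: (1e-9 floor, widened to the solver residual among boundary SVs)
    boundary_tol: float = 1e-9

    @property
    def support_vectors(self) -> np.ndarray:
        return self.model.X[self.support_mask]

    @property
    def n_support(self) -> int:
        return int(self.support_mask.sum())

    @property
    def n_bounded(self) -> int:
        return int(self.bounded_mask.sum())

    @property
    def center_linear(self) -> np.ndarray:
        """Sphere center in input space (linear kernel only)."""
        if self.model.kernel.kind != "linear":
            raise ValueError("explicit center only available for the linear kernel")
        return self.alphas @ self.model.X

    def distance2(self, Z: np.ndarray) -> np.ndarray:
        """Squared kernel distance ``K(z,z) - 2 sum_i alpha_i K(x_i,z) + offset``."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.model.X.shape[1]:
            raise ValueError(
                f"dimension mismatch: {Z.shape[1]} vs {self.model.X.shape[1]}"
            )
        sv = self.model.X[self.support_mask]
        a = self.alphas[self.support_mask]
        cross = kernel_matrix(self.model.kernel, Z, sv) @ a
        return kernel_diag(self.model.kernel, Z) - 2.0 * cross + self.offset

    def predict(self, Z: np.ndarray) -> np.ndarray:
        """Boolean acceptance per row: True = target (inside or on the sphere)."""
        return self.distance2(Z) <= self.radius2 + self.boundary_tol

    def training_rejection_rate(self) -> float:
        return float(np.mean(self.dist2_train > self.radius2 + self.boundary_tol))

    def dual_objective(self) -> float:
        K = kernel_matrix(self.model.kernel, self.model.X)
        return float(self.alphas @ np.diag(K) - self.alphas @ K @ self.alphas)

    def summary(self) -> str:
        k = self.model.kernel
        lines = [
            "Support Vector Data Description",
            "=" * 39,
            f"n training samples     {self.model.n:>8d}",
            f"kernel                 {k.kind:>8s}"
            + (f" (sigma={k.sigma:.4g})" if k.kind == "rbf" else ""),
            f"rejection fraction f   {self.model.rejection_fraction:>8.3f}",
            f"penalty C              {self.model.C:>8.4f}",
            f"support vectors        {self.n_support:>8d}",
            f"  bounded (outside)    {self.n_bounded:>8d}",
            f"squared radius R^2     {self.radius2:>8.5f}",
            f"train rejection rate   {self.training_rejection_rate():>8.3f}",
            f"KKT violation          {self.kkt_violation:>8.2e}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        k = self.model.kernel
        return {
            "type": "svdd",
            "kernel_kind": k.kind,
            "kernel_sigma": k.sigma,
            "rejection_fraction": self.model.rejection_fraction,
            "C": self.model.C,
            "radius2": self.radius2,
            "offset": self.offset,
            "support_vectors": self.support_vectors.tolist(),
            "alphas": self.alphas[self.support_mask].tolist(),
        }


def svdd_fit(
    X: np.ndarray,
    kernel: KernelSpec | None = None,
    rejection_fraction: float = 0.1,
    **fit_kwargs,
) -> SVDDResults:
    """Convenience constructor+fit; see :class:`SVDD`."""
    return SVDD(X, kernel=kernel, rejection_fraction=rejection_fraction).fit(**fit_kwargs)
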