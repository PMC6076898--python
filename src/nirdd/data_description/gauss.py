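"""Unimodal Gaussian data description.

Fits a single multivariate normal to the target class (sample mean and
covariance, divisor n - 1) and accepts a point when its squared Mahalanobis
distance falls below the chi-square quantile at the chosen coverage: for
``d``-dimensional Gaussian data the squared Mahalanobis distance is
chi-square distributed with ``d`` degrees of freedom, so the threshold
``theta = chi2_d^{-1}(coverage)`` accepts the requested fraction of the
target population.

Badly conditioned or singular covariance is handled either by Tikhonov
regularization (``Sigma' = Sigma + lambda I``, the default, with a
scale-aware ``lambda = 1e-6 * trace(Sigma) / d``) or by the Moore-Penrose
pseudoinverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.stats import chi2

__all__ = ["GaussianDD", "GaussianDDResults", "gauss_fit", "chi2_quantile"]


class SingularCovarianceError(np.linalg.LinAlgError):
    pass


def chi2_quantile(d: int, coverage: float) -> float:
    """Inverse chi-square CDF with ``d`` degrees of freedom at ``coverage``."""
    if d < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    return float(chi2.ppf(coverage, df=d))


class GaussianDD:
    """Gaussian data description model.

    Parameters
    ----------
    X : ndarray, shape (n_samples, n_features)
        Target-class training data; ``n >= d + 1`` recommended for a
        full-rank covariance.
    lam : float or None
        Regularization lambda added to the covariance diagonal; ``None``
        (default) uses ``1e-6 * trace(Sigma) / d``.
    coverage : float
        Intended target acceptance fraction; default 0.95.
    inv_mode : {"regularized", "pseudoinverse"}
        How the covariance is inverted.
    """

    def __init__(
        self,
        X: np.ndarray,
        lam: float | None = None,
        coverage: float = 0.95,
        inv_mode: str = "regularized",
    ) -> None:
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 samples to estimate a covariance")
        if inv_mode not in ("regularized", "pseudoinverse"):
            raise ValueError(f"unknown inv_mode {inv_mode!r}")
        if lam is not None and lam < 0:
            raise ValueError("lambda must be non-negative")
        if not 0 < coverage < 1:
            raise ValueError("coverage must be in (0, 1)")
        self.lam = lam
        self.coverage = float(coverage)
        self.inv_mode = inv_mode

    def fit(self) -> "GaussianDDResults":
        X = self.X
        n, d = X.shape
        mu = X.mean(axis=0)
        sigma = np.cov(X, rowvar=False, ddof=1).reshape(d, d)
        lam = self.lam
        if lam is None:
            lam = 1e-6 * float(np.trace(sigma)) / d
        sigma_reg = sigma + lam * np.eye(d)
        if self.inv_mode == "pseudoinverse":
            precision = np.linalg.pinv(sigma_reg)
        else:
            try:
                cho = linalg.cho_factor(sigma_reg, lower=True)
                precision = linalg.cho_solve(cho, np.eye(d))
            except np.linalg.LinAlgError:
                raise SingularCovarianceError(
                    "covariance matrix is singular; use lambda > 0 or "
                    "inv_mode='pseudoinverse'"
                ) from None
            # Cholesky succeeds on PSD-singular matrices only by luck of
            # rounding; verify conditioning explicitly when lam == 0
            if lam == 0.0 and np.linalg.matrix_rank(sigma) < d:
                raise SingularCovarianceError(
                    "covariance matrix is rank-deficient; use lambda > 0 or "
                    "inv_mode='pseudoinverse'"
                )
        theta = chi2_quantile(d, self.coverage)
        return GaussianDDResults(
            model=self,
            mu=mu,
            sigma_reg=sigma_reg,
            precision=precision,
            lam=float(lam),
            theta=theta,
            d=d,
        )


@dataclass
class GaussianDDResults:
    """Fitted Gaussian description: mean, regularized covariance, threshold."""

    model: GaussianDD
    mu: np.ndarray
    sigma_reg: np.ndarray
    precision: np.ndarray
    lam: float
    theta: float
    d: int

    def mahalanobis2(self, Z: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of each row to the fitted mean."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.d:
            raise ValueError(f"dimension mismatch: {Z.shape[1]} vs {self.d}")
        diff = Z - self.mu
        return np.einsum("ij,jk,ik->i", diff, self.precision, diff)

    def predict(self, Z: np.ndarray) -> np.ndarray:
        """Boolean acceptance per row: Mahalanobis^2 <= theta."""
        return self.mahalanobis2(Z) <= self.theta

    def summary(self) -> str:
        return "\n".join(
            [
                "Gaussian Data Description",
                "=" * 39,
                f"n training samples     {self.model.X.shape[0]:>8d}",
                f"dimension d            {self.d:>8d}",
                f"coverage               {self.model.coverage:>8.3f}",
                f"lambda                 {self.lam:>8.3e}",
                f"inv mode               {self.model.inv_mode:>14s}",
                f"chi2 threshold theta   {self.theta:>8.4f}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "type": "gauss",
            "mu": self.mu.tolist(),
            "sigma_reg": self.sigma_reg.tolist(),
            "lambda": self.lam,
            "coverage": self.model.coverage,
            "inv_mode": self.model.inv_mode,
            "theta": self.theta,
            "d": self.d,
        }


def gauss_fit(
    X: np.ndarray,
    lam: float | None = None,
    coverage: float = 0.95,
    inv_mode: str = "regularized",
) -> GaussianDDResults:
    """Convenience constructor+fit; see :class:`GaussianDD`."""
    return GaussianDD(X, lam=lam, coverage=coverage, inv_mode=inv_mode).fit()
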