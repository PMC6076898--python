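"""SVDD: kernel values, dual optimality, oracle equivalences, decision rule."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.optimize import minimize

from nirdd.data_description import KernelSpec, kernel_matrix, rbf_kernel, svdd_fit


def qp_oracle_dual(K, C):
    """Generic solver (SLSQP) for the SVDD dual; returns (alpha, objective)."""
    n = K.shape[0]
    diag = np.diag(K)

    def obj(a):
        return -(a @ diag - a @ K @ a)

    def jac(a):
        return -(diag - 2 * K @ a)

    sol = minimize(
        obj,
        np.full(n, 1.0 / n),
        jac=jac,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0}],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 1000},
    )
    return sol.x, -sol.fun


def meb_oracle_2d(X):
    """Exact minimum enclosing ball in <=2-D by enumerating boundary subsets."""
    X = np.asarray(X, dtype=float)
    best = None
    for i, j in itertools.combinations(range(len(X)), 2):
        c = (X[i] + X[j]) / 2
        r2 = np.sum((X[i] - c) ** 2)
        if np.all(np.sum((X - c) ** 2, axis=1) <= r2 + 1e-12):
            if best is None or r2 < best[1]:
                best = (c, r2)
    if best is not None:
        return best
    for i, j, k in itertools.combinations(range(len(X)), 3):
        A = 2 * np.array([X[j] - X[i], X[k] - X[i]])
        b = np.array(
            [X[j] @ X[j] - X[i] @ X[i], X[k] @ X[k] - X[i] @ X[i]]
        )
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        c = np.linalg.solve(A, b)
        r2 = np.sum((X[i] - c) ** 2)
        if np.all(np.sum((X - c) ** 2, axis=1) <= r2 + 1e-12):
            if best is None or r2 < best[1]:
                best = (c, r2)
    return best


class TestRBFKernel:
    def test_identical_vectors(self):
        assert rbf_kernel([1.0, 2.0], [1.0, 2.0], sigma=0.7) == pytest.approx(1.0)

    def test_hand_value(self):
        # unit separation at sigma 1: exp(-1), note no factor 2 in denominator
        assert rbf_kernel([0.0, 0.0], [1.0, 0.0], 1.0) == pytest.approx(
            np.exp(-1.0), abs=1e-12
        )

    def test_large_sigma_limit(self):
        assert rbf_kernel([0.0], [3.0], sigma=1e6) == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            rbf_kernel([0.0], [0.0, 1.0], 1.0)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            KernelSpec("rbf", 0.0)
        with pytest.raises(ValueError):
            KernelSpec("cubic")


class TestSVDDFit:
    def test_single_point(self):
        r = svdd_fit(np.array([[2.0, 3.0]]), KernelSpec("rbf", 1.0), 0.1)
        np.testing.assert_allclose(r.alphas, [1.0])
        assert r.radius2 == 0.0
        assert r.predict(np.array([[2.0, 3.0]]))[0]

    def test_linear_three_points(self):
        X = np.array([[0.0], [1.0], [2.0]])
        r = svdd_fit(X, KernelSpec("linear"), rejection_fraction=0.1)
        np.testing.assert_allclose(r.center_linear, [1.0], atol=1e-6)
        assert r.radius2 == pytest.approx(1.0, abs=1e-6)
        assert set(np.flatnonzero(r.support_mask)) == {0, 2}
        assert r.distance2(np.array([[5.0]]))[0] == pytest.approx(16.0, abs=1e-5)

    def test_alpha_constraints(self, rng):
        X = rng.normal(size=(25, 3))
        f = 0.2
        r = svdd_fit(X, KernelSpec("rbf", 1.5), f)
        assert r.alphas.sum() == pytest.approx(1.0, abs=1e-8)
        C = 1.0 / (25 * f)
        assert np.all(r.alphas >= -1e-12) and np.all(r.alphas <= C + 1e-12)
        assert r.n_bounded <= int(np.ceil(f * 25))

    @pytest.mark.parametrize("seed", range(6))
    def test_dual_matches_qp_oracle_small(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        X = rng.normal(size=(n, 2))
        f = float(rng.uniform(0.1, 0.5))
        ker = KernelSpec("rbf", float(rng.uniform(0.5, 3.0)))
        r = svdd_fit(X, ker, f)
        _, obj = qp_oracle_dual(kernel_matrix(ker, X), 1.0 / (n * f))
        assert r.dual_objective() == pytest.approx(obj, abs=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_linear_hard_margin_matches_meb_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 10
        X = rng.normal(size=(n, 2))
        # f small enough that C >= 1: hard-margin minimum enclosing ball
        r = svdd_fit(X, KernelSpec("linear"), rejection_fraction=0.5 / n)
        c, r2 = meb_oracle_2d(X)
        np.testing.assert_allclose(r.center_linear, c, atol=1e-5)
        assert r.radius2 == pytest.approx(r2, abs=1e-5)

    def test_training_rejection_bounded_by_f(self, rng):
        X = rng.normal(size=(40, 2))
        f = 0.15
        r = svdd_fit(X, KernelSpec("rbf", 2.0), f)
        assert r.training_rejection_rate() <= f + 1.0 / 40 + 1e-12

    def test_large_sigma_approaches_linear_solution(self, rng):
        """sigma >> data diameter: RBF boundary degenerates to the rigid
        hypersphere, i.e. the linear-kernel accepted set."""
        X = rng.normal(size=(30, 2))
        diam = max(
            np.linalg.norm(a - b) for a in X for b in X
        )
        r_rbf = svdd_fit(X, KernelSpec("rbf", 100.0 * diam), 0.1)
        r_lin = svdd_fit(X, KernelSpec("linear"), 0.1)
        np.testing.assert_array_equal(r_rbf.predict(X), r_lin.predict(X))

    def test_invalid_rejection_fraction(self):
        with pytest.raises(ValueError, match="rejection_fraction"):
            svdd_fit(np.zeros((3, 1)), KernelSpec("linear"), 0.0)


class TestSVDDDecision:
    def test_unbounded_sv_on_boundary_and_accepted(self, rng):
        X = rng.normal(size=(20, 2))
        r = svdd_fit(X, KernelSpec("rbf", 1.5), 0.2)
        unbounded = r.support_mask & ~r.bounded_mask
        assert unbounded.any()
        d2 = r.distance2(X[unbounded])
        np.testing.assert_allclose(d2, r.radius2, atol=1e-6)
        assert r.predict(X[unbounded]).all()

    def test_center_accepted_far_point_rejected(self, rng):
        X = rng.normal(size=(15, 2))
        r = svdd_fit(X, KernelSpec("rbf", 2.0), 0.1)
        assert r.predict(X.mean(axis=0)[None])[0]
        assert not r.predict(np.array([[50.0, -40.0]]))[0]

    def test_dimension_mismatch(self, rng):
        r = svdd_fit(rng.normal(size=(5, 2)), KernelSpec("rbf", 1.0), 0.2)
        with pytest.raises(ValueError, match="mismatch"):
            r.distance2(np.zeros((1, 3)))

    def test_predictions_deterministic(self, rng):
        X = rng.normal(size=(20, 2))
        Z = rng.normal(size=(10, 2))
        r = svdd_fit(X, KernelSpec("rbf", 1.0), 0.1)
        np.testing.assert_array_equal(r.predict(Z), r.predict(Z))

    @pytest.mark.parametrize("seed", range(10))
    def test_accepted_set_matches_ocsvm_oracle(self, seed):
        """nu-one-class-SVM with nu=f and matched width is dual-equivalent
        for the RBF kernel (K(x,x) constant): decisions must agree away
        from the numerical boundary."""
        OneClassSVM = pytest.importorskip("sklearn.svm").OneClassSVM
        rng = np.random.default_rng(200 + seed)
        X = rng.normal(size=(30, 2))
        f, sigma = 0.1, 2.0
        r = svdd_fit(X, KernelSpec("rbf", sigma), f)
        oc = OneClassSVM(kernel="rbf", gamma=1.0 / sigma**2, nu=f, tol=1e-9).fit(X)
        Z = np.vstack([X, rng.normal(size=(50, 2)) * 1.5])
        robust = np.abs(r.distance2(Z) - r.radius2) > 1e-6
        np.testing.assert_array_equal(
            r.predict(Z)[robust], oc.decision_function(Z)[robust] >= 0
        )


def test_no_unbounded_sv_falls_back_with_warning():
    # two identical + one distant point with tiny C forces all alphas to bound
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        r = svdd_fit(X, KernelSpec("rbf", 0.5), rejection_fraction=0.999999)
    assert r.radius2 >= 0.0
    # either converged with unbounded SVs or warned about the fallback
    if not (r.support_mask & ~r.bounded_mask).any():
        assert any("unbounded" in str(w.message) for w in rec)
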