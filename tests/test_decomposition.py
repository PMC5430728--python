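"""Multilinear primitives, regularized updates and the full solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from phenotensor import RunConfig, TrainingSplit, fit_model
from phenotensor.decomposition import (
    FactorModel,
    compute_fit,
    factor_gradient,
    factor_objective,
    fit_theta_ridge,
    khatri_rao,
    mode_fold,
    mode_unfold,
    mortality_neg_log_likelihood,
    newton_update_factor,
    newton_update_patient_row,
    newton_update_patient_rows,
    normalize_and_threshold,
    patient_row_objective,
    _factor_hessian,
    _row_grad_hess,
)
from phenotensor.errors import DegenerateLabelsError, ParameterError, UndefinedFitError
from phenotensor.synthetic import PlantSpec, plant_factors


class TestKhatriRao:
    def test_identity_pattern(self):
        out = khatri_rao(np.eye(2), np.eye(2))
        expected = np.zeros((4, 2))
        expected[0, 0] = 1.0  # kron(e1, e1)
        expected[3, 1] = 1.0  # kron(e2, e2)
        np.testing.assert_array_equal(out, expected)

    def test_column_norm_multiplicativity(self):
        rng = np.random.default_rng(0)
        m1, m2 = rng.random((5, 3)), rng.random((4, 3))
        norms = np.linalg.norm(khatri_rao(m1, m2), axis=0)
        np.testing.assert_allclose(norms, np.linalg.norm(m1, axis=0) * np.linalg.norm(m2, axis=0))

    def test_column_mismatch(self):
        with pytest.raises(ParameterError):
            khatri_rao(np.ones((2, 2)), np.ones((2, 3)))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 4), st.integers(1, 5), st.integers(1, 5))
    def test_matches_columnwise_kron_definition(self, seed, r, n1, n2):
        rng = np.random.default_rng(seed)
        m1, m2 = rng.normal(size=(n1, r)), rng.normal(size=(n2, r))
        out = khatri_rao(m1, m2)
        assert out.shape == (n1 * n2, r)
        for col in range(r):
            np.testing.assert_allclose(out[:, col], np.kron(m1[:, col], m2[:, col]))


class TestUnfolding:
    def test_index_arithmetic_2x2x2(self):
        t = np.arange(1, 9, dtype=float).reshape(2, 2, 2)
        o1 = mode_unfold(t, 1)
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    assert o1[i, k * 2 + j] == t[i, j, k]

    @pytest.mark.parametrize("mode", [1, 2, 3])
    def test_fold_unfold_involution(self, mode):
        rng = np.random.default_rng(1)
        t = rng.random((3, 4, 5))
        np.testing.assert_array_equal(mode_fold(mode_unfold(t, mode), mode, t.shape), t)

    def test_khatri_rao_reconstruction_identity(self):
        rng = np.random.default_rng(2)
        a, b, c = rng.random((3, 2)), rng.random((4, 2)), rng.random((5, 2))
        t = np.einsum("ir,jr,kr->ijk", a, b, c)
        np.testing.assert_allclose(mode_unfold(t, 1), a @ khatri_rao(c, b).T, atol=1e-12)
        np.testing.assert_allclose(mode_unfold(t, 2), b @ khatri_rao(c, a).T, atol=1e-12)
        np.testing.assert_allclose(mode_unfold(t, 3), c @ khatri_rao(b, a).T, atol=1e-12)


class TestSupervisedPieces:
    def test_nll_basics(self):
        theta = np.zeros(4)
        assert mortality_neg_log_likelihood(np.ones(3), 1, theta) == pytest.approx(np.log(2))
        big = np.array([0.0, 0.0, 0.0, 1000.0])
        assert mortality_neg_log_likelihood(np.zeros(3), 1, big) == pytest.approx(0.0, abs=1e-12)
        rng = np.random.default_rng(3)
        a, th = rng.normal(size=3), rng.normal(size=4)
        delta = a @ th[:3] + th[3]
        direct = -np.log(1.0 / (1.0 + np.exp(-(-1) * delta)))
        assert mortality_neg_log_likelihood(a, -1, th) == pytest.approx(direct)

    def test_row_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        r = 3
        B, C = rng.random((5, r)), rng.random((6, r))
        kr = khatri_rao(C, B)
        a = rng.random(r)
        o_row = rng.random(30)
        theta = rng.normal(size=r + 1)
        omega, y = 2.0, -1
        grad, hess = _row_grad_hess(a, y, theta, kr.T @ kr, o_row @ kr, omega)
        eps = 1e-6
        for idx in range(r):
            ap, am = a.copy(), a.copy()
            ap[idx] += eps
            am[idx] -= eps
            fd = (patient_row_objective(ap, y, theta, B, C, o_row, omega)
                  - patient_row_objective(am, y, theta, B, C, o_row, omega)) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-5)
        # Hessian vs finite differences of the gradient
        for idx in range(r):
            ap, am = a.copy(), a.copy()
            ap[idx] += eps
            am[idx] -= eps
            gp, _ = _row_grad_hess(ap, y, theta, kr.T @ kr, o_row @ kr, omega)
            gm, _ = _row_grad_hess(am, y, theta, kr.T @ kr, o_row @ kr, omega)
            np.testing.assert_allclose(hess[:, idx], (gp - gm) / (2 * eps), rtol=1e-4)

    def test_row_step_stationary_at_least_squares(self):
        rng = np.random.default_rng(5)
        r = 3
        B, C = rng.random((5, r)), rng.random((6, r))
        a_star = rng.random(r)
        o_row = a_star @ khatri_rao(C, B).T  # exact rank-R data
        new = newton_update_patient_row(a_star, 1, np.zeros(r + 1), B, C, o_row, omega=0.0)
        assert np.linalg.norm(new - a_star) <= 1e-6

    def test_batched_sweep_matches_single_row_updates(self):
        rng = np.random.default_rng(6)
        i, r = 7, 3
        B, C = rng.random((4, r)), rng.random((5, r))
        A = rng.random((i, r))
        O1 = rng.random((i, 20))
        y = np.where(rng.random(i) < 0.5, 1, -1)
        theta = rng.normal(size=r + 1)
        mask = np.ones(i, dtype=bool)
        batched = newton_update_patient_rows(A, y, theta, B, C, O1, 1.5, mask)
        for row in range(i):
            single = newton_update_patient_row(A[row], y[row], theta, B, C, O1[row], 1.5)
            np.testing.assert_allclose(batched[row], single, atol=1e-8)


class TestFitThetaRidge:
    def test_matches_generic_optimizer(self):
        rng = np.random.default_rng(7)
        A_L = rng.random((40, 3))
        y = np.where(rng.random(40) < 0.5, 1.0, -1.0)
        c = 0.7
        theta = fit_theta_ridge(A_L, y, c)
        design = np.hstack([A_L, np.ones((40, 1))])

        def obj(th):
            return np.sum(np.logaddexp(0, -y * (design @ th))) + c * th @ th

        ref = minimize(obj, np.zeros(4), method="BFGS")
        assert obj(theta) <= ref.fun + 1e-8

    def test_separation_stays_finite_and_large_c_shrinks(self):
        x = np.linspace(-1, 1, 20).reshape(-1, 1)
        y = np.where(x[:, 0] > 0, 1.0, -1.0)
        theta = fit_theta_ridge(x, y, 0.5)
        assert np.all(np.isfinite(theta))
        tiny = fit_theta_ridge(x, y, 1e6)
        assert np.linalg.norm(tiny) < 1e-2

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            fit_theta_ridge(np.ones((5, 2)), np.ones(5), 1.0)


class TestFactorUpdates:
    def _instance(self, seed, j=5, r=2, mu=3.0):
        rng = np.random.default_rng(seed)
        B = rng.random((j, r))
        A, C = rng.random((4, r)), rng.random((6, r))
        O2 = rng.random((j, 24))
        s = rng.random((j, j))
        S = (s + s.T) / 2
        return B, A, C, O2, S, mu

    def test_gradient_matches_finite_differences(self):
        B, A, C, O2, S, mu = self._instance(8)
        grad = factor_gradient(B, A, C, O2, S, mu)
        eps = 1e-6
        for j in range(B.shape[0]):
            for r in range(B.shape[1]):
                bp, bm = B.copy(), B.copy()
                bp[j, r] += eps
                bm[j, r] -= eps
                fd = (factor_objective(bp, A, C, O2, S, mu) - factor_objective(bm, A, C, O2, S, mu)) / (2 * eps)
                assert grad[j, r] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_similarity_term_vanishes_when_s_equals_bbt(self):
        B, A, C, O2, _, mu = self._instance(9)
        S = B @ B.T
        base = factor_gradient(B, A, C, O2, S, 0.0)
        with_mu = factor_gradient(B, A, C, O2, S, mu)
        np.testing.assert_allclose(base, with_mu, atol=1e-12)

    def test_hessian_matches_fd_at_rank_one(self):
        B, A, C, O2, S, mu = self._instance(10, j=4, r=1)
        hess = _factor_hessian(B, (C.T @ C) * (A.T @ A), S, mu)
        eps = 1e-6
        for j in range(4):
            bp, bm = B.copy(), B.copy()
            bp[j, 0] += eps
            bm[j, 0] -= eps
            gp = factor_gradient(bp, A, C, O2, S, mu).ravel()
            gm = factor_gradient(bm, A, C, O2, S, mu).ravel()
            np.testing.assert_allclose(hess[:, j], (gp - gm) / (2 * eps), rtol=1e-4)

    def test_projection_nonnegative_and_objective_nonincreasing(self):
        B, A, C, O2, S, mu = self._instance(11)
        B = B - 0.5  # start with negatives
        before = factor_objective(np.maximum(B, 0), A, C, O2, S, mu)
        out = newton_update_factor(np.maximum(B, 0), A, C, O2, S, mu)
        assert np.all(out >= 0)
        assert factor_objective(out, A, C, O2, S, mu) <= before + 1e-9

    def test_rank_one_planted_recovery(self):
        rng = np.random.default_rng(12)
        a, b, c = rng.random(4) + 0.5, rng.random(5) + 0.5, rng.random(6) + 0.5
        t = np.einsum("i,j,k->ijk", a, b, c)
        O2 = mode_unfold(t, 2)
        B = rng.random((5, 1))
        for _ in range(20):
            B = newton_update_factor(B, a.reshape(-1, 1), c.reshape(-1, 1), O2, None, 0.0)
        cos = float(B[:, 0] @ b / (np.linalg.norm(B) * np.linalg.norm(b)))
        assert cos >= 0.999


class TestFitAndNormalization:
    def test_compute_fit_basics(self):
        rng = np.random.default_rng(13)
        o = rng.random((3, 4, 5))
        assert compute_fit(o, o) == pytest.approx(1.0)
        assert compute_fit(o, np.zeros_like(o)) == pytest.approx(0.0)
        x = rng.random((3, 4, 5))
        direct = 1 - np.linalg.norm(o - x) / np.linalg.norm(o)
        assert compute_fit(o, x) == pytest.approx(direct)
        with pytest.raises(UndefinedFitError):
            compute_fit(np.zeros((2, 2, 2)), x[:2, :2, :2])

    def test_normalize_and_threshold(self):
        A = np.array([[3.0, 0.0], [4.0, 0.0]])
        B = np.array([[1.0, 5e-4], [0.0, 2e-3]])
        C = np.array([[2.0, 1.0], [0.0, 0.0]])
        model = normalize_and_threshold(FactorModel(A=A, B=B, C=C, theta=np.zeros(3)))
        np.testing.assert_allclose(model.A_bar[:, 0], [0.6, 0.8])
        assert model.lam[0] == pytest.approx(5 * 1 * 2)
        assert model.lam[1] == 0.0  # zero A column
        # after normalization by its column norm, 5e-4/||.|| < 1e-3 is zeroed
        col1 = model.B_bar[:, 1]
        assert np.all((col1 == 0) | (col1 >= 1e-3))

    def test_reconstruction_identity_when_nothing_thresholded(self):
        rng = np.random.default_rng(14)
        A, B, C = rng.random((4, 3)) + 0.5, rng.random((5, 3)) + 0.5, rng.random((6, 3)) + 0.5
        model = normalize_and_threshold(FactorModel(A=A, B=B, C=C, theta=np.zeros(4)))
        raw = np.einsum("ir,jr,kr->ijk", A, B, C)
        rebuilt = np.einsum("r,ir,jr,kr->ijk", model.lam, model.A_bar, model.B_bar, model.C_bar)
        np.testing.assert_allclose(rebuilt, raw, atol=1e-10)


def test_symmetric_nmf_trace_identity():
    """||S - BB^T||^2 + 2 Tr(B^T S B) - ||S||^2 - ||B^T B||^2 == 0: maximizing
    the spectral-clustering trace and minimizing the symmetric-NMF residual
    rank candidate factors identically."""
    rng = np.random.default_rng(15)
    for _ in range(10):
        B = rng.random((7, 3))
        s = rng.random((7, 7))
        S = (s + s.T) / 2
        gap = (np.sum((S - B @ B.T) ** 2) + 2 * np.trace(B.T @ S @ B)
               - np.sum(S**2) - np.sum((B.T @ B) ** 2))
        assert abs(gap) <= 1e-9


class TestFitModel:
    def test_noiseless_low_rank_recovery(self):
        spec = PlantSpec(I=10, J=10, K=10, R_true=2, seed=16, lam_true=np.full(2, 80.0))
        a, b, c = plant_factors(spec)
        mean = np.einsum("ir,jr,kr->ijk", a, b, c)
        model = fit_model(mean, cfg=RunConfig(rank=2, omega=0, mu=0, seed=3, max_iter=100))
        assert model.fit_history[-1] >= 0.99

    def test_zero_weight_paths_identical_to_plain_cp(self):
        """Passing labels and similarity matrices with omega = mu = 0 must not
        perturb the trajectory at all."""
        rng = np.random.default_rng(17)
        t = rng.integers(0, 4, size=(8, 6, 7)).astype(float)
        y = np.where(rng.random(8) < 0.5, 1, -1)
        sb, sc = np.eye(6), np.eye(7)
        cfg = RunConfig(rank=3, omega=0.0, mu=0.0, seed=5, max_iter=15, min_iter=1)
        plain = fit_model(t, cfg=cfg)
        loaded = fit_model(t, sb, sc, y, split=TrainingSplit(np.arange(4)), cfg=cfg)
        np.testing.assert_array_equal(plain.A, loaded.A)
        np.testing.assert_array_equal(plain.B, loaded.B)
        np.testing.assert_array_equal(plain.C, loaded.C)

    def test_factors_nonnegative_and_fit_monotone_without_regularizers(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = rng.integers(0, 5, size=(10, 6, 5)).astype(float)
            model = fit_model(t, cfg=RunConfig(rank=2, omega=0, mu=0, seed=seed, max_iter=30, min_iter=1))
            assert model.A.min() >= 0 and model.B.min() >= 0 and model.C.min() >= 0
            fits = np.array(model.fit_history)
            assert np.all(np.diff(fits) >= -1e-9)

    def test_supervised_run_produces_theta(self, small_world):
        t, y = small_world["tensor"], small_world["labels"]
        cfg = RunConfig(rank=3, omega=1.0, mu=0.0, seed=2, max_iter=15, min_iter=1)
        model = fit_model(t, None, None, y, cfg=cfg)
        assert model.theta.shape == (4,)
        assert np.any(model.theta != 0)

    def test_mu_requires_similarities(self):
        with pytest.raises(ParameterError):
            fit_model(np.ones((2, 2, 2)), cfg=RunConfig(rank=1, omega=0, mu=10.0))
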