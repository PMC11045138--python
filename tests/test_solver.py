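"""Estimation core: projector, L1-ball solver, variable projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from bpwp.basis import build_dct_basis, build_polynomial_basis
from bpwp.solver import (
    BPWPProblem,
    fit_bpwp,
    joint_fit_oracle,
    project_l1_ball,
    reconstruct,
    recover_polynomial,
    residual_projector,
    solve_l1_constrained,
    solve_l1_constrained_multi,
)


def lars_constrained_oracle(A, y, delta):
    """Exact L1-ball-constrained solution from the piecewise-linear lasso path."""
    from sklearn.linear_model import lars_path

    _, _, coefs = lars_path(A, y, method="lasso")
    norms = np.abs(coefs).sum(axis=0)
    if delta >= norms[-1]:
        return coefs[:, -1]
    j = int(np.searchsorted(norms, delta))
    frac = (delta - norms[j - 1]) / (norms[j] - norms[j - 1])
    return coefs[:, j - 1] + frac * (coefs[:, j] - coefs[:, j - 1])


class TestResidualProjector:
    def test_all_ones_column_is_centering(self):
        P = residual_projector(np.ones((4, 1)))
        I = np.eye(4)
        assert np.allclose(P(I), I - np.ones((4, 4)) / 4, atol=1e-12)

    def test_annihilates_column_space(self, rng):
        B = rng.standard_normal((9, 3))
        P = residual_projector(B)
        assert np.max(np.abs(P(B))) < 1e-10

    def test_idempotent_and_symmetric(self, rng):
        B = rng.standard_normal((7, 2))
        P = residual_projector(B)
        M = P(np.eye(7))
        assert np.allclose(M @ M, M, atol=1e-10)
        assert np.allclose(M, M.T, atol=1e-12)

    def test_rank_deficient_warns(self):
        B = np.ones((5, 2))  # duplicated column
        with pytest.warns(UserWarning, match="rank-deficient"):
            residual_projector(B)


class TestL1Projection:
    def test_inside_ball_unchanged(self):
        v = np.array([0.2, -0.3, 0.1])
        assert np.array_equal(project_l1_ball(v, 1.0), v)

    def test_projection_properties(self, rng):
        for _ in range(20):
            v = rng.standard_normal(15) * 3
            r = float(rng.uniform(0.1, 2.0))
            w = project_l1_ball(v, r)
            assert np.abs(w).sum() <= r * (1 + 1e-12)
            # optimality: w is the closest point, checked against cvx-free
            # subgradient condition via random feasible perturbations
            for _ in range(20):
                u = project_l1_ball(w + rng.standard_normal(15) * 0.1, r)
                assert np.sum((v - w) ** 2) <= np.sum((v - u) ** 2) + 1e-9

    def test_zero_radius_maps_to_origin(self, rng):
        assert np.array_equal(project_l1_ball(rng.standard_normal(5), 0.0), np.zeros(5))

    @given(
        v=hnp.arrays(np.float64, st.integers(1, 30),
                     elements=st.floats(-1e6, 1e6, allow_nan=False)),
        r=st.floats(0.0, 1e6, allow_nan=False),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_projection_feasible_and_idempotent(self, v, r):
        w = project_l1_ball(v, r)
        assert np.abs(w).sum() <= r * (1 + 1e-9) + 1e-9
        assert np.allclose(project_l1_ball(w, r), w, atol=1e-9 * (1 + r))
        # projection never flips signs or grows magnitudes
        assert np.all(np.abs(w) <= np.abs(v) + 1e-12)
        assert np.all(w * v >= 0)


class TestConstrainedSolver:
    def test_delta_zero_gives_zero(self, rng):
        A = rng.standard_normal((5, 8))
        assert np.array_equal(solve_l1_constrained(A, rng.standard_normal(5), 0.0), np.zeros(8))

    def test_inactive_constraint_recovers_inverse(self, rng):
        A = rng.standard_normal((6, 6))
        y = rng.standard_normal(6)
        x_free = np.linalg.solve(A, y)
        x = solve_l1_constrained(A, y, 1.5 * np.abs(x_free).sum(), tol=1e-12)
        assert np.allclose(x, x_free, atol=1e-4)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_lasso_path_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        A = rng.standard_normal((6, 6))
        y = rng.standard_normal(6)
        delta = float(rng.uniform(0.2, 2.0))
        x = solve_l1_constrained(A, y, delta, tol=1e-12)
        x_star = lars_constrained_oracle(A, y, delta)
        f = np.sum((y - A @ x) ** 2)
        f_star = np.sum((y - A @ x_star) ** 2)
        assert abs(f - f_star) <= 1e-6 * (1 + f_star)

    def test_batched_matches_single(self, rng):
        A = rng.standard_normal((15, 25))
        Y = rng.standard_normal((15, 4))
        deltas = np.array([0.0, 0.5, 2.0, 50.0])
        X, obj, _ = solve_l1_constrained_multi(A, Y, deltas, tol=1e-12, check=False)
        for j in range(4):
            xj = solve_l1_constrained(A, Y[:, j], deltas[j], tol=1e-12, check=False)
            fj = np.sum((Y[:, j] - A @ xj) ** 2)
            assert abs(obj[j] - fj) <= 1e-7 * (1 + fj)
            assert np.abs(X[:, j]).sum() <= deltas[j] * (1 + 1e-6)

    def test_feasibility_and_interior_stationarity(self, rng):
        A = rng.standard_normal((12, 20))
        y = rng.standard_normal(12)
        for delta in (0.1, 1.0, 100.0):
            x = solve_l1_constrained(A, y, delta, tol=1e-12)
            assert np.abs(x).sum() <= delta * (1 + 1e-6)
            if np.abs(x).sum() < delta * (1 - 1e-6):
                grad = A.T @ (A @ x - y)
                assert np.max(np.abs(grad)) < 1e-4


class TestRecoverPolynomial:
    def test_x_zero_gives_ols_fit(self, rng):
        B = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        A = rng.standard_normal((10, 4))
        z = recover_polynomial(B, y, A, np.zeros(4))
        assert np.allclose(z, np.linalg.lstsq(B, y, rcond=None)[0], atol=1e-12)

    def test_exact_trend_recovered(self, rng):
        B = rng.standard_normal((10, 3))
        z0 = np.array([1.0, -2.0, 0.5])
        z = recover_polynomial(B, B @ z0, rng.standard_normal((10, 4)), np.zeros(4))
        assert np.allclose(z, z0, atol=1e-10)

    def test_pinv_dual_path(self, rng):
        # normal equations vs SVD pseudo-inverse agree on a well-posed instance
        B = rng.standard_normal((12, 3))
        y = rng.standard_normal(12)
        z1 = recover_polynomial(B, y, np.zeros((12, 1)), np.zeros(1))
        z2 = np.linalg.solve(B.T @ B, B.T @ y)
        assert np.allclose(z1, z2, atol=1e-8)


class TestFitBPWP:
    def test_zero_data_gives_zero_fit(self, rng):
        A = rng.standard_normal((8, 10))
        B = rng.standard_normal((8, 2))
        fit = fit_bpwp(BPWPProblem(y=np.zeros(8), A=A, B=B, delta=1.0))
        assert np.allclose(fit.x, 0) and np.allclose(fit.z, 0)
        assert fit.objective == pytest.approx(0.0, abs=1e-20)

    def test_exact_recovery_noiseless(self):
        N = 64
        basis = build_dct_basis(N)
        poly = build_polynomial_basis(np.arange(N, dtype=float), 1)
        x_true = np.zeros(N)
        x_true[[5, 20]] = [2.0, -1.0]
        z_true = np.array([3.0, 0.5])
        y = basis.matrix @ x_true + poly.matrix @ z_true
        fit = fit_bpwp(
            BPWPProblem(y=y, A=basis.matrix, B=poly.matrix, delta=np.abs(x_true).sum()),
            tol=1e-12,
        )
        assert np.allclose(fit.x, x_true, atol=1e-4)
        assert np.allclose(fit.z, z_true, atol=1e-4)

    def test_objective_nonincreasing_in_delta(self, rng):
        A = rng.standard_normal((12, 18))
        B = rng.standard_normal((12, 2))
        y = rng.standard_normal(12)
        objs = [
            fit_bpwp(BPWPProblem(y=y, A=A, B=B, delta=d), tol=1e-10).objective
            for d in np.geomspace(0.01, 10, 8)
        ]
        assert np.all(np.diff(objs) <= 1e-8)

    def test_l1_budget_respected(self, rng):
        A = rng.standard_normal((10, 30))
        B = rng.standard_normal((10, 2))
        fit = fit_bpwp(BPWPProblem(y=rng.standard_normal(10), A=A, B=B, delta=0.7), tol=1e-10)
        assert np.abs(fit.x).sum() <= 0.7 * (1 + 1e-6)


class TestJointOracle:
    @pytest.mark.parametrize("trial", range(20))
    def test_variable_projection_matches_joint(self, trial):
        rng = np.random.default_rng(5000 + trial)
        m, n, p = rng.integers(8, 20), rng.integers(4, 30), rng.integers(1, 4)
        prob = BPWPProblem(
            y=rng.standard_normal(m),
            A=rng.standard_normal((m, n)),
            B=rng.standard_normal((m, p)),
            delta=float(rng.uniform(0.1, 3.0)),
        )
        fit = fit_bpwp(prob, tol=1e-12)
        xo, zo = joint_fit_oracle(prob)
        fo = np.sum((prob.y - prob.A @ xo - prob.B @ zo) ** 2)
        assert abs(fit.objective - fo) <= 1e-6 * (1 + fo)

    def test_delta_zero_reduces_to_polynomial_ls(self, rng):
        m = 10
        B = rng.standard_normal((m, 2))
        y = rng.standard_normal(m)
        prob = BPWPProblem(y=y, A=rng.standard_normal((m, 5)), B=B, delta=0.0)
        x, z = joint_fit_oracle(prob)
        assert np.allclose(x, 0, atol=1e-8)
        assert np.allclose(z, np.linalg.lstsq(B, y, rcond=None)[0], atol=1e-6)

    def test_empty_trend_reduces_to_bpdn(self, rng):
        m = 8
        A = rng.standard_normal((m, 6))
        y = rng.standard_normal(m)
        prob = BPWPProblem(y=y, A=A, B=np.zeros((m, 0)), delta=0.8)
        x, _ = joint_fit_oracle(prob)
        xc = solve_l1_constrained(A, y, 0.8, tol=1e-12)
        f1 = np.sum((y - A @ x) ** 2)
        f2 = np.sum((y - A @ xc) ** 2)
        assert abs(f1 - f2) <= 1e-6 * (1 + f2)

    def test_size_guard(self, rng):
        prob = BPWPProblem(
            y=rng.standard_normal(60), A=rng.standard_normal((60, 60)),
            B=rng.standard_normal((60, 1)), delta=1.0,
        )
        with pytest.raises(ValueError):
            joint_fit_oracle(prob)


class TestReconstruct:
    def test_constant_trend_only(self):
        N = 32
        basis = build_dct_basis(N)
        poly = build_polynomial_basis(np.arange(N, dtype=float), 1)
        from bpwp.solver import BPWPFit

        fit = BPWPFit(x=np.zeros(N), z=np.array([4.5, 0.0]), delta=0.0,
                      objective=0.0, residual=np.zeros(N), solver_tolerance=1e-8)
        out = reconstruct(fit, basis, poly)
        assert np.allclose(out.values, 4.5)

    def test_full_fit_round_trip(self):
        N = 64
        basis = build_dct_basis(N)
        poly = build_polynomial_basis(np.arange(N, dtype=float), 1)
        x_true = np.zeros(N)
        x_true[[3, 11]] = [1.5, -0.7]
        z_true = np.array([2.0, 1.0])
        y = basis.matrix @ x_true + poly.matrix @ z_true
        fit = fit_bpwp(
            BPWPProblem(y=y, A=basis.matrix, B=poly.matrix, delta=np.abs(x_true).sum()),
            tol=1e-12,
        )
        out = reconstruct(fit, basis, poly)
        assert np.allclose(out.values, y, atol=1e-4)

    def test_keep_nothing_leaves_trend(self):
        N = 16
        basis = build_dct_basis(N)
        poly = build_polynomial_basis(np.arange(N, dtype=float), 1)
        from bpwp.solver import BPWPFit

        fit = BPWPFit(x=np.ones(N), z=np.array([1.0, 2.0]), delta=N + 0.0,
                      objective=0.0, residual=np.zeros(N), solver_tolerance=1e-8)
        out = reconstruct(fit, basis, poly, keep=np.zeros(N, dtype=bool))
        assert np.allclose(out.values, poly.matrix @ fit.z)

    def test_filter_length_mismatch_rejected(self):
        N = 8
        basis = build_dct_basis(N)
        poly = build_polynomial_basis(np.arange(N, dtype=float), 0)
        from bpwp.solver import BPWPFit

        fit = BPWPFit(x=np.zeros(N), z=np.zeros(1), delta=0.0, objective=0.0,
                      residual=np.zeros(N), solver_tolerance=1e-8)
        with pytest.raises(ValueError):
            reconstruct(fit, basis, poly, keep=np.zeros(3, dtype=bool))
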