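"""Unit tests for the core MTJL solver and its closed-form updates."""

import numpy as np
import pytest
import sklearn.linear_model

from mtjl import (
    MTJLHyperparams,
    MTJLRegressor,
    SingularTrialError,
    nuclear_norm,
    objective,
    solve_mtjl,
    trace_surrogate,
    update_Dr,
    update_b,
    update_w,
)
from _oracles import objective_direct, random_instance, ridge_with_intercept


class TestNuclearNorm:
    def test_diagonal(self):
        assert nuclear_norm(np.diag([3.0, 4.0])) == pytest.approx(7.0)

    def test_zero_matrix(self):
        assert nuclear_norm(np.zeros((4, 3))) == 0.0

    def test_matches_svd_oracle(self, rng):
        W = rng.standard_normal((4, 3))
        expected = float(np.linalg.svd(W, compute_uv=False).sum())
        assert nuclear_norm(W) == pytest.approx(expected, rel=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="non-finite"):
            nuclear_norm(np.array([[1.0, np.nan]]))


class TestTraceSurrogate:
    def test_zero_matrix(self):
        assert trace_surrogate(np.zeros((3, 2)), 1e-4) == pytest.approx(0.0)

    def test_diagonal_limit(self):
        assert trace_surrogate(np.diag([3.0, 4.0]), 1e-12) == pytest.approx(7.0, abs=1e-5)

    def test_converges_to_nuclear_norm(self, rng):
        W = rng.standard_normal((5, 3))
        assert trace_surrogate(W, 1e-10) == pytest.approx(nuclear_norm(W), abs=1e-4)

    def test_rejects_bad_delta(self):
        with pytest.raises(ValueError, match="delta"):
            trace_surrogate(np.eye(2), 0.0)

    def test_surrogate_consistency_random(self, rng):
        """For well-separated singular values the smoothed surrogate matches
        the SVD nuclear norm to 1e-4."""
        for _ in range(10):
            A = rng.standard_normal((6, 4))
            U, s, Vt = np.linalg.svd(A, full_matrices=False)
            s = 0.1 + np.abs(s)  # keep every singular value >= 0.1
            W = (U * s) @ Vt
            assert trace_surrogate(W, 1e-10) == pytest.approx(
                nuclear_norm(W), abs=1e-4
            )


class TestObjective:
    def test_zero_model_pure_residual(self, rng):
        X, Y = random_instance(rng, n=6, d=3, m=2)
        hp = MTJLHyperparams(lam=0.0, gam=0.0)
        val = objective(X, np.zeros((3, 2)), np.zeros(2), hp, scores=Y)
        assert val == pytest.approx(2 * float(Y @ Y))

    def test_exact_fit_is_zero(self, rng):
        X = rng.standard_normal((5, 2, 3))
        W = rng.standard_normal((3, 2))
        b = rng.standard_normal(2)
        # noiseless response reproduced trial-by-trial only when both trials agree
        Y = X[:, 0, :] @ W[:, 0] + b[0]
        X[:, 1, :] = X[:, 0, :]
        W[:, 1] = W[:, 0]
        b[1] = b[0]
        hp = MTJLHyperparams(lam=0.0, gam=0.0)
        assert objective(X, W, b, hp, scores=Y) == pytest.approx(0.0, abs=1e-18)

    def test_matches_term_by_term_oracle(self, rng):
        X, Y = random_instance(rng, n=5, d=2, m=2)
        W = rng.standard_normal((2, 2))
        b = rng.standard_normal(2)
        hp = MTJLHyperparams(lam=1.0, gam=1.0, delta=1e-8)
        expected = objective_direct(X, Y, W, b, 1.0, 1.0, 1e-8)
        assert objective(X, W, b, hp, scores=Y) == pytest.approx(expected, rel=1e-10)

    def test_shape_mismatch(self, rng):
        X, Y = random_instance(rng, n=5, d=2, m=2)
        with pytest.raises(ValueError, match="W must be"):
            objective(X, np.zeros((3, 2)), np.zeros(2), MTJLHyperparams(), scores=Y)


class TestUpdateDr:
    def test_identity_weights(self):
        Dr = update_Dr(np.eye(3), 1e-12)
        assert np.allclose(Dr, 0.5 * np.eye(3), atol=1e-6)

    def test_scalar_case(self):
        Dr = update_Dr(np.array([[2.0]]), 1e-12)
        assert Dr[0, 0] == pytest.approx(0.25, abs=1e-6)

    def test_inverse_square_root_identity(self, rng):
        W = rng.standard_normal((3, 4))
        delta = 1e-8
        M = update_Dr(W, delta)
        lhs = np.linalg.inv((2 * M) @ (2 * M))
        assert np.allclose(lhs, W @ W.T + delta * np.eye(3), atol=1e-6)

    def test_symmetric_positive_definite(self, rng):
        Dr = update_Dr(rng.standard_normal((4, 2)), 1e-8)
        assert np.allclose(Dr, Dr.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(Dr) > 0)


class TestClosedFormUpdates:
    def test_update_w_identity_design(self):
        y = np.array([1.0, -2.0, 3.0])
        hp = MTJLHyperparams(lam=1.0, gam=0.0)
        w = update_w(np.eye(3), y, 0.0, np.zeros((3, 3)), hp)
        assert np.allclose(w, y / 2)

    def test_update_w_ols_limit(self, rng):
        X = rng.standard_normal((10, 3))
        Y = rng.standard_normal(10)
        hp = MTJLHyperparams(lam=0.0, gam=0.0)
        w = update_w(X, Y, 0.0, np.zeros((3, 3)), hp)
        expected = np.linalg.lstsq(X, Y, rcond=None)[0]
        assert np.allclose(w, expected, atol=1e-10)

    def test_update_w_matches_generic_solver(self, rng):
        X = rng.standard_normal((20, 3))
        Y = rng.standard_normal(20)
        b_i = 0.7
        Dr = update_Dr(rng.standard_normal((3, 5)), 1e-8)
        hp = MTJLHyperparams(lam=1.0, gam=1.0)
        w = update_w(X, Y, b_i, Dr, hp)
        A = X.T @ X + np.eye(3) + Dr
        expected = np.linalg.solve(A, X.T @ (Y - b_i))
        assert np.allclose(w, expected, atol=1e-10)
        # stationarity residual
        assert np.linalg.norm(A @ w - X.T @ (Y - b_i)) <= 1e-8 * np.linalg.norm(Y)

    def test_update_w_singular_names_trial(self):
        X = np.ones((4, 2))  # rank 1
        hp = MTJLHyperparams(lam=0.0, gam=0.0)
        with pytest.raises(SingularTrialError, match="trial 3"):
            update_w(X, np.ones(4), 0.0, np.zeros((2, 2)), hp, trial_index=3)

    def test_update_b_zero_weights(self, rng):
        X = rng.standard_normal((8, 3))
        Y = rng.standard_normal(8)
        assert update_b(X, Y, np.zeros(3)) == pytest.approx(float(Y.mean()))

    def test_update_b_zero_residual(self, rng):
        X = rng.standard_normal((8, 3))
        w = rng.standard_normal(3)
        assert update_b(X, X @ w, w) == pytest.approx(0.0, abs=1e-12)

    def test_update_b_is_residual_mean(self, rng):
        X = rng.standard_normal((8, 3))
        Y = rng.standard_normal(8)
        w = rng.standard_normal(3)
        assert update_b(X, Y, w) == pytest.approx(float(np.mean(Y - X @ w)))


class TestSolver:
    def test_single_trial_gamma_zero_is_ridge(self, rng):
        """m=1, gam=0 must reproduce the centered ridge-with-intercept fit,
        checked against both a closed-form oracle and sklearn Ridge."""
        X = rng.standard_normal((25, 1, 4))
        Y = rng.standard_normal(25) + 3.0
        res = solve_mtjl(X, MTJLHyperparams(lam=1.0, gam=0.0), scores=Y)
        w_ref, b_ref = ridge_with_intercept(X[:, 0, :], Y, 1.0)
        assert np.allclose(res.W[:, 0], w_ref, atol=1e-8)
        assert res.b[0] == pytest.approx(b_ref, abs=1e-8)
        sk = sklearn.linear_model.Ridge(alpha=1.0).fit(X[:, 0, :], Y)
        assert np.allclose(res.W[:, 0], sk.coef_, atol=1e-6)

    def test_gamma_zero_decouples_into_per_trial_ridge(self, rng):
        X, Y = random_instance(rng, n=15, d=4, m=3)
        res = solve_mtjl(X, MTJLHyperparams(lam=0.5, gam=0.0), scores=Y)
        for i in range(3):
            w_ref, b_ref = ridge_with_intercept(X[:, i, :], Y, 0.5)
            assert np.allclose(res.W[:, i], w_ref, atol=1e-8)
            assert res.b[i] == pytest.approx(b_ref, abs=1e-8)

    @pytest.mark.parametrize("init", ["ridge_warm_start", "zeros"])
    def test_objective_trace_non_increasing(self, rng, init):
        X, Y = random_instance(rng, n=20, d=4, m=3)
        # the zeros start crosses a slow rank-reduction regime; allow it room
        hp = MTJLHyperparams(lam=1.0, gam=1.0, init=init, max_iter=1000)
        res = solve_mtjl(X, hp, scores=Y)
        tr = np.asarray(res.objective_trace)
        assert np.all(np.diff(tr) <= 1e-9 * np.maximum(1.0, np.abs(tr[:-1])))
        assert res.converged

    def test_stationarity_at_convergence(self, rng):
        """Re-applying the closed-form updates at the fixed point moves nothing."""
        X, Y = random_instance(rng, n=25, d=4, m=3)
        hp = MTJLHyperparams(lam=1.0, gam=1.0, tol=1e-12, max_iter=5000)
        res = solve_mtjl(X, hp, scores=Y)
        Dr = update_Dr(res.W, hp.delta)
        for i in range(3):
            w_new = update_w(X[:, i, :], Y, res.b[i], Dr, hp)
            assert np.max(np.abs(w_new - res.W[:, i])) < 1e-6
            assert abs(update_b(X[:, i, :], Y, w_new) - res.b[i]) < 1e-6

    def test_noiseless_low_rank_recovery(self, rng):
        """With shared trial design and tiny penalties, the planted weights
        are recovered almost exactly."""
        n, d, m, r = 200, 6, 8, 2
        base = rng.standard_normal((n, d))
        X = np.repeat(base[:, None, :], m, axis=1)
        W0 = rng.standard_normal((d, r)) @ rng.standard_normal((r, m))
        b0 = rng.standard_normal(m)
        Y = (np.einsum("nid,di->ni", X, W0) + b0).mean(axis=1)
        # identical trials force identical optimal columns: project truth
        res = solve_mtjl(X, MTJLHyperparams(lam=1e-6, gam=1e-6), scores=Y)
        pred = np.einsum("nid,di->ni", X, res.W).mean(axis=1) + res.b.mean()
        assert np.allclose(pred, Y, atol=1e-4)

    def test_nan_input_rejected(self, rng):
        X, Y = random_instance(rng, n=10, d=3, m=2)
        X[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            solve_mtjl(X, MTJLHyperparams(), scores=Y)


class TestEstimator:
    def test_constant_model_predicts_constant(self, rng):
        X, Y = random_instance(rng, n=10, d=3, m=2)
        model = MTJLRegressor(lam=1.0, gam=1.0).fit(X, Y)
        model.W_ = np.zeros_like(model.W_)
        model.b_ = np.full(2, 55.0)
        assert np.allclose(model.predict(X), 55.0)

    def test_predict_is_mean_of_per_trial_affine_maps(self, rng):
        X, Y = random_instance(rng, n=12, d=3, m=4)
        model = MTJLRegressor(lam=1.0, gam=1.0, normalize=False).fit(X, Y)
        expected = np.mean(
            [X[:, i, :] @ model.W_[:, i] + model.b_[i] for i in range(4)], axis=0
        )
        assert np.allclose(model.predict(X), expected, atol=1e-12)

    def test_exact_fit_limit_predicts_truth(self, rng):
        n, d, m = 50, 3, 4
        base = rng.standard_normal((n, d))
        X = np.repeat(base[:, None, :], m, axis=1)
        w = rng.standard_normal(d)
        Y = base @ w + 5.0
        model = MTJLRegressor(lam=1e-8, gam=0.0, normalize=False).fit(X, Y)
        assert np.allclose(model.predict(X), Y, atol=1e-6)

    def test_permutation_equivariance(self, rng):
        """Permuting feature columns permutes the rows of W and leaves
        predictions unchanged."""
        X, Y = random_instance(rng, n=20, d=5, m=3)
        perm = rng.permutation(5)
        m1 = MTJLRegressor(lam=1.0, gam=1.0).fit(X, Y)
        m2 = MTJLRegressor(lam=1.0, gam=1.0).fit(X[:, :, perm], Y)
        assert np.allclose(m2.W_, m1.W_[perm, :], atol=1e-8)
        assert np.allclose(m2.predict(X[:, :, perm]), m1.predict(X), atol=1e-10)

    def test_trial_count_mismatch_raises(self, rng):
        X, Y = random_instance(rng, n=10, d=3, m=2)
        model = MTJLRegressor().fit(X, Y)
        with pytest.raises(ValueError, match="expected"):
            model.predict(X[:, :1, :])

    def test_get_set_params_roundtrip(self):
        model = MTJLRegressor(lam=2.0, gam=0.5)
        params = model.get_params()
        clone = MTJLRegressor().set_params(**params)
        assert clone.get_params() == params

    def test_flat_2d_input_accepted_after_fit(self, rng):
        X, Y = random_instance(rng, n=10, d=3, m=2)
        model = MTJLRegressor(lam=1.0, gam=0.0).fit(X, Y)
        flat = X.reshape(10, -1)
        assert np.allclose(model.predict(flat), model.predict(X))
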