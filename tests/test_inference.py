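import numpy as np
import pytest

import tfcircuit as tc
from tfcircuit.inference import e_step, initialize_state, m_step, objective

from conftest import random_instance


def dense_posterior_oracle(expr, conn, c, mu, sigma2, alpha):
    """Independent Gaussian-posterior computation via the Woodbury route.

    Treats (weights, data) as jointly Gaussian per gene and conditions:
    cov(w|e) = aI - aX^T (X a X^T + s2 I)^-1 X a, which never forms the
    posterior precision the implementation factorizes.
    """
    E = np.asarray(expr.values, float)
    T = conn.entries
    G, F = T.shape
    mean = np.zeros((G, F))
    var = np.zeros((G, F))
    for g in range(G):
        idx = np.nonzero(T[g])[0]
        if idx.size == 0:
            continue
        X = c[idx, :].T  # samples x k
        S = alpha * X @ X.T + sigma2 * np.eye(X.shape[0])
        K = alpha * X.T @ np.linalg.inv(S)
        mean[g, idx] = K @ (E[g] - mu[g])
        var[g, idx] = np.diag(alpha * np.eye(idx.size) - K @ X * alpha)
    return mean, var


def result_moments(state):
    W_var = np.zeros_like(state.W_mean)
    for grp, Sigma in zip(state.groups, state.W_cov):
        W_var[grp.genes[:, None], grp.idx] = np.diagonal(Sigma, axis1=1, axis2=2)
    return state.W_mean, W_var


class TestInitializeState:
    def test_constant_matrix_gives_floor_variance(self):
        expr = tc.ExpressionMatrix(["g1", "g2"], ["s1", "s2"], np.full((2, 2), 5.0))
        conn = tc.ConnectivityMatrix(["g1", "g2"], ["f1"], np.array([[1], [1]]))
        state = initialize_state(expr, conn, tc.InferenceConfig(seed=0))
        np.testing.assert_array_equal(state.mu, [5.0, 5.0])
        assert state.sigma2 == tc.InferenceConfig().min_sigma2

    def test_same_seed_bit_identical(self):
        expr, conn = random_instance(3)
        cfg = tc.InferenceConfig(seed=9)
        s1 = initialize_state(expr, conn, cfg)
        s2 = initialize_state(expr, conn, cfg)
        np.testing.assert_array_equal(s1.c, s2.c)
        np.testing.assert_array_equal(s1.mu, s2.mu)

    def test_zero_samples_rejected(self):
        expr = tc.ExpressionMatrix(["g1"], [], np.zeros((1, 0)))
        conn = tc.ConnectivityMatrix(["g1"], ["f1"], np.array([[1]]))
        with pytest.raises(tc.ValidationError):
            initialize_state(expr, conn, tc.InferenceConfig())

    def test_misaligned_inputs_rejected(self):
        expr = tc.ExpressionMatrix(["g1", "g2"], ["s1"], np.zeros((2, 1)))
        conn = tc.ConnectivityMatrix(["g2", "g1"], ["f1"], np.array([[1], [1]]))
        with pytest.raises(tc.ValidationError):
            initialize_state(expr, conn, tc.InferenceConfig())


class TestEStep:
    def test_identity_design_weak_prior_recovers_residual(self):
        # one gene connected to two TFs, c = I over two samples:
        # with a nearly flat prior the posterior mean is e - mu itself
        expr = tc.ExpressionMatrix(["g1"], ["s1", "s2"], np.array([[3.0, 5.0]]))
        conn = tc.ConnectivityMatrix(["g1"], ["f1", "f2"], np.array([[1, 1]]))
        state = initialize_state(expr, conn, tc.InferenceConfig(prior_variance=1e6, seed=0))
        state.mu = np.zeros(1)
        state.sigma2 = 1.0
        state.c = np.eye(2)
        e_step(state)
        np.testing.assert_allclose(state.W_mean[0], [3.0, 5.0], atol=1e-2)

    def test_strong_prior_shrinks_to_zero(self):
        expr, conn = random_instance(1)
        state = initialize_state(expr, conn, tc.InferenceConfig(prior_variance=1e-12, seed=0))
        e_step(state)
        assert np.abs(state.W_mean).max() < 1e-6

    def test_unconnected_gene_row_stays_zero(self):
        expr = tc.ExpressionMatrix(["g1", "g2"], ["s1"], np.array([[1.0], [2.0]]))
        conn = tc.ConnectivityMatrix(["g1", "g2"], ["f1"], np.array([[0], [1]]))
        state = initialize_state(expr, conn, tc.InferenceConfig(seed=0))
        e_step(state)
        assert np.all(state.W_mean[0] == 0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_independent_dense_oracle(self, seed):
        expr, conn = random_instance(seed)
        cfg = tc.InferenceConfig(prior_variance=0.7, seed=seed)
        state = initialize_state(expr, conn, cfg)
        e_step(state)
        mean, var = result_moments(state)
        o_mean, o_var = dense_posterior_oracle(
            expr, conn, state.c, state.mu, state.sigma2, cfg.prior_variance
        )
        np.testing.assert_allclose(mean, o_mean, atol=1e-10)
        np.testing.assert_allclose(var, o_var, atol=1e-10)


class TestMStep:
    def test_exact_truth_zero_variance_gives_least_squares_c(self):
        rng = np.random.default_rng(0)
        W = rng.standard_normal((6, 2))
        c_true = rng.standard_normal((2, 4))
        expr = tc.ExpressionMatrix(
            [f"g{i}" for i in range(6)], [f"s{j}" for j in range(4)], W @ c_true
        )
        conn = tc.ConnectivityMatrix(
            list(expr.gene_ids), ["f1", "f2"], np.ones((6, 2), dtype=np.int8)
        )
        state = initialize_state(expr, conn, tc.InferenceConfig(seed=1))
        state.mu = np.zeros(6)
        state.W_mean = W.copy()
        state.W_cov = [np.zeros((6, 2, 2))]
        state.W_logdet = np.zeros(6)
        m_step(state)
        expected, *_ = np.linalg.lstsq(W, expr.values, rcond=None)
        np.testing.assert_allclose(state.c, expected, atol=1e-10)
        np.testing.assert_allclose(state.c, c_true, atol=1e-10)

    def test_duplicate_samples_get_identical_c_columns(self):
        expr, conn = random_instance(4, n_samples=2)
        values = np.column_stack([expr.values[:, 0], expr.values[:, 0]])
        expr = tc.ExpressionMatrix(expr.gene_ids, ["s1", "s2"], values)
        state = initialize_state(expr, conn, tc.InferenceConfig(seed=2))
        e_step(state)
        m_step(state)
        np.testing.assert_allclose(state.c[:, 0], state.c[:, 1], atol=1e-12)


class TestObjective:
    def test_deterministic_for_fixed_state(self):
        expr, conn = random_instance(5)
        state = initialize_state(expr, conn, tc.InferenceConfig(seed=3))
        e_step(state)
        m_step(state)
        e_step(state)
        assert objective(state) == objective(state)

    def test_finite_at_variance_floor(self):
        expr = tc.ExpressionMatrix(["g1", "g2"], ["s1", "s2"], np.full((2, 2), 2.0))
        conn = tc.ConnectivityMatrix(["g1", "g2"], ["f1"], np.array([[1], [1]]))
        state = initialize_state(expr, conn, tc.InferenceConfig(seed=0))
        e_step(state)
        m_step(state)
        e_step(state)
        assert np.isfinite(objective(state))

    @pytest.mark.parametrize("seed", range(10))
    def test_em_bound_monotone(self, seed):
        expr, conn = random_instance(seed, n_genes=8, n_tfs=3, n_samples=4)
        state = initialize_state(expr, conn, tc.InferenceConfig(seed=seed))
        prev = None
        for _ in range(25):
            e_step(state)
            m_step(state)
            obj = objective(state)
            if prev is not None:
                assert obj >= prev - 1e-8 * max(abs(prev), 1.0)
            prev = obj


class TestInfer:
    def test_noiseless_rank1_matches_svd_oracle(self):
        expr = tc.ExpressionMatrix(
            ["g1", "g2"], ["s1", "s2"], np.array([[1.0, 2.0], [2.0, 4.0]])
        )
        conn = tc.ConnectivityMatrix(["g1", "g2"], ["f1"], np.array([[1], [1]]))
        result = tc.infer(
            expr, conn, tc.InferenceConfig(prior_variance=1e4, seed=0, tolerance=1e-10)
        )
        # oracle: the data matrix is exactly rank one, so the best rank-1
        # approximation (leading SVD term) is the matrix itself
        u, s, vt = np.linalg.svd(expr.values)
        oracle = s[0] * np.outer(u[:, 0], vt[0])
        rmse = np.sqrt(np.mean((result.reconstruction() - oracle) ** 2))
        assert rmse < 1e-3

    def test_constant_matrix_fixed_point(self):
        expr = tc.ExpressionMatrix(["g1", "g2"], ["s1", "s2"], np.full((2, 2), 7.0))
        conn = tc.ConnectivityMatrix(["g1", "g2"], ["f1"], np.array([[1], [1]]))
        result = tc.infer(expr, conn, tc.InferenceConfig(seed=4))
        assert np.abs(result.W_mean).max() < 1e-8
        np.testing.assert_allclose(result.mu, [7.0, 7.0], atol=1e-8)
        assert result.sigma2 == result.config.min_sigma2

    def test_same_seed_bit_identical_results(self):
        expr, conn = random_instance(11, n_genes=10)
        cfg = tc.InferenceConfig(seed=8, max_iterations=50)
        r1 = tc.infer(expr, conn, cfg)
        r2 = tc.infer(expr, conn, cfg)
        np.testing.assert_array_equal(r1.W_mean, r2.W_mean)
        np.testing.assert_array_equal(r1.c, r2.c)
        np.testing.assert_array_equal(r1.objective_trace, r2.objective_trace)

    def test_support_constraint_exact(self, fitted_pair):
        ds, ref, alt, _ = fitted_pair
        off = ds.conn.entries == 0
        assert np.all(ref.W_mean[off] == 0) and np.all(ref.W_var[off] == 0)
        assert np.all(alt.W_mean[off] == 0)

    def test_sign_convention_mean_concentration_nonnegative(self, fitted_pair):
        _, ref, alt, _ = fitted_pair
        assert np.all(ref.c_summary >= 0)
        assert np.all(alt.c_summary >= 0)

    def test_objective_trace_monotone(self, fitted_pair):
        _, ref, _, _ = fitted_pair
        tr = ref.objective_trace
        assert np.all(np.diff(tr) >= -1e-8 * np.maximum(np.abs(tr[:-1]), 1.0))

    def test_cross_seed_runs_agree_on_product(self):
        expr, conn = random_instance(21, n_genes=12, n_tfs=2, n_samples=5, sigma=0.05)
        cfg1 = tc.InferenceConfig(seed=1, tolerance=1e-13, max_iterations=20000)
        cfg2 = tc.InferenceConfig(seed=77, tolerance=1e-13, max_iterations=20000)
        r1 = tc.infer(expr, conn, cfg1)
        r2 = tc.infer(expr, conn, cfg2)
        rmse = np.sqrt(np.mean((r1.W_mean @ r1.c - r2.W_mean @ r2.c) ** 2))
        assert rmse < 1e-6

    def test_non_convergence_is_flagged_not_fatal(self):
        expr, conn = random_instance(2)
        result = tc.infer(expr, conn, tc.InferenceConfig(seed=0, max_iterations=2))
        assert result.converged is False
        assert len(result.objective_trace) == 2

    def test_parameter_recovery_on_benchmark(self, fitted_pair):
        ds, ref, alt, _ = fitted_pair
        for tag, fit in (("ref", ref), ("alt", alt)):
            r = np.corrcoef(ds.true_signal(tag).ravel(), (fit.W_mean @ fit.c).ravel())[0, 1]
            assert r > 0.95
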