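"""Flow-model MAP EM: E-step, M-step updates, logit Newton solver, full fit."""

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.metrics import adjusted_rand_score

from cytomix import flow
from cytomix.types import (
    DesignMatrix,
    Hyperparams,
    MarkerMatrix,
    MixtureWeights,
    ModelParams,
)


def _uniform_phi(n, L):
    return MixtureWeights(np.full((n, L), 1.0 / L))


class TestEStep:
    def test_single_component(self, rng):
        Y = MarkerMatrix(rng.normal(size=(8, 2)))
        params = ModelParams(np.zeros((2, 1)), np.eye(2)[None], np.zeros((1, 1)))
        w = flow.e_step(Y, params, _uniform_phi(8, 1)).w
        np.testing.assert_allclose(w, 1.0)

    def test_identical_components_return_phi(self, rng):
        Y = MarkerMatrix(rng.normal(size=(10, 2)))
        mu = np.zeros((2, 3))
        sigma = np.stack([np.eye(2)] * 3)
        params = ModelParams(mu, sigma, np.zeros((1, 3)))
        phi = MixtureWeights(rng.dirichlet(np.ones(3), 10))
        w = flow.e_step(Y, params, phi).w
        np.testing.assert_allclose(w, phi.phi, atol=1e-12)

    @pytest.mark.parametrize("y", [0.0, 1.0, -2.5])
    def test_univariate_against_scalar_density_oracle(self, y):
        params = ModelParams(
            np.array([[-1.0, 1.0]]), np.stack([np.eye(1)] * 2), np.zeros((1, 2))
        )
        Y = MarkerMatrix(np.array([[y]]))
        w = flow.e_step(Y, params, _uniform_phi(1, 2)).w[0]
        d = np.array([norm.pdf(y, -1, 1), norm.pdf(y, 1, 1)])
        np.testing.assert_allclose(w, d / d.sum(), rtol=1e-10)

    def test_rows_normalised(self, rng):
        Y = MarkerMatrix(rng.normal(size=(30, 3)))
        mu = rng.normal(size=(3, 4))
        sigma = np.stack([np.eye(3)] * 4)
        params = ModelParams(mu, sigma, np.zeros((1, 4)))
        w = flow.e_step(Y, params, _uniform_phi(30, 4)).w
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)


class TestMeanUpdate:
    def test_hand_arithmetic(self):
        Y = MarkerMatrix(np.array([[1.0], [3.0]]))
        w = np.ones((2, 1))
        np.testing.assert_allclose(flow.update_means(Y, w, tau=1.0), [[4.0 / 3.0]])

    def test_small_tau_gives_sample_mean(self, rng):
        y = rng.normal(size=(50, 2))
        w = np.ones((50, 1))
        mu = flow.update_means(MarkerMatrix(y), w, tau=1e-12)
        np.testing.assert_allclose(mu[:, 0], y.mean(axis=0), atol=1e-10)

    def test_large_tau_shrinks_to_zero(self, rng):
        y = rng.normal(5.0, 1.0, size=(50, 2))
        mu = flow.update_means(MarkerMatrix(y), np.ones((50, 1)), tau=1e12)
        np.testing.assert_allclose(mu, 0.0, atol=1e-9)


class TestCovarianceUpdate:
    def test_empty_cluster_prior_only(self):
        # no responsibility and mu=0: Sigma = Lambda / (nu - K)
        Y = MarkerMatrix(np.array([[1.0, 2.0], [0.5, -1.0]]))
        hyper = Hyperparams(tau=0.01, nu=4.0, lambda_mat=np.eye(2))
        w = np.zeros((2, 1))
        sigma = flow.update_covariances(Y, w, np.zeros((2, 1)), hyper)
        np.testing.assert_allclose(sigma[0], np.eye(2) / 2.0)

    def test_hand_scalar_example(self):
        # y=(-1,1), w=1, mu=0, tau->0, Lambda=1, nu=3: (1+1+1)/(2+3-1) = 0.75
        Y = MarkerMatrix(np.array([[-1.0], [1.0]]))
        hyper = Hyperparams(tau=1e-300, nu=3.0, lambda_mat=np.eye(1))
        sigma = flow.update_covariances(Y, np.ones((2, 1)), np.zeros((1, 1)), hyper)
        np.testing.assert_allclose(sigma[0, 0, 0], 0.75)

    def test_output_positive_definite(self, rng):
        Y = MarkerMatrix(rng.normal(size=(40, 3)))
        w = rng.dirichlet(np.ones(2), 40)
        mu = flow.update_means(Y, w, 0.01)
        sigma = flow.update_covariances(Y, w, mu, Hyperparams.default(3))
        for s in sigma:
            np.linalg.cholesky(s)  # must not raise


class TestBetaObjective:
    def test_q_at_zero_closed_form(self, rng):
        N, L = 9, 4
        X = DesignMatrix(np.column_stack([np.ones(N), rng.integers(0, 2, N)]))
        w = rng.dirichlet(np.ones(L), N)
        assert flow.q_beta(np.zeros((2, L)), w, X) == pytest.approx(-N * np.log(L))

    def test_single_cell_two_clusters(self):
        X = DesignMatrix(np.ones((1, 1)))
        w = np.array([[1.0, 0.0]])
        assert flow.q_beta(np.zeros((1, 2)), w, X) == pytest.approx(-np.log(2))

    def test_q_matches_double_loop_oracle(self, rng):
        N, D, L = 6, 2, 3
        X = DesignMatrix(np.column_stack([np.ones(N), rng.normal(size=N)]))
        w = rng.dirichlet(np.ones(L), N)
        beta = np.zeros((D, L))
        beta[:, 1:] = rng.normal(size=(D, L - 1))
        expected = 0.0
        for n in range(N):
            logits = [sum(X.values[n, d] * beta[d, l] for d in range(D)) for l in range(L)]
            lse = np.log(sum(np.exp(v) for v in logits))
            for l in range(L):
                expected += w[n, l] * (logits[l] - lse)
        assert flow.q_beta(beta, w, X) == pytest.approx(expected)


def _fd_grad(beta, w, X, eps=1e-5):
    D, L = beta.shape
    g = np.zeros(D * L)
    for i in range(D, D * L):  # free entries only
        d, l = i % D, i // D
        bp, bm = beta.copy(), beta.copy()
        bp[d, l] += eps
        bm[d, l] -= eps
        g[i] = (flow.q_beta(bp, w, X) - flow.q_beta(bm, w, X)) / (2 * eps)
    return g


class TestGradHess:
    def test_gradient_zero_at_stationary_point(self, rng):
        N, D, L = 12, 2, 3
        X = DesignMatrix(np.column_stack([np.ones(N), rng.integers(0, 2, N)]))
        beta = np.zeros((D, L))
        beta[:, 1:] = rng.normal(size=(D, L - 1))
        from cytomix.types import compute_phi

        w = compute_phi(X, beta).phi
        assert np.abs(flow.grad_q(beta, w, X)).max() < 1e-10

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        N, D, L = 15, 2, 4
        X = DesignMatrix(np.column_stack([np.ones(N), rng.normal(size=N)]))
        w = rng.dirichlet(np.ones(L), N)
        beta = np.zeros((D, L))
        beta[:, 1:] = rng.normal(0, 0.7, (D, L - 1))
        g = flow.grad_q(beta, w, X)
        fd = _fd_grad(beta, w, X)
        assert np.abs(g - fd).max() / max(np.abs(fd).max(), 1.0) < 1e-5

    def test_intercept_gradient_at_zero_beta(self, rng):
        N, L = 20, 3
        X = DesignMatrix(np.ones((N, 1)))
        w = rng.dirichlet(np.ones(L), N)
        g = flow.grad_q(np.zeros((1, L)), w, X)
        np.testing.assert_allclose(g[1:], (w - 1.0 / L).sum(axis=0)[1:], atol=1e-12)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_curvature_matches_negated_grad_derivative(self, seed):
        rng = np.random.default_rng(seed)
        N, D, L = 10, 2, 3
        X = DesignMatrix(np.column_stack([np.ones(N), rng.normal(size=N)]))
        w = rng.dirichlet(np.ones(L), N)
        beta = np.zeros((D, L))
        beta[:, 1:] = rng.normal(0, 0.5, (D, L - 1))
        C = flow.hess_q(beta, X)
        eps = 1e-5
        free = np.arange(D, D * L)
        fdH = np.zeros((D * L, D * L))
        for i in free:
            d, l = i % D, i // D
            bp, bm = beta.copy(), beta.copy()
            bp[d, l] += eps
            bm[d, l] -= eps
            fdH[:, i] = (flow.grad_q(bp, w, X) - flow.grad_q(bm, w, X)) / (2 * eps)
        sub = np.ix_(free, free)
        assert np.abs(C[sub] + fdH[sub]).max() / np.abs(C).max() < 1e-4

    def test_binary_logistic_reduction(self, rng):
        # L=2, D=1: curvature collapses to sum_n phi (1-phi) x^2
        N = 8
        x = rng.normal(size=N)
        X = DesignMatrix(np.ones((N, 1)))
        X.values[:, 0] = 1.0  # intercept-only design, scalar x folded below
        beta = np.array([[0.0, 0.7]])
        from cytomix.types import compute_phi

        phi = compute_phi(X, beta).phi
        C = flow.hess_q(beta, X)
        expected = np.sum(phi[:, 1] * (1 - phi[:, 1]))
        assert C[1, 1] == pytest.approx(expected)

    def test_per_cell_block_rows_sum_to_zero(self, rng):
        # (diag(phi) - phi phi^T) 1 = 0: summing curvature blocks over the
        # cluster index annihilates any direction constant across clusters
        N, D, L = 5, 2, 4
        X = DesignMatrix(np.column_stack([np.ones(N), rng.normal(size=N)]))
        beta = np.zeros((D, L))
        beta[:, 1:] = rng.normal(size=(D, L - 1))
        C = flow.hess_q(beta, X)
        block_rowsum = sum(
            C[:, m * D : (m + 1) * D] for m in range(L)
        )
        np.testing.assert_allclose(block_rowsum, 0.0, atol=1e-10)


class TestNewton:
    def test_no_move_at_stationary_point(self, rng):
        N, D, L = 10, 2, 3
        X = DesignMatrix(np.column_stack([np.ones(N), rng.integers(0, 2, N)]))
        beta = np.zeros((D, L))
        beta[:, 1:] = rng.normal(size=(D, L - 1))
        from cytomix.types import compute_phi

        w = compute_phi(X, beta).phi
        out = flow.newton_step(beta, w, X)
        np.testing.assert_allclose(out, beta, atol=1e-8)

    def test_intercept_only_closed_form(self, rng):
        N, L = 40, 3
        X = DesignMatrix(np.ones((N, 1)))
        w = rng.dirichlet(np.ones(L), N)
        beta = flow.optimize_beta(np.zeros((1, L)), w, X)
        wbar = w.mean(axis=0)
        np.testing.assert_allclose(beta[0], np.log(wbar / wbar[0]), atol=1e-7)

    def test_binary_covariate_groupwise_closed_form(self, rng):
        # with one binary covariate the logit MLE matches the per-group
        # multinomial closed form log(wbar_g,l / wbar_g,1)
        N, L = 60, 2
        x = rng.integers(0, 2, N)
        X = DesignMatrix(np.column_stack([np.ones(N), x]).astype(float))
        w = rng.dirichlet(np.ones(L), N)
        beta = flow.optimize_beta(np.zeros((2, L)), w, X)
        for g in (0, 1):
            wbar = w[x == g].mean(axis=0)
            logit = beta[0, 1] + g * beta[1, 1]
            assert logit == pytest.approx(np.log(wbar[1] / wbar[0]), abs=1e-6)

    def test_ascent_never_decreases_q(self, rng):
        N, D, L = 25, 2, 4
        X = DesignMatrix(np.column_stack([np.ones(N), rng.normal(size=N)]))
        w = rng.dirichlet(np.ones(L), N)
        beta = np.zeros((D, L))
        for _ in range(5):
            q0 = flow.q_beta(beta, w, X)
            beta = flow.newton_step(beta, w, X)
            assert flow.q_beta(beta, w, X) >= q0 - 1e-12
            assert np.allclose(beta[:, 0], 0.0)


class TestLogLikelihood:
    def test_standard_normal_at_zero(self):
        Y = MarkerMatrix(np.zeros((1, 1)))
        X = DesignMatrix(np.ones((1, 1)))
        params = ModelParams(np.zeros((1, 1)), np.eye(1)[None], np.zeros((1, 1)))
        assert flow.log_likelihood(Y, X, params) == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_invariant_under_joint_label_permutation(self, rng):
        Y = MarkerMatrix(rng.normal(size=(12, 2)))
        X = DesignMatrix(np.column_stack([np.ones(12), rng.integers(0, 2, 12)]))
        mu = rng.normal(size=(2, 3))
        sigma = np.stack([np.eye(2)] * 3)
        beta = np.zeros((2, 3))
        beta[:, 1:] = rng.normal(size=(2, 2))
        params = ModelParams(mu, sigma, beta)
        perm = np.array([2, 0, 1])
        bp = beta[:, perm]
        bp = bp - bp[:, :1]
        permuted = ModelParams(mu[:, perm], sigma[perm], bp)
        assert flow.log_likelihood(Y, X, params) == pytest.approx(
            flow.log_likelihood(Y, X, permuted)
        )

    def test_matches_brute_force_summation(self, rng):
        from scipy.stats import multivariate_normal

        from cytomix.types import compute_phi

        Y = MarkerMatrix(rng.normal(size=(5, 2)))
        X = DesignMatrix(np.column_stack([np.ones(5), rng.integers(0, 2, 5)]))
        mu = rng.normal(size=(2, 2))
        sigma = np.stack([np.eye(2), 2 * np.eye(2)])
        beta = np.zeros((2, 2))
        beta[:, 1] = [0.4, -0.3]
        params = ModelParams(mu, sigma, beta)
        phi = compute_phi(X, beta).phi
        expected = sum(
            np.log(
                sum(
                    phi[n, l] * multivariate_normal.pdf(Y.values[n], mu[:, l], sigma[l])
                    for l in range(2)
                )
            )
            for n in range(5)
        )
        assert flow.log_likelihood(Y, X, params) == pytest.approx(expected)


class TestFitFlow:
    def test_single_gaussian_single_cluster(self, rng):
        y = rng.normal(1.0, 1.0, size=(300, 2))
        Y = MarkerMatrix(y)
        X = DesignMatrix(np.ones((300, 1)))
        fit = flow.fit_flow(Y, X, 1, seed=0)
        # tau=0.01 shrinkage is ~N/(N+tau) of the sample mean
        np.testing.assert_allclose(fit.params.mu[:, 0], y.mean(axis=0), atol=0.01)
        assert fit.converged

    def test_separated_clusters_perfect_ari(self, rng):
        n = 200
        labels = rng.integers(0, 2, n)
        y = np.where(labels[:, None] == 0, -5.0, 5.0) + rng.standard_normal((n, 2))
        Y = MarkerMatrix(y)
        X = DesignMatrix(np.ones((n, 1)))
        fit = flow.fit_flow(Y, X, 2, seed=0)
        assert adjusted_rand_score(labels, fit.latent.hard_labels) == 1.0

    def test_objective_trace_nondecreasing(self, small_mixture):
        Y, X, _ = small_mixture
        fit = flow.fit_flow(Y, X, 2, seed=1)
        tr = np.array(fit.objective_trace)
        assert np.all(np.diff(tr) >= -1e-8 * (np.abs(tr[:-1]) + 1.0))

    def test_covariate_effect_recovered(self, rng):
        # cluster 2 enriched in category x=1
        n = 600
        x = (np.arange(n) >= n // 2).astype(float)
        p = np.where(x == 0, 0.2, 0.7)
        labels = (rng.random(n) < p).astype(int)
        y = np.where(labels[:, None] == 0, -4.0, 4.0) + rng.standard_normal((n, 2))
        Y = MarkerMatrix(y)
        X = DesignMatrix(np.column_stack([np.ones(n), x]))
        fit = flow.fit_flow(Y, X, 2, seed=0)
        from cytomix.simulate import align_labels, category_proportions

        props = category_proportions(align_labels(fit), X)
        # category 1 is ~(0.8, 0.2); sorting ascending puts the enriched
        # cluster first, so category 2 reads (0.7, 0.3) in the same order
        assert props[0, 0] == pytest.approx(0.2, abs=0.06)
        assert props[1, 0] == pytest.approx(0.7, abs=0.06)
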