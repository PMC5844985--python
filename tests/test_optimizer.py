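"""Conjugate-gradient minimization: line search, descent, oracle equivalence."""

import numpy as np
import pytest

from mmpen import (GenotypeMatrix, NoiseModel, Phenotype, PriorSpec,
                   fit_mixture_model, ncg_minimize, newton_line_search)
from mmpen.data import make_windows
from mmpen.optimize import ObjectiveState, OptimizerConfig, default_anneal_schedule


class QuadraticState:
    """Minimal objective protocol for 1/2 b'Ab - c'b (optimizer-only oracle)."""

    def __init__(self, A, c):
        self.A, self.c = A, c
        self.n = len(c)

    def value(self, b):
        return float(0.5 * b @ self.A @ b - self.c @ b)

    def value_grad(self, b):
        return self.value(b), self.A @ b - self.c

    def grad_curv(self, b):
        return self.A @ b - self.c, np.zeros(self.n)

    def hvp(self, v, curvature):
        return self.A @ v

    def responsibilities(self, b):
        return np.zeros(self.n)


def spd_matrix(rng, n):
    M = rng.standard_normal((n, n))
    return M @ M.T + n * np.eye(n)


class TestNewtonLineSearch:
    def test_exact_on_quadratic_in_one_step(self, rng):
        A = spd_matrix(rng, 6)
        c = rng.standard_normal(6)
        state = QuadraticState(A, c)
        beta = rng.standard_normal(6)
        _, g = state.value_grad(beta)
        d = -g
        # argmin_t of the quadratic along d has the closed form below
        t_star = float(g @ g) / float(d @ A @ d)
        t = newton_line_search(beta, d, state, max_newton=1)
        assert t == pytest.approx(t_star, rel=1e-12)

    def test_matches_dense_grid_on_ridge_objective(self, rng):
        X = rng.standard_normal((40, 8))
        y = rng.standard_normal(40)
        prior = PriorSpec.constant(8, pi1=1.0, slab_sd=1.0)
        state = ObjectiveState(X, y, 1.0, prior)
        beta = rng.standard_normal(8) * 0.1
        _, g = state.value_grad(beta)
        d = -g
        t = newton_line_search(beta, d, state)
        grid = np.linspace(0, 2 * t + 0.1, 100_000)
        vals = [state.value(beta + ti * d) for ti in grid]
        t_grid = grid[int(np.argmin(vals))]
        assert t == pytest.approx(t_grid, abs=2 * (grid[1] - grid[0]))

    def test_backtracking_on_negative_curvature(self, rng):
        """Spike/slab region with phi'' < 0 still yields strict decrease."""
        X = np.array([[1.0], [1.0]])
        y = np.array([2.0, 2.0])
        # narrow spike makes the mixture cost concave between the modes
        prior = PriorSpec([0.5], [2.0], "normal_spike", 0.01)
        state = ObjectiveState(X, y, 1.0, prior)
        beta = np.array([0.03])
        f0, g = state.value_grad(beta)
        curv = state.grad_curv(beta)[1]
        d = -g
        phi2 = float(d @ state.hvp(d, curv))
        assert phi2 < 0  # genuinely in the non-convex region of the penalty
        t = newton_line_search(beta, d, state, f0=f0, g0=g)
        assert t > 0
        assert state.value(beta + t * d) < f0

    def test_ascent_direction_returns_zero(self, rng):
        state = QuadraticState(np.eye(3), np.zeros(3))
        beta = np.ones(3)
        _, g = state.value_grad(beta)
        assert newton_line_search(beta, +g, state) == 0.0


class TestNcgMinimize:
    @pytest.mark.parametrize("update", ["fletcher_reeves", "polak_ribiere_plus",
                                        "dai_yuan", "hager_zhang"])
    def test_quadratic_converges_to_solution(self, rng, update):
        A = spd_matrix(rng, 10)
        c = rng.standard_normal(10)
        res = ncg_minimize(np.zeros(10), QuadraticState(A, c),
                           OptimizerConfig(beta_update=update, grad_tol=1e-10,
                                           f_rel_tol=1e-16))
        np.testing.assert_allclose(res.beta_hat, np.linalg.solve(A, c),
                                   atol=1e-8)
        assert res.converged

    def test_all_slab_matches_ridge_closed_form(self, rng):
        X = rng.standard_normal((100, 30))
        y = rng.standard_normal(100)
        sigma2, slab_sd = 1.4, 0.8
        prior = PriorSpec.constant(30, pi1=1.0, slab_sd=slab_sd)
        res = ncg_minimize(np.zeros(30), ObjectiveState(X, y, sigma2, prior),
                           OptimizerConfig(grad_tol=1e-9, f_rel_tol=1e-16))
        ridge = np.linalg.solve(X.T @ X / sigma2 + np.eye(30) / slab_sd**2,
                                X.T @ y / sigma2)
        np.testing.assert_allclose(res.beta_hat, ridge, atol=1e-6)

    def test_two_snp_spike_slab_matches_grid_search(self, rng):
        """Exhaustive 2-D grid is the oracle; instance checked unimodal by it."""
        X = rng.standard_normal((30, 2))
        beta_true = np.array([0.8, 0.0])
        y = X @ beta_true + 0.3 * rng.standard_normal(30)
        prior = PriorSpec.constant(2, pi1=0.3, slab_sd=1.0,
                                   null_family="normal_spike", null_scale=0.05)
        state = ObjectiveState(X, y, 0.3**2, prior)
        res = ncg_minimize(np.zeros(2), state, OptimizerConfig(grad_tol=1e-10))

        step = 1e-3
        b1 = np.arange(-1.5, 1.5, step)
        b2 = np.arange(-1.5, 1.5, step)
        B1, B2 = np.meshgrid(b1, b2, indexing="ij")
        # vectorized objective over the grid
        XtX = X.T @ X
        Xty = X.T @ y
        quad = (0.5 * (B1**2 * XtX[0, 0] + 2 * B1 * B2 * XtX[0, 1]
                       + B2**2 * XtX[1, 1])
                - B1 * Xty[0] - B2 * Xty[1]) / 0.09

        def cost1(b, pi1=0.3, s1=1.0, s0=0.05):
            m = (pi1 * np.exp(-0.5 * (b / s1) ** 2) / (np.sqrt(2 * np.pi) * s1)
                 + (1 - pi1) * np.exp(-0.5 * (b / s0) ** 2)
                 / (np.sqrt(2 * np.pi) * s0))
            return -np.log(m)

        F = quad + cost1(B1) + cost1(B2)
        i, j = np.unravel_index(np.argmin(F), F.shape)
        np.testing.assert_allclose(res.beta_hat, [b1[i], b2[j]], atol=2 * step)

    def test_objective_trace_non_increasing(self, small_sim):
        g, y, _, _ = small_sim
        for pi1, family in [(0.01, "laplace"), (0.2, "normal_spike"),
                            (1.0, "normal_spike")]:
            prior = PriorSpec.constant(g.n_snps, pi1=pi1, null_family=family)
            state = ObjectiveState(g.dosages, y.values,
                                   0.5 * np.var(y.values, ddof=1), prior)
            res = ncg_minimize(np.zeros(g.n_snps), state)
            assert np.all(np.diff(res.objective_trace) <= 1e-12)

    def test_permutation_equivariance(self, rng):
        X = rng.standard_normal((50, 12))
        y = rng.standard_normal(50)
        pi1 = rng.uniform(0.05, 0.9, 12)
        prior = PriorSpec(pi1, np.full(12, 1.0), "normal_spike", 0.05)
        res = ncg_minimize(np.zeros(12), ObjectiveState(X, y, 1.0, prior))
        perm = rng.permutation(12)
        prior_p = PriorSpec(pi1[perm], np.full(12, 1.0), "normal_spike", 0.05)
        res_p = ncg_minimize(np.zeros(12),
                             ObjectiveState(X[:, perm], y, 1.0, prior_p))
        np.testing.assert_allclose(res_p.beta_hat, res.beta_hat[perm],
                                   atol=1e-8)

    def test_bitwise_deterministic(self, rng):
        X = rng.standard_normal((40, 10))
        y = rng.standard_normal(40)
        prior = PriorSpec.constant(10, pi1=0.1, null_family="laplace",
                                   null_scale=0.05)
        r1 = ncg_minimize(np.zeros(10), ObjectiveState(X, y, 1.0, prior))
        r2 = ncg_minimize(np.zeros(10), ObjectiveState(X, y, 1.0, prior))
        assert np.array_equal(r1.objective_trace, r2.objective_trace)
        assert np.array_equal(r1.beta_hat, r2.beta_hat)

    def test_annealing_rarely_hurts(self):
        """Final F with the null-scale homotopy <= cold fit in >= 80% of
        seeded spike/slab instances (statistical property, 20 instances)."""
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((80, 20))
            beta_true = np.zeros(20)
            beta_true[r.choice(20, 3, replace=False)] = r.standard_normal(3)
            y = X @ beta_true + 0.5 * r.standard_normal(80)
            prior = PriorSpec.constant(20, pi1=0.05, slab_sd=1.0,
                                       null_family="normal_spike",
                                       null_scale=0.02)
            sigma2 = 0.25
            cold = ncg_minimize(np.zeros(20),
                                ObjectiveState(X, y, sigma2, prior))
            beta = np.zeros(20)
            for pi_m, sc_m in default_anneal_schedule():
                from dataclasses import replace
                stage = replace(prior, null_scale=prior.null_scale * sc_m)
                res = ncg_minimize(beta, ObjectiveState(X, y, sigma2, stage))
                beta = res.beta_hat
            state = ObjectiveState(X, y, sigma2, prior)
            if state.value(beta) <= state.value(cold.beta_hat) + 1e-8:
                wins += 1
        assert wins >= 16


class TestFitMixtureModel:
    def test_requires_standardized_genotypes(self, rng):
        g = GenotypeMatrix(rng.integers(0, 3, (20, 5)).astype(float),
                           [f"v{j}" for j in range(5)], ["1"] * 5,
                           np.full(5, 0.3))
        y = Phenotype(rng.standard_normal(20),
                      np.array([f"s{i}" for i in range(20)]))
        prior = PriorSpec.constant(5)
        with pytest.raises(ValueError, match="standardized"):
            fit_mixture_model(g, y, prior, NoiseModel([1.0]))

    def test_windows_fit_independently(self, small_sim):
        """Per-window results equal fitting each window's block alone."""
        g, y, _, _ = small_sim
        gw, noise = make_windows(g, "per_chromosome", total_h2=0.5)
        prior = PriorSpec.constant(g.n_snps, pi1=0.05)
        results = fit_mixture_model(gw, y, prior, noise)
        assert len(results) == len(np.unique(gw.window_id))
        w0 = np.flatnonzero(gw.window_id == 0)
        sub = gw.take_variants(w0)
        sub_res = fit_mixture_model(sub, y, prior.take(w0),
                                    noise.bind_phenotype(y.values))
        np.testing.assert_allclose(results[0].beta_hat,
                                   sub_res[0].beta_hat, atol=1e-10)

    def test_infinitesimal_reproduces_ridge(self, small_sim):
        g, y, _, _ = small_sim
        sigma2 = 0.5 * np.var(y.values, ddof=1)
        prior = PriorSpec.constant(g.n_snps, pi1=1.0, slab_sd=1.0)
        res = fit_mixture_model(g, y, prior, NoiseModel([sigma2]),
                                OptimizerConfig(grad_tol=1e-8))
        X = g.dosages
        ridge = np.linalg.solve(X.T @ X / sigma2 + np.eye(g.n_snps),
                                X.T @ y.values / sigma2)
        np.testing.assert_allclose(res[0].beta_hat, ridge, atol=1e-5)

    def test_mm_cp_configuration_converges(self, small_sim):
        """Constant pi1=0.01 with Laplacian null runs to convergence."""
        g, y, _, _ = small_sim
        prior = PriorSpec.constant(g.n_snps, pi1=0.01, null_family="laplace",
                                   null_scale=0.01)
        res = fit_mixture_model(g, y, prior, NoiseModel([np.nan], 0.5))
        assert res[0].converged
        assert np.all((res[0].responsibilities >= 0)
                      & (res[0].responsibilities <= 1))

    def test_window_cap_enforced(self, small_sim):
        g, y, _, _ = small_sim
        prior = PriorSpec.constant(g.n_snps)
        with pytest.raises(ValueError, match="smaller windows"):
            fit_mixture_model(g, y, prior, NoiseModel([1.0]),
                              OptimizerConfig(max_window_snps=10))
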