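"""Conditional MLE, kernel estimators, information matrix and diagnostics."""
import numpy as np
import pytest
from scipy.special import expit

from latentlink import (
    EstimationConfig,
    FixedEffects,
    ModelParams,
    NetworkPanel,
    SimulationConfig,
    delta_matrix,
    entropy_HC,
    estimate_all_fixed_effects,
    estimate_fixed_effect,
    fit_mle,
    information_matrix,
    kernel_delta,
    profile_loglik,
    simulate_panel,
    split_panel_jackknife,
)
from conftest import additive_model_panel, random_panel


class TestFitMLE:
    def test_recovers_true_parameters(self):
        errs = []
        for seed in range(3):
            panel, params, _ = additive_model_panel(n_nodes=40, n_periods=10, seed=seed)
            fit = fit_mle(panel, q=1)
            assert fit.converged
            errs.append(np.linalg.norm(fit.theta_hat.as_vector() - params.as_vector()))
        assert np.mean(errs) < 0.15

    def test_effects_sum_to_zero(self):
        panel, _, _ = additive_model_panel(n_nodes=20, n_periods=8, seed=1)
        fit = fit_mle(panel, q=1)
        assert abs(fit.a_hat.node_effects.sum()) < 1e-8

    def test_empty_network_flags_separation(self):
        panel = NetworkPanel(np.zeros((5, 10, 10), dtype=int),
                             np.ones((10, 1)))
        fit = fit_mle(panel, q=1, config=EstimationConfig(max_iter=15))
        assert fit.diagnostics["separation_nodes"] == list(range(10))

    def test_ridge_restores_convergence_under_separation(self):
        panel = NetworkPanel(np.zeros((5, 10, 10), dtype=int), np.ones((10, 1)))
        fit = fit_mle(panel, q=1, config=EstimationConfig(ridge=1e-2))
        assert fit.converged

    def test_loglik_never_below_profiled_fit(self):
        panel, params, _ = additive_model_panel(n_nodes=25, n_periods=8, seed=3)
        full = fit_mle(panel, q=1)
        prof_ll, _ = profile_loglik(panel, 1, params)
        assert full.loglik >= prof_ll - 1e-8

    def test_absolute_difference_rule_not_estimable(self):
        # the estimation design is additive by construction; the simulation
        # rule |A_i - A_j| has no concave representation and no code path here
        panel, _, _ = additive_model_panel(n_nodes=15, n_periods=6, seed=0)
        fit = fit_mle(panel, q=1)
        assert fit.a_hat.pair_rule == "additive"


class TestInformation:
    def test_symmetric_psd(self):
        panel, _, _ = additive_model_panel(n_nodes=25, n_periods=8, seed=2)
        fit = fit_mle(panel, q=1)
        J = information_matrix(panel, fit)
        np.testing.assert_allclose(J, J.T, atol=1e-10)
        assert np.linalg.eigvalsh(J).min() > 0

    def test_one_parameter_finite_difference_oracle(self):
        # static single-covariate model: profile information in beta equals
        # the numeric negative second difference of the profile log-likelihood
        panel, _, _ = additive_model_panel(n_nodes=15, n_periods=6, seed=4, alpha=0.0)
        fit = fit_mle(panel, q=0)
        beta_hat = fit.theta_hat.beta[0]
        J = information_matrix(panel, fit)[0, 0]
        h = 1e-4
        lp = lambda b: profile_loglik(panel, 0, ModelParams(beta=[b]))[0]
        fd = -(lp(beta_hat + h) - 2 * lp(beta_hat) + lp(beta_hat - h)) / h**2
        assert J == pytest.approx(fd, rel=1e-3)

    def test_jackknife_returns_finite_correction(self):
        panel, params, _ = additive_model_panel(n_nodes=30, n_periods=12, seed=5)
        theta_bc, full = split_panel_jackknife(panel, q=1)
        assert np.isfinite(theta_bc.as_vector()).all()
        assert np.linalg.norm(theta_bc.as_vector() - params.as_vector()) < 0.5


class TestKernelDelta:
    def _twin_panel(self):
        # nodes 0 and 1 have identical link patterns (both tied to 2 and 3)
        C = np.zeros((2, 5, 5), dtype=int)
        for t in range(2):
            for k in (2, 3):
                C[t, 0, k] = C[t, k, 0] = 1
                C[t, 1, k] = C[t, k, 1] = 1
        return NetworkPanel(C, np.linspace(0, 1, 5)[:, None])

    def test_identical_rows_give_zero(self):
        panel = self._twin_panel()
        assert kernel_delta(panel, 0, 1, x=0.5) == pytest.approx(0.0)

    def test_antisymmetry(self):
        panel = random_panel(n_nodes=9, n_periods=4, seed=7)
        for (i, j) in [(0, 3), (2, 8), (4, 5)]:
            d1 = kernel_delta(panel, i, j, x=0.1)
            d2 = kernel_delta(panel, j, i, x=0.1)
            assert d1 == pytest.approx(-d2)

    def test_direct_weighted_average_oracle(self):
        panel = random_panel(n_nodes=8, n_periods=3, seed=8)
        cfg = EstimationConfig()
        x = 0.2
        X = panel.covariates[:, :, 0]
        h = 1.06 * X.std() * 8 ** (-0.2)
        u = (x - X) / h
        K = np.where(np.abs(u) <= 1, 0.75 * (1 - u**2), 0.0)
        W = K / K.sum()
        for (i, j) in [(0, 1), (3, 6)]:
            manual = ((panel.adjacency[:, i, :] - panel.adjacency[:, j, :]) * W).sum()
            assert kernel_delta(panel, i, j, x=x, config=cfg) == pytest.approx(manual)
            assert delta_matrix(panel, x, cfg)[i, j] == pytest.approx(manual)

    def test_query_outside_support_raises(self):
        panel = random_panel(n_nodes=8, n_periods=3, seed=9)
        with pytest.raises(ValueError, match="empty kernel neighborhood"):
            kernel_delta(panel, 0, 1, x=1e6)

    def test_contrast_error_shrinks_with_network_size(self):
        # covariate-free benchmark: constant covariate makes weights uniform
        # and the population contrast has the closed form mean_l p_il - p_jl
        def max_err(N, seed):
            rng = np.random.default_rng(seed)
            a = rng.uniform(-1, 1, N)
            a -= a.mean()
            cfg = SimulationConfig(
                n_nodes=N, n_periods=10, params=ModelParams(),
                effects=FixedEffects(a, "additive"),
                covariates=np.ones((N, 1)), seed=seed,
            )
            panel = simulate_panel(cfg)
            P = expit(a[:, None] + a[None, :])
            np.fill_diagonal(P, 0.0)
            v = P.mean(axis=1)
            true = v[:, None] - v[None, :]
            return np.abs(delta_matrix(panel, 1.0) - true).max()

        errs30 = np.mean([max_err(30, s) for s in range(5)])
        errs90 = np.mean([max_err(90, s) for s in range(5)])
        assert errs90 < errs30


class TestKernelFixedEffect:
    def test_zero_theta_gives_zero(self):
        panel = random_panel(n_nodes=10, n_periods=3, seed=10)
        assert estimate_fixed_effect(panel, 2, ModelParams(beta=[0.0])) == 0.0

    def test_uniform_weight_reduction(self):
        # an enormous bandwidth flattens the weights, so the estimate reduces
        # to (1/N) times the plain mean of the homophily scalars
        panel = random_panel(n_nodes=8, n_periods=3, seed=11)
        theta = ModelParams(beta=[0.7])
        cfg = EstimationConfig(bandwidth_sigma=1e12)
        l = 4
        N = 8
        iu = np.triu_indices(N, 1)
        keep = (iu[0] != l) & (iu[1] != l)
        s = np.zeros(len(iu[0]))
        for t in range(3):
            X = panel.covariates[t]
            X_il = X * X[l]
            u = X_il.sum(axis=1)
            w = X_il @ theta.beta
            s += 0.5 * (u[iu[0]] * w[iu[1]] + u[iu[1]] * w[iu[0]])
        expected = s[keep].mean() / 3 / N
        assert estimate_fixed_effect(panel, l, theta, cfg) == pytest.approx(expected, rel=1e-6)

    def test_recovers_covariate_driven_heterogeneity(self):
        # effects generated as a smooth function of the node covariate plus
        # 30% independent noise: the kernel estimator tracks the smooth part
        cors = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            N, T = 100, 20
            x = rng.uniform(0.5, 1.5, N)
            signal = 0.8 * (x**2 - (x**2).mean())
            a = signal + rng.normal(0, 0.3 * signal.std(), N)
            a -= a.mean()
            params = ModelParams(alpha=[0.3], beta=[0.5])
            cfg = SimulationConfig(
                n_nodes=N, n_periods=T, params=params,
                effects=FixedEffects(a, "additive"), covariates=x[:, None], seed=seed,
            )
            panel = simulate_panel(cfg)
            a_hat = estimate_all_fixed_effects(panel, params)
            cors.append(np.corrcoef(a_hat, a)[0, 1])
        assert np.mean(cors) > 0.8


def test_entropy_estimate_approaches_truth_with_size():
    """Per-dyad-period gap between entropy at fitted vs true parameters shrinks."""
    gaps = []
    for N in (30, 60, 120):
        d = []
        for seed in range(3):
            panel, params, effects = additive_model_panel(n_nodes=N, n_periods=10, seed=100 + seed)
            fit = fit_mle(panel, q=1, compute_information=False)
            H0 = entropy_HC(panel, params, effects, mode="closed_form").H_per_dyad_period
            Hh = entropy_HC(panel, fit.theta_hat, fit.a_hat, mode="closed_form").H_per_dyad_period
            d.append(abs(Hh - H0))
        gaps.append(np.mean(d))
    assert gaps[2] < gaps[1] < gaps[0]
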