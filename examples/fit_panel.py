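"""Estimate persistence, homophily and node effects from one simulated panel.

Simulates a 60-node, 15-period panel with known theta = (alpha, beta) =
(0.3, 0.5) and additive node effects, then runs the joint conditional MLE
under the sum-to-zero normalization and prints estimates with standard
errors from the profile information, plus the split-panel jackknife
bias-corrected point estimate."""
import numpy as np

from latentlink import (
    FixedEffects,
    ModelParams,
    SimulationConfig,
    fit_mle,
    simulate_panel,
    split_panel_jackknife,
)

rng = np.random.default_rng(0)
N, T = 60, 15
x = rng.choice([-1.0, 1.0], size=N)[:, None]
a = rng.uniform(-0.5, 0.5, N)
a -= a.mean()
truth = ModelParams(alpha=[0.3], beta=[0.5])
panel = simulate_panel(SimulationConfig(
    n_nodes=N, n_periods=T, params=truth,
    effects=FixedEffects(a, "additive"), covariates=x, seed=0,
))

fit = fit_mle(panel, q=1)
names = ["alpha_1 (persistence)", "beta (homophily)"]
print(f"converged in {fit.n_iter} Newton steps, loglik = {fit.loglik:.1f}")
for name, tru, est, se in zip(names, truth.as_vector(), fit.theta_hat.as_vector(), fit.std_errors):
    print(f"{name:22s} true {tru:5.2f}  estimate {est:6.3f} +/- {se:.3f}")
print(f"node effects: sum = {fit.a_hat.node_effects.sum():.2e} (normalized), "
      f"corr with truth = {np.corrcoef(fit.a_hat.node_effects, a)[0, 1]:.3f}")

theta_bc, _ = split_panel_jackknife(panel, q=1)
print("split-panel jackknife estimate:", np.round(theta_bc.as_vector(), 3),
      "(removes the leading short-panel bias)")
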