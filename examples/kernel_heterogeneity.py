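"""Kernel estimation of unobserved heterogeneity from link contrasts.

Node effects are generated as a smooth function of the node covariate plus
independent noise (correlated heterogeneity).  The dyadic contrast
delta_ij(x) localizes pairs that behave alike toward nodes with covariate
near x; the kernel-weighted homophily average then tracks the
covariate-predictable part of each node's effect."""
import numpy as np

from latentlink import (
    FixedEffects,
    ModelParams,
    SimulationConfig,
    delta_matrix,
    estimate_all_fixed_effects,
    simulate_panel,
)

rng = np.random.default_rng(3)
N, T = 100, 20
x = rng.uniform(0.5, 1.5, N)
signal = 0.8 * (x**2 - (x**2).mean())
a = signal + rng.normal(0, 0.3 * signal.std(), N)
a -= a.mean()
params = ModelParams(alpha=[0.3], beta=[0.5])
panel = simulate_panel(SimulationConfig(
    n_nodes=N, n_periods=T, params=params,
    effects=FixedEffects(a, "additive"), covariates=x[:, None], seed=3,
))

dm = delta_matrix(panel, x=1.0)
print(f"dyadic contrast delta_ij at x=1.0: antisymmetry residual "
      f"{np.abs(dm + dm.T).max():.1e}, range [{dm.min():.3f}, {dm.max():.3f}]")

a_hat = estimate_all_fixed_effects(panel, params)
corr = np.corrcoef(a_hat, a)[0, 1]
print(f"kernel fixed-effect estimates vs true effects: correlation = {corr:.3f}")
print("(only the covariate-predictable component of heterogeneity is identified)")
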