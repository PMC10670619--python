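import numpy as np
import pytest

from latentlink import (
    FixedEffects,
    ModelParams,
    NetworkPanel,
    SimulationConfig,
    simulate_panel,
)


def random_panel(n_nodes=8, n_periods=4, seed=0, density=0.3, with_covariates=True, d=1):
    """Arbitrary valid panel (not drawn from the model): a fixture factory."""
    rng = np.random.default_rng(seed)
    C = np.zeros((n_periods, n_nodes, n_nodes), dtype=np.int8)
    iu = np.triu_indices(n_nodes, 1)
    for t in range(n_periods):
        links = (rng.random(len(iu[0])) < density).astype(np.int8)
        C[t][iu] = links
        C[t][(iu[1], iu[0])] = links
    cov = rng.normal(size=(n_nodes, d)) if with_covariates else None
    return NetworkPanel(C, cov)


def additive_model_panel(n_nodes=40, n_periods=10, seed=0, alpha=0.3, beta=0.5,
                         effect_scale=0.5):
    """Panel simulated from the model with additive effects: the estimation DGP.

    Binary +/-1 node covariates under the product transform, centered uniform
    node effects of half-width ``effect_scale``, q = 1.
    """
    rng = np.random.default_rng(seed)
    x = rng.choice([-1.0, 1.0], size=n_nodes)[:, None]
    a = rng.uniform(-effect_scale, effect_scale, n_nodes)
    a -= a.mean()
    params = ModelParams(alpha=[alpha], beta=[beta])
    effects = FixedEffects(a, "additive")
    cfg = SimulationConfig(
        n_nodes=n_nodes, n_periods=n_periods, params=params, effects=effects,
        covariates=x, seed=seed,
    )
    return simulate_panel(cfg), params, effects


@pytest.fixture
def small_panel():
    return random_panel(n_nodes=8, n_periods=4, seed=42)
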