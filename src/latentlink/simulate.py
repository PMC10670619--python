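"""Synthetic data generators.

Three kinds of objects are generated here:

* dynamic network panels drawn from the latent-index formation rule,
  including the exact benchmark design (T=15, q=10, beta=0.5, parity
  covariates, |A_i - A_j| effects with A_i = ((N-i)/(N-1)) log N);
* one-period Erdos-Renyi and Barabasi-Albert baseline networks;
* sparse taxon x sample (OTU) count tables with global singletons,
  multi-level taxonomy strings and optional planted co-abundance blocks,
  emulating an 18S rRNA amplicon survey (the reference survey has 3831
  taxa over 19 samples of which 1779 are global singletons; those are the
  generator defaults).

All randomness flows through a single :class:`numpy.random.Generator`; the
logistic shocks are drawn by inverse-CDF from one uniform stream so the same
seed reproduces a panel bit for bit.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    CovTransform,
    FixedEffects,
    LagConvention,
    ModelParams,
    NetworkPanel,
)
from .otu import OTUTable

__all__ = [
    "SimulationConfig",
    "simulate_panel",
    "dgp_section4",
    "erdos_renyi",
    "barabasi_albert",
    "synthetic_otu_table",
]


@dataclass
class SimulationConfig:
    """Full description of one panel-simulation experiment."""

    n_nodes: int
    n_periods: int
    params: ModelParams
    effects: FixedEffects | None = None
    covariates: np.ndarray | None = None      # (N, d) or (T, N, d)
    cov_transform: CovTransform = "product"
    include_memory: bool = False
    lag_convention: LagConvention = "strict_past"
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self):
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")
        if self.n_periods < 1:
            raise ValueError("need at least 1 period")
        if self.params.q >= 1 and self.params.alpha_norm >= 1.0:
            raise ValueError(
                f"persistence vector must satisfy ||alpha|| < 1; got {self.params.alpha_norm:.3f}"
            )


def simulate_panel(config: SimulationConfig) -> NetworkPanel:
    """Draw one panel from the latent-index rule.

    Period by period: form the index from lagged links, covariates, memory and
    effects, then set C_ij,t = 1{index > eps} with eps standard logistic,
    drawn once per unordered pair via inverse CDF of a seeded uniform stream.

    Memory accumulation during simulation is necessarily strict-past (the
    current period's links cannot enter their own formation rule); requesting
    ``inclusive`` here is an error.
    """
    if config.include_memory and config.lag_convention == "inclusive":
        raise ValueError(
            "inclusive memory is circular in simulation: C_t would enter its own formation rule"
        )
    rng = np.random.default_rng(config.seed)
    N, T = config.n_nodes, config.n_periods
    C = np.zeros((T, N, N), dtype=np.int8)
    D_running = np.zeros((N, N), dtype=np.int64)
    iu = np.triu_indices(N, 1)

    for t in range(1, T + 1):
        idx = _index_for_period(C, config, D_running, t)
        u = rng.random(len(iu[0]))
        eps = np.log(u) - np.log1p(-u)          # standard logistic via inverse CDF
        links = (idx[iu] > eps).astype(np.int8)
        C[t - 1][iu] = links
        C[t - 1][(iu[1], iu[0])] = links
        if config.include_memory:
            S = C[t - 1].astype(np.int64) @ C[t - 1].astype(np.int64)
            np.fill_diagonal(S, 0)
            D_running += S
    return NetworkPanel(C, config.covariates, None)


def _index_for_period(C, config: SimulationConfig, D_running, t: int) -> np.ndarray:
    """Latent index at period t given the simulated history in C[: t-1]."""
    from .model import pair_covariates

    N = config.n_nodes
    params = config.params
    idx = np.zeros((N, N))
    for p in range(1, params.q + 1):
        tp = t - p
        if tp >= 1:
            idx += params.alpha[p - 1] * C[tp - 1]
    if params.beta.size:
        if config.covariates is None:
            raise ValueError("beta specified but no covariates in config")
        X = np.asarray(config.covariates, dtype=float)
        x_t = X[t - 1] if X.ndim == 3 else X
        Xp = pair_covariates(x_t, config.cov_transform)
        if Xp.shape[2] != params.beta.size:
            raise ValueError(
                f"beta dim {params.beta.size} != pair covariate dim {Xp.shape[2]}"
            )
        idx += Xp @ params.beta
    if config.include_memory:
        idx = idx + D_running
    if config.effects is not None:
        idx = idx + config.effects.pair_matrix()
    np.fill_diagonal(idx, 0.0)
    return idx


def dgp_section4(
    N: int,
    T: int = 15,
    q: int = 10,
    seed: int = 0,
    alpha_norm_target: float = 0.9,
) -> tuple[NetworkPanel, ModelParams, FixedEffects]:
    """The benchmark data-generating process at size N.

    beta0 = 0.5 (scalar); node covariate X_i = 1 - 2*1{i even} (1-based), so
    even-indexed nodes prefer even-indexed partners under the product
    transform; A_i = ((N-i)/(N-1)) log N with pair rule |A_i - A_j|; alpha0 is
    drawn uniform on (-1,1)^q and rescaled to the requested norm (< 1).  The
    displayed benchmark rule carries no shared-partner memory term, so the
    panel is simulated without it.

    Returns the panel together with the true parameters and effects.
    """
    if N < q + 2:
        raise ValueError(f"need N >= q+2 = {q + 2}; got N={N}")
    if not 0 < alpha_norm_target < 1:
        raise ValueError("alpha_norm_target must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    alpha = rng.uniform(-1.0, 1.0, size=q)
    alpha *= alpha_norm_target / np.linalg.norm(alpha)
    params = ModelParams(alpha=alpha, beta=[0.5])
    i = np.arange(1, N + 1)
    x = np.where(i % 2 == 0, -1.0, 1.0)[:, None]
    a = (N - i) / (N - 1) * np.log(N)
    effects = FixedEffects(a, pair_rule="absolute_difference")
    config = SimulationConfig(
        n_nodes=N, n_periods=T, params=params, effects=effects,
        covariates=x, cov_transform="product", include_memory=False,
        seed=int(rng.integers(2**31 - 1)),
    )
    return simulate_panel(config), params, effects


def erdos_renyi(N: int, p: float, seed: int = 0) -> NetworkPanel:
    """One-period Erdos-Renyi G(N, p): each unordered pair linked independently."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(N, 1)
    C = np.zeros((1, N, N), dtype=np.int8)
    links = (rng.random(len(iu[0])) < p).astype(np.int8)
    C[0][iu] = links
    C[0][(iu[1], iu[0])] = links
    return NetworkPanel(C)


def barabasi_albert(
    N: int, m: int = 5, seed: int = 0, seed_graph_density: float = 0.5
) -> NetworkPanel:
    """One-period preferential-attachment network.

    Growth starts from an m-node seed graph whose density is
    ``seed_graph_density`` (standard preferential attachment has no per-link
    probability; the benchmark's "connection probability of 0.5" is read as
    the seed-graph density).  Each arriving node attaches to ``m`` distinct
    existing nodes chosen proportionally to degree (uniformly while all
    degrees are zero), giving ~ m(N - m) growth edges.
    """
    if N <= m:
        raise ValueError(f"need N > m = {m}")
    rng = np.random.default_rng(seed)
    A = np.zeros((N, N), dtype=np.int8)
    iu = np.triu_indices(m, 1)
    links = (rng.random(len(iu[0])) < seed_graph_density).astype(np.int8)
    A[:m, :m][iu] = links
    A[:m, :m][(iu[1], iu[0])] = links
    degrees = A.sum(axis=1).astype(np.float64)
    for new in range(m, N):
        existing = np.arange(new)
        # tiny floor keeps zero-degree nodes reachable when fewer than m
        # nodes have positive degree (sparse seed graphs)
        w = degrees[:new] + 1e-9
        w /= w.sum()
        k = min(m, new)
        targets = rng.choice(existing, size=k, replace=False, p=w)
        for tgt in targets:
            A[new, tgt] = A[tgt, new] = 1
        degrees[new] += k
        degrees[targets] += 1
    return NetworkPanel(A[None, :, :])


_TAXON_LEVELS: list[list[str]] = [
    ["Dinophyta", "Metazoa", "Rhizaria", "Archaeplastida", "Opisthokonta", "Alveolata"],
    ["Syndiniales", "Dinophyceae", "Ciliophora", "Acantharia", "Chlorophyta", "Arthropoda", "Fungi"],
    ["DinoGroupII", "DinoGroupI", "Suessiales", "Spirotrichea", "Chaunacanthida", "Pyramimonadales"],
    ["Clade10", "Clade16", "Clade7", "CladeX", "Clade1", "Clade3"],
    ["GyrodiniumX", "SymbiodiniumX", "ProtaspaX", "HexaconusX", "KarlodiniumX"],
    ["sp1", "sp2", "sp3", "spX"],
    ["strainA", "strainB", "strainC"],
    ["isolate1", "isolate2"],
]


def _taxonomy_string(rng: np.random.Generator) -> str:
    depth = int(rng.integers(7, 9))  # 7 or 8 semicolon-delimited levels
    return ";".join(str(rng.choice(_TAXON_LEVELS[k])) for k in range(depth))


def synthetic_otu_table(
    n_taxa: int = 3831,
    n_samples: int = 19,
    n_singletons: int = 1779,
    seed: int = 0,
    community_structure: dict | None = None,
    mean_depth: float = 3e4,
) -> OTUTable:
    """Sparse taxon x sample count table with planted structure.

    Core (non-singleton) taxa receive log-normal base abundances; per-sample
    counts are multinomial at a log-normally varying sequencing depth, with
    independent per-taxon-per-sample log-normal abundance shifts.  Optional
    ``community_structure={"n_blocks": B, "strength": s, "block_size": k}``
    plants B co-abundance blocks: block members share a per-sample log-normal
    factor of scale s, so block-mates co-vary across samples.  Exactly
    ``n_singletons`` additional taxa carry a single count in one sample
    (core taxa sampled down to a total of <= 1 are topped up so the global
    singleton count is exact by construction).
    """
    if n_singletons >= n_taxa:
        raise ValueError("n_singletons must be smaller than n_taxa")
    if n_samples < 2:
        raise ValueError("need at least two samples")
    rng = np.random.default_rng(seed)
    n_core = n_taxa - n_singletons
    base = rng.lognormal(mean=0.0, sigma=2.0, size=n_core)
    logshift = rng.normal(0.0, 0.5, size=(n_core, n_samples))
    intensity = base[:, None] * np.exp(logshift)

    block_of = np.full(n_core, -1)
    if community_structure:
        B = int(community_structure.get("n_blocks", 2))
        strength = float(community_structure.get("strength", 1.5))
        block_size = int(community_structure.get("block_size", max(3, n_core // (2 * B))))
        if B * block_size > n_core:
            raise ValueError("planted blocks exceed the number of core taxa")
        factors = rng.lognormal(mean=0.0, sigma=strength, size=(B, n_samples))
        for b in range(B):
            members = np.arange(b * block_size, (b + 1) * block_size)
            block_of[members] = b
            intensity[members] *= factors[b]

    counts = np.zeros((n_core, n_samples), dtype=np.int64)
    depths = rng.lognormal(mean=np.log(mean_depth), sigma=0.25, size=n_samples)
    for s in range(n_samples):
        pr = intensity[:, s] / intensity[:, s].sum()
        counts[:, s] = rng.multinomial(int(depths[s]), pr)
    # keep the global singleton count exact: top up core taxa sampled to <= 1
    low = np.flatnonzero(counts.sum(axis=1) <= 1)
    for r in low:
        counts[r, rng.integers(n_samples)] += 2

    singles = np.zeros((n_singletons, n_samples), dtype=np.int64)
    singles[np.arange(n_singletons), rng.integers(0, n_samples, size=n_singletons)] = 1

    all_counts = np.vstack([counts, singles])
    taxonomy = [_taxonomy_string(rng) + f";OTU{r + 1}" for r in range(n_taxa)]
    sample_ids = [f"S{s + 1}" for s in range(n_samples)]
    meta = {"block": np.concatenate([block_of, np.full(n_singletons, -1)])}
    return OTUTable(all_counts, taxonomy, sample_ids, metadata=meta)
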