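"""Core data structures and deterministic maps of the dynamic latent-index
link-formation model.

The model describes an undirected binary network observed over ``T`` periods.
For every unordered dyad ``{i, j}`` and period ``t`` the link indicator is

    C_ij,t = 1{ sum_p alpha_p C_ij,t-p + beta' X_ij,t + D_ij,t + A_ij > eps_ij,t }

with i.i.d. standard-logistic shocks ``eps_ij,t``, so that conditionally on
history the link is Bernoulli with probability ``p_ij,t = z/(1+z)`` where
``z = exp(index)``.  The index combines four channels:

* persistence  -- ``alpha`` acting on the dyad's own ``q`` lagged links;
* homophily    -- ``beta`` acting on a symmetric transform of the two node
                  covariate vectors (elementwise product by default);
* triadic memory -- ``D_ij,t``, the cumulative count of common neighbours the
                  dyad has had in the past ("shared partners");
* unobserved heterogeneity -- ``A_ij`` built from node effects ``A_i`` via a
                  symmetric pair rule.

Everything in this module is deterministic given its inputs; random panel
generation lives in :mod:`latentlink.simulate` and estimation in
:mod:`latentlink.estimate`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy.special import expit

PairRule = Literal["additive", "absolute_difference"]
CovTransform = Literal["product", "absolute_difference", "distance"]
LagConvention = Literal["strict_past", "inclusive"]

__all__ = [
    "NetworkPanel",
    "ModelParams",
    "FixedEffects",
    "MemoryTensor",
    "LikelihoodField",
    "TotalLogLik",
    "compute_memory",
    "pair_covariates",
    "latent_index",
    "link_probability",
    "loglik_contribution",
    "total_loglik",
    "theorem1_deviation",
]


def _as_adjacency(adjacency) -> np.ndarray:
    arr = np.asarray(adjacency)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError(f"adjacency must be (T, N, N); got shape {arr.shape}")
    if arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValueError("empty panel: need at least one period and one node")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("adjacency entries must be 0/1")
    if np.abs(arr - np.swapaxes(arr, 1, 2)).max(initial=0) != 0:
        raise ValueError("adjacency matrices must be symmetric")
    if any(np.diagonal(arr[t]).any() for t in range(arr.shape[0])):
        raise ValueError("self-ties are ruled out: diagonal must be zero")
    return arr.astype(np.int8)


@dataclass
class NetworkPanel:
    """Observed object: T symmetric binary adjacency matrices + covariates.

    Parameters
    ----------
    adjacency : array (T, N, N)
        Binary, symmetric, zero-diagonal matrices ``C_t``.
    covariates : array (N, d) or (T, N, d), optional
        Per-node covariate vectors ``X_i,t``; a 2-d array is treated as
        time-invariant and broadcast over periods.
    node_ids : sequence of str, optional
        Labels; defaults to "1".."N" (1-based, matching the TSV formats).
    """

    adjacency: np.ndarray
    covariates: np.ndarray | None = None
    node_ids: Sequence[str] | None = None

    def __post_init__(self):
        self.adjacency = _as_adjacency(self.adjacency)
        T, N, _ = self.adjacency.shape
        if self.covariates is not None:
            X = np.asarray(self.covariates, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            if X.ndim == 2:
                X = np.broadcast_to(X, (T,) + X.shape).copy()
            if X.ndim != 3 or X.shape[0] != T or X.shape[1] != N:
                raise ValueError(
                    f"covariates must be (N, d) or (T, N, d) with N={N}, T={T}; "
                    f"got {np.asarray(self.covariates).shape}"
                )
            self.covariates = X
        if self.node_ids is None:
            self.node_ids = [str(i + 1) for i in range(N)]
        elif len(self.node_ids) != N:
            raise ValueError("node_ids length must equal N")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[1]

    @property
    def n_periods(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[2]

    def degree_sequence(self, t: int) -> np.ndarray:
        """Row sums of C_t (1-based period index): the degree sequence C+."""
        return self.adjacency[t - 1].sum(axis=1)

    def subpanel(self, periods: Sequence[int]) -> "NetworkPanel":
        """Panel restricted to the given 1-based periods (order preserved)."""
        idx = [t - 1 for t in periods]
        cov = None if self.covariates is None else self.covariates[idx]
        return NetworkPanel(self.adjacency[idx], cov, list(self.node_ids))


@dataclass
class ModelParams:
    """theta = (alpha, beta): persistence and homophily coefficients.

    ``alpha`` has length q (the lag order; q = 0 gives the static submodel),
    ``beta`` has the dimension of the pair covariate transform.  The formation
    model requires ||alpha|| < 1; this is enforced where panels are simulated,
    not here, because estimated values must remain representable.
    """

    alpha: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not (np.isfinite(self.alpha).all() and np.isfinite(self.beta).all()):
            raise ValueError("model parameters must be finite")

    @property
    def q(self) -> int:
        return self.alpha.size

    @property
    def alpha_norm(self) -> float:
        return float(np.linalg.norm(self.alpha))

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.alpha, self.beta])


@dataclass
class FixedEffects:
    """Node effects a_N = (A_1..A_N) and the pair rule mapping them to A_ij."""

    node_effects: np.ndarray
    pair_rule: PairRule = "additive"

    def __post_init__(self):
        self.node_effects = np.atleast_1d(np.asarray(self.node_effects, dtype=float))
        if not np.isfinite(self.node_effects).all():
            raise ValueError("node effects must be finite")
        if self.pair_rule not in ("additive", "absolute_difference"):
            raise ValueError(f"unknown pair_rule: {self.pair_rule!r}")

    @property
    def n_nodes(self) -> int:
        return self.node_effects.size

    def pair_matrix(self) -> np.ndarray:
        """A_ij as an (N, N) symmetric zero-diagonal matrix."""
        a = self.node_effects
        if self.pair_rule == "additive":
            M = a[:, None] + a[None, :]
        else:
            M = np.abs(a[:, None] - a[None, :])
        np.fill_diagonal(M, 0.0)
        return M

    @classmethod
    def zero(cls, n: int, pair_rule: PairRule = "additive") -> "FixedEffects":
        return cls(np.zeros(n), pair_rule)


@dataclass
class MemoryTensor:
    """Shared-partner memory D_ij,t accumulated over periods.

    ``values[t-1]`` holds D_.,t.  Under the default ``strict_past`` convention
    D_ij,t counts common neighbours over periods t' <= t-1, keeping the latent
    index predetermined; ``inclusive`` (t' <= t) follows the printed formula
    literally but makes C_t enter its own formation rule.
    """

    values: np.ndarray
    lag_convention: LagConvention = "strict_past"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("memory values must be (T, N, N)")


def compute_memory(panel: NetworkPanel, lag_convention: LagConvention = "strict_past") -> MemoryTensor:
    """Cumulative shared-partner counts D_ij,t = sum_{t'} sum_k C_ik,t' C_jk,t'.

    The per-period contribution is the off-diagonal part of ``C_t' @ C_t'``
    (entry (i,j) counts common neighbours of i and j at t').  ``strict_past``
    accumulates over t' <= t-1 (D_.,1 = 0); ``inclusive`` over t' <= t.
    """
    if lag_convention not in ("strict_past", "inclusive"):
        raise ValueError(f"unknown lag_convention: {lag_convention!r}")
    C = panel.adjacency.astype(np.int64)
    T, N, _ = C.shape
    shared = np.einsum("tik,tjk->tij", C, C)
    for t in range(T):
        np.fill_diagonal(shared[t], 0)
    cum = np.cumsum(shared, axis=0)
    if lag_convention == "strict_past":
        D = np.zeros_like(cum)
        D[1:] = cum[:-1]
    else:
        D = cum
    return MemoryTensor(D, lag_convention)


def pair_covariates(x_t: np.ndarray, transform: CovTransform = "product") -> np.ndarray:
    """Symmetric dyad transform X_ij,t from node covariates x_t of shape (N, d).

    ``product`` gives the elementwise product X_i * X_j (the benchmark DGP's
    X_it X_jt' form); ``absolute_difference`` the per-component |X_i - X_j|;
    ``distance`` the Euclidean distance as a single component.
    """
    x_t = np.atleast_2d(np.asarray(x_t, dtype=float))
    if transform == "product":
        return x_t[:, None, :] * x_t[None, :, :]
    if transform == "absolute_difference":
        return np.abs(x_t[:, None, :] - x_t[None, :, :])
    if transform == "distance":
        d = np.linalg.norm(x_t[:, None, :] - x_t[None, :, :], axis=2)
        return d[:, :, None]
    raise ValueError(f"unknown covariate transform: {transform!r}")


def latent_index(
    panel: NetworkPanel,
    params: ModelParams,
    effects: FixedEffects | None = None,
    memory: MemoryTensor | None = None,
    t: int = 1,
    cov_transform: CovTransform = "product",
) -> np.ndarray:
    """Latent index matrix for period t (1-based).

    index_ij,t = sum_{p=1..q} alpha_p C_ij,t-p + beta' X_ij,t + D_ij,t + A_ij.
    Pre-sample lags (t-p < 1) are zero matrices.
    """
    T, N = panel.n_periods, panel.n_nodes
    if not 1 <= t <= T:
        raise ValueError(f"period t={t} outside 1..{T}")
    idx = np.zeros((N, N))
    for p in range(1, params.q + 1):
        tp = t - p
        if tp >= 1:
            idx += params.alpha[p - 1] * panel.adjacency[tp - 1]
    if params.beta.size:
        if panel.covariates is None:
            raise ValueError(
                f"beta has dim {params.beta.size} but panel has no covariates"
            )
        Xp = pair_covariates(panel.covariates[t - 1], cov_transform)
        if Xp.shape[2] != params.beta.size:
            raise ValueError(
                f"beta dim {params.beta.size} != pair covariate dim {Xp.shape[2]}"
            )
        idx += Xp @ params.beta
    if memory is not None:
        idx = idx + memory.values[t - 1]
    if effects is not None:
        idx = idx + effects.pair_matrix()
    np.fill_diagonal(idx, 0.0)
    return idx


@dataclass
class LikelihoodField:
    """Link probabilities and odds for one period.

    ``p = z / (1 + z)`` elementwise with ``z = exp(index)``; p is clipped into
    [kappa, 1-kappa] so log-likelihood terms are finite (the clip is applied
    only inside probability space, never to simulated draws).
    """

    index: np.ndarray
    p: np.ndarray
    clip_kappa: float = 1e-12

    @property
    def z(self) -> np.ndarray:
        return self.p / (1.0 - self.p)


def link_probability(index: np.ndarray, clip_kappa: float = 1e-12) -> LikelihoodField:
    """Map a latent index matrix to link probabilities via the logistic CDF.

    Computed with :func:`scipy.special.expit` (numerically stable for large
    |index|), then clipped to [kappa, 1-kappa].
    """
    if not np.isfinite(index).all():
        raise ValueError("latent index must be finite")
    if not 0 < clip_kappa < 0.5:
        raise ValueError("clip_kappa must lie in (0, 0.5)")
    p = np.clip(expit(index), clip_kappa, 1.0 - clip_kappa)
    return LikelihoodField(index=np.asarray(index, dtype=float), p=p, clip_kappa=clip_kappa)


def loglik_contribution(panel: NetworkPanel, fld: LikelihoodField, t: int) -> np.ndarray:
    """Per-dyad log-likelihood l_ij,t = c log p + (1-c) log(1-p), diagonal zeroed."""
    c = panel.adjacency[t - 1]
    l = c * np.log(fld.p) + (1 - c) * np.log1p(-fld.p)
    np.fill_diagonal(l, 0.0)
    return l


class TotalLogLik(NamedTuple):
    raw: float        # sum over i<j, t of l_ij,t
    scaled: float     # (N T_used)^(-1/2) * raw; argmax-equivalent
    n_dyad_periods: int


def total_loglik(
    panel: NetworkPanel,
    params: ModelParams,
    effects: FixedEffects | None = None,
    memory: MemoryTensor | None = None,
    cov_transform: CovTransform = "product",
    periods: Literal["all", "post_lag"] = "all",
    clip_kappa: float = 1e-12,
) -> TotalLogLik:
    """Panel log-likelihood over i<j and the selected periods.

    ``periods="all"`` uses t = 1..T with zero pre-sample lags; ``"post_lag"``
    restricts to t = q+1..T (the estimation sample).  Both the raw sum and a
    (N*T)^(-1/2)-scaled version are returned; scaling does not move the argmax.
    """
    N, T = panel.n_nodes, panel.n_periods
    t0 = params.q + 1 if periods == "post_lag" else 1
    if t0 > T:
        raise ValueError(f"no usable periods: q={params.q} >= T={T}")
    iu = np.triu_indices(N, 1)
    raw = 0.0
    for t in range(t0, T + 1):
        idx = latent_index(panel, params, effects, memory, t, cov_transform)
        fld = link_probability(idx, clip_kappa)
        raw += float(loglik_contribution(panel, fld, t)[iu].sum())
    T_used = T - t0 + 1
    return TotalLogLik(raw, raw / np.sqrt(N * T_used), len(iu[0]) * T_used)


def theorem1_deviation(
    panel: NetworkPanel,
    params: ModelParams,
    effects: FixedEffects | None = None,
    memory: MemoryTensor | None = None,
    cov_transform: CovTransform = "product",
) -> tuple[float, float]:
    """Concentration diagnostic: aggregate link-frequency deviation vs ln(NT).

    Returns ``(stat, bound)`` with
    stat = |sum_{i<j,t} (C_ij,t - p_ij,t)| / ((N-1) T) and bound = ln(N T);
    under the model the statistic falls below the bound with probability
    approaching one, so it is asserted on every simulated fixture.
    """
    N, T = panel.n_nodes, panel.n_periods
    iu = np.triu_indices(N, 1)
    dev = 0.0
    for t in range(1, T + 1):
        idx = latent_index(panel, params, effects, memory, t, cov_transform)
        fld = link_probability(idx)
        dev += float((panel.adjacency[t - 1] - fld.p)[iu].sum())
    return abs(dev) / ((N - 1) * T), float(np.log(N * T))
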