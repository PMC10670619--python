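"""Shannon-type entropy of a dynamic network and reference entropies.

Each dyad-period contributes the probability mass the model assigns to the
realized outcome, ltilde_ij,t = p^c (1-p)^(1-c) in (0, 1) (the exponential of
the log-likelihood contribution).  The dynamic-network entropy is

    H(C) = sum_{i<j} sum_t -ltilde log ltilde
         = sum_{i<j} sum_t sum_{k>=1} ltilde (1 - ltilde)^k / k,

the two forms being identical through the series -log x = sum_k (1-x)^k / k
for x in (0, 1).  H(C) is 0 exactly when every realized outcome was predicted
with probability one, and grows as outcomes become less predictable; the
per-dyad-period value is bounded by 1/e (the maximum of -x log x).

Two closed-form topology bounds are evaluated verbatim with a component
breakdown for audit.  Both involve quantities that can leave the domain of
the logarithm on ordinary instances (the chain constant K = sum log[p(1-p)]
is always negative, and the chained-dyad residual rho can be negative), so
each bound carries a ``defined`` flag and violations are reported by the
diagnostic audit rather than asserted.

Reference measures for comparison tables: the Erdos-Renyi entropy
C(N,2) * H_b(p) (independent-edge binary entropy) and the Shannon entropy of
the empirical degree distribution.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .model import (
    CovTransform,
    FixedEffects,
    MemoryTensor,
    ModelParams,
    NetworkPanel,
    latent_index,
    link_probability,
    loglik_contribution,
)

__all__ = [
    "EntropyReport",
    "BoundReport",
    "outcome_likelihoods",
    "entropy_HC",
    "entropy_upper_bound",
    "entropy_lower_bound",
    "erdos_renyi_entropy",
    "degree_shannon_entropy",
]


@dataclass
class BoundReport:
    value: float
    defined: bool
    components: dict = field(default_factory=dict)
    reason: str | None = None


@dataclass
class EntropyReport:
    H_raw: float
    H_series: float
    H_per_dyad_period: float
    series_truncation_k: int
    n_dyad_periods: int
    upper_bound: BoundReport | None = None
    lower_bound: BoundReport | None = None
    baselines: dict = field(default_factory=dict)


def outcome_likelihoods(
    panel: NetworkPanel,
    params: ModelParams,
    effects: FixedEffects | None = None,
    memory: MemoryTensor | None = None,
    cov_transform: CovTransform = "product",
    clip_kappa: float = 1e-12,
) -> np.ndarray:
    """ltilde_ij,t = exp(l_ij,t) = p^c (1-p)^(1-c) stacked as (T, n_pairs)."""
    N, T = panel.n_nodes, panel.n_periods
    iu = np.triu_indices(N, 1)
    out = np.empty((T, len(iu[0])))
    for t in range(1, T + 1):
        idx = latent_index(panel, params, effects, memory, t, cov_transform)
        fld = link_probability(idx, clip_kappa)
        out[t - 1] = np.exp(loglik_contribution(panel, fld, t)[iu])
    if out.min() <= 0.0 or out.max() >= 1.0:
        raise AssertionError("outcome likelihoods left (0, 1) after clipping")
    return out


def _series_kmax(lt: np.ndarray, tol: float = 1e-10, cap: int = 200_000) -> int:
    """Smallest k with r^k / k < tol for r = max(1 - ltilde)."""
    r = float((1.0 - lt).max())
    if r <= 0.0:
        return 1
    k = max(1, int(np.ceil(np.log(tol) / np.log(r))))
    while r**k / k >= tol and k < cap:
        k = min(cap, k * 2)
    return k


def entropy_HC(
    panel: NetworkPanel,
    params: ModelParams,
    effects: FixedEffects | None = None,
    memory: MemoryTensor | None = None,
    mode: Literal["closed_form", "series", "both"] = "both",
    k_max: int | None = None,
    cov_transform: CovTransform = "product",
    clip_kappa: float = 1e-12,
) -> EntropyReport:
    """Dynamic-network entropy H(C) in closed and/or series form.

    The closed form sums -ltilde log ltilde over dyad-periods; the series form
    truncates sum_k ltilde (1-ltilde)^k / k at ``k_max`` (chosen so the
    worst-case tail is below 1e-10 when not given).  Both are reported;
    ``mode`` selects which ones are actually computed (the other is copied).
    """
    lt = outcome_likelihoods(panel, params, effects, memory, cov_transform, clip_kappa)
    n_dp = lt.size
    H_closed = float(-(lt * np.log(lt)).sum()) if mode in ("closed_form", "both") else np.nan
    if mode in ("series", "both"):
        k_used = k_max if k_max is not None else _series_kmax(lt)
        flat = lt.ravel()
        term = np.ones_like(flat)
        r = 1.0 - flat
        H_series = 0.0
        for k in range(1, k_used + 1):
            term = term * r
            H_series += float((flat * term).sum()) / k
    else:
        k_used = 0
        H_series = np.nan
    if mode == "series":
        H_closed = H_series
    if mode == "closed_form":
        H_series, k_used = H_closed, 0
    return EntropyReport(
        H_raw=H_closed,
        H_series=H_series,
        H_per_dyad_period=H_closed / n_dp,
        series_truncation_k=k_used,
        n_dyad_periods=n_dp,
    )


def entropy_upper_bound(
    panel: NetworkPanel,
    params: ModelParams,
    effects: FixedEffects | None = None,
    memory: MemoryTensor | None = None,
    cov_transform: CovTransform = "product",
) -> BoundReport:
    """Topology upper bound built from chained dyads (i, i+1) and spokes (i, N).

    Per period t:  (rho_t/K) log(K (N-2) / rho_t)
                   - sum_i (l_{i,i+1,t}/K) log(l_{i,i+1,t}/K)
                   - sum_i (l_{i,N,t}/K)  log(l_{i,N,t}/K),
    with rho_t = sum_{k<l} l_kl,t - sum_k [l_{k,k+1,t} + l_{k,N,t}] and the
    chain constant K = sum_{i<j,t} log[z/(1+z)^2]; contributions l are on the
    ltilde mapping.  Summed over t.  K <= 0 or rho_t <= 0 puts the expression
    outside the domain of the logarithm; the bound is then flagged undefined
    (components still reported for audit).
    """
    N, T = panel.n_nodes, panel.n_periods
    iu = np.triu_indices(N, 1)
    lt = outcome_likelihoods(panel, params, effects, memory, cov_transform)
    # K from the raw odds: z/(1+z)^2 = p(1-p)
    K = 0.0
    for t in range(1, T + 1):
        idx = latent_index(panel, params, effects, memory, t, cov_transform)
        p = link_probability(idx).p
        K += float(np.log(p * (1.0 - p))[iu].sum())
    Lmat = np.zeros((T, N, N))
    Lmat[:, iu[0], iu[1]] = lt
    Lmat[:, iu[1], iu[0]] = lt

    chain_idx = (np.arange(N - 1), np.arange(1, N))       # (i, i+1), i = 1..N-1
    spoke_idx = (np.arange(N - 1), np.full(N - 1, N - 1))  # (i, N)
    rho_ts, value = [], 0.0
    defined = K > 0.0
    reason = None if defined else "chain constant K <= 0"
    for t in range(T):
        chain = Lmat[t][chain_idx]
        spoke = Lmat[t][spoke_idx]
        rho_t = float(lt[t].sum() - chain.sum() - spoke.sum())
        rho_ts.append(rho_t)
        if defined and rho_t > 0.0:
            value += (rho_t / K) * np.log(K * (N - 2) / rho_t)
            value -= float(((chain / K) * np.log(chain / K)).sum())
            value -= float(((spoke / K) * np.log(spoke / K)).sum())
        elif defined:
            defined, reason = False, f"rho <= 0 at period {t + 1}"
    return BoundReport(
        value=value if defined else np.nan,
        defined=defined,
        components={"K": K, "rho": rho_ts},
        reason=reason,
    )


def entropy_lower_bound(
    panel: NetworkPanel,
    params: ModelParams,
    effects: FixedEffects | None = None,
    memory: MemoryTensor | None = None,
    lag: int = 1,
    cov_transform: CovTransform = "product",
) -> BoundReport:
    """Mutual-information lower bound from two lagged information sets.

    The dyad distributions rho_ij,F and rho_ij,F' normalize the average
    outcome likelihoods over the later periods (t > lag) and the earlier
    periods (t <= T - lag) respectively; each sums to one over i < j.  The
    bound is -sum rho_F log rho_F' - (1/ln 2) sum (rho_F^2 - rho_F rho_F')
    / rho_F'.  With lag = 0 the filtrations coincide and the bound reduces to
    the plain Shannon entropy -sum rho log rho of the dyad distribution.
    """
    T = panel.n_periods
    if not 0 <= lag < T:
        raise ValueError(f"lag must lie in 0..{T - 1}")
    lt = outcome_likelihoods(panel, params, effects, memory, cov_transform)
    late = lt[lag:].mean(axis=0)
    early = lt[: T - lag].mean(axis=0)
    if late.sum() == 0.0 or early.sum() == 0.0:
        raise ValueError("zero normalizer in filtration distributions")
    rho_F = late / late.sum()
    rho_Fp = early / early.sum()
    cross = float(-(rho_F * np.log(rho_Fp)).sum())
    chi = float(((rho_F**2 - rho_F * rho_Fp) / rho_Fp).sum())
    value = cross - chi / np.log(2.0)
    return BoundReport(
        value=value,
        defined=True,
        components={"cross_entropy": cross, "chi_term": chi,
                    "rho_F_sum": float(rho_F.sum()), "rho_Fp_sum": float(rho_Fp.sum())},
    )


def erdos_renyi_entropy(N: int, p: float, base: float = np.e) -> float:
    """C(N,2) independent-edge binary entropies: the random-graph reference."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p in (0.0, 1.0):
        return 0.0
    hb = -p * np.log(p) - (1.0 - p) * np.log(1.0 - p)
    return float(N * (N - 1) / 2 * hb / np.log(base))


def degree_shannon_entropy(panel: NetworkPanel, period: int | None = None, base: float = np.e) -> float:
    """Shannon entropy of the empirical degree distribution (final period)."""
    t = panel.n_periods if period is None else period
    deg = panel.degree_sequence(t)
    _, counts = np.unique(deg, return_counts=True)
    qd = counts / counts.sum()
    return float(-(qd * np.log(qd)).sum() / np.log(base))
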