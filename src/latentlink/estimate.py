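"""Conditional maximum-likelihood estimation and kernel heterogeneity tools.

The joint log-likelihood of a panel is concave in (theta, a_N) when node
effects enter additively (A_ij = A_i + A_j), because the latent index is then
linear in all parameters and the Bernoulli/logistic log-likelihood is concave
in the index.  ``fit_mle`` maximizes it by damped Newton steps with analytic
gradient and Hessian, under the location normalization sum_i A_i = 0 (the
effects are only identified up to a constant absorbed by the dyad rule).  The
normalization is imposed by optimizing over the first N-1 effects with
A_N = -sum of the rest.

The |A_i - A_j| pair rule used by the benchmark simulation is not concave in
a_N and is deliberately not supported for estimation.

Kernel tools:

* ``kernel_delta`` -- the dyadic contrast delta_ij(x), a self-normalized
  (Nadaraya-Watson) average of C_il,t - C_jl,t over partner nodes l whose
  covariate is near the query x.  It is antisymmetric in (i, j) by
  construction.
* ``estimate_fixed_effect`` -- a kernel-weighted average of homophily
  contributions that targets the covariate-predictable component of a node's
  unobserved effect; pairs (i, j) that treat nodes like l similarly
  (delta_ij(x_l) near 0) receive high weight.

Standard errors come from the observed profile information in theta: the
Schur complement I = H_tt - H_ta H_aa^{-1} H_at of the full negative Hessian,
equivalently the negative curvature of the profile log-likelihood.  An
optional split-panel jackknife over the time dimension removes the leading
dynamic-panel bias.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import expit

from .model import (
    CovTransform,
    FixedEffects,
    LagConvention,
    ModelParams,
    NetworkPanel,
    compute_memory,
    pair_covariates,
)

__all__ = [
    "EstimationConfig",
    "FitResult",
    "fit_mle",
    "profile_loglik",
    "information_matrix",
    "split_panel_jackknife",
    "kernel_delta",
    "delta_matrix",
    "estimate_fixed_effect",
    "estimate_all_fixed_effects",
]


@dataclass
class EstimationConfig:
    """Tuning knobs for the MLE and the kernel estimators.

    Bandwidths default to the normal-reference rule 1.06 * sd * N^(-1/5)
    applied to the covariate (for K) and to the delta values (for L).
    """

    kernel_K: Literal["epanechnikov", "gaussian_truncated"] = "epanechnikov"
    bandwidth_h: float | None = None
    kernel_L: Literal["gaussian"] = "gaussian"
    bandwidth_sigma: float | None = None
    max_iter: int = 60
    tolerance: float = 1e-6        # sup-norm of the score at convergence
    ridge: float = 0.0             # concave -ridge/2 ||params||^2 penalty
    normalize: bool = True         # impose sum_i A_i = 0
    cov_transform: CovTransform = "product"
    include_memory: bool = False
    lag_convention: LagConvention = "strict_past"
    clip_kappa: float = 1e-12


@dataclass
class FitResult:
    theta_hat: ModelParams
    a_hat: FixedEffects
    loglik: float
    information: np.ndarray | None     # observed profile information in theta
    std_errors: np.ndarray | None
    converged: bool
    n_iter: int
    diagnostics: dict
    q: int
    config: EstimationConfig

    def to_dict(self) -> dict:
        return {
            "alpha": self.theta_hat.alpha.tolist(),
            "beta": self.theta_hat.beta.tolist(),
            "node_effects": self.a_hat.node_effects.tolist(),
            "pair_rule": self.a_hat.pair_rule,
            "loglik": self.loglik,
            "information": None if self.information is None else self.information.tolist(),
            "std_errors": None if self.std_errors is None else self.std_errors.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "diagnostics": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.diagnostics.items()
            },
            "q": self.q,
            "config": {
                "cov_transform": self.config.cov_transform,
                "include_memory": self.config.include_memory,
                "lag_convention": self.config.lag_convention,
                "ridge": self.config.ridge,
                "tolerance": self.config.tolerance,
                "max_iter": self.config.max_iter,
                "normalize": self.config.normalize,
            },
        }


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _build_design(panel: NetworkPanel, q: int, config: EstimationConfig):
    """Stack the estimation sample t = q+1..T, i < j into flat arrays.

    Returns (y, Z_theta, Z_a, offset, pair_index) where Z_theta holds the lag
    and covariate columns, Z_a the reduced node-incidence columns (N-1, with
    the last node's effect equal to minus the sum of the others), and offset
    the fixed-coefficient memory term.
    """
    N, T = panel.n_nodes, panel.n_periods
    if T <= q:
        raise ValueError(f"need T > q; got T={T}, q={q}")
    iu = np.triu_indices(N, 1)
    npairs = len(iu[0])
    periods = list(range(q + 1, T + 1))
    nt = len(periods)

    y = np.concatenate([panel.adjacency[t - 1][iu] for t in periods]).astype(float)

    cols = []
    for p in range(1, q + 1):
        cols.append(np.concatenate([panel.adjacency[t - p - 1][iu] for t in periods]).astype(float))
    d = panel.n_covariates
    if d:
        for a in range(d):
            block = []
            for t in periods:
                Xp = pair_covariates(panel.covariates[t - 1], config.cov_transform)
                block.append(Xp[:, :, a][iu])
            cols.append(np.concatenate(block))
    Z_theta = np.column_stack(cols) if cols else np.zeros((nt * npairs, 0))

    # node incidence, reduced for the sum-zero normalization
    B = np.zeros((npairs, N))
    B[np.arange(npairs), iu[0]] = 1.0
    B[np.arange(npairs), iu[1]] += 1.0
    Z_a_pair = B[:, : N - 1] - B[:, [N - 1]]
    Z_a = np.tile(Z_a_pair, (nt, 1))

    if config.include_memory:
        mem = compute_memory(panel, config.lag_convention)
        offset = np.concatenate([mem.values[t - 1][iu] for t in periods]).astype(float)
    else:
        offset = np.zeros(nt * npairs)

    pair_index = (np.tile(iu[0], nt), np.tile(iu[1], nt))
    return y, Z_theta, Z_a, offset, pair_index


def _separation_flags(y, pair_index, N) -> list[int]:
    """Nodes whose every usable dyad-period outcome is all-0 or all-1."""
    flags = []
    for k in range(N):
        rows = (pair_index[0] == k) | (pair_index[1] == k)
        if rows.any():
            yk = y[rows]
            if yk.min() == yk.max():
                flags.append(k)
    return flags


def _newton(y, Z, offset, ridge, tol, max_iter):
    """Damped Newton ascent of the (penalized) logistic log-likelihood."""
    n, P = Z.shape
    phi = np.zeros(P)

    def loglik(phi):
        eta = offset + Z @ phi
        ll = y @ eta - np.logaddexp(0.0, eta).sum()
        return ll - 0.5 * ridge * phi @ phi

    ll = loglik(phi)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(offset + Z @ phi)
        g = Z.T @ (y - p) - ridge * phi
        if np.abs(g).max() < tol:
            converged = True
            break
        w = p * (1.0 - p)
        H = (Z * w[:, None]).T @ Z
        H[np.diag_indices_from(H)] += ridge + 1e-12
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # halving line search on the concave objective
        s = 1.0
        for _ in range(40):
            cand = phi + s * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                phi, ll = cand, ll_new
                break
            s *= 0.5
        else:
            break
    grad_norm = float(np.abs(Z.T @ (y - expit(offset + Z @ phi)) - ridge * phi).max())
    return phi, ll, converged, it, grad_norm


def fit_mle(
    panel: NetworkPanel,
    q: int = 1,
    config: EstimationConfig | None = None,
    theta_fixed: ModelParams | None = None,
    compute_information: bool = True,
) -> FitResult:
    """Joint conditional MLE of (theta, a_N) with additive node effects.

    Maximizes sum_{i<j, t>q} [c log p + (1-c) log(1-p)] by damped Newton on
    the concave objective, under sum_i A_i = 0.  Complete separation (a node
    with all-0 or all-1 outcomes) is flagged in ``diagnostics`` and, when
    ``config.ridge > 0``, regularized away; non-convergence is flagged, never
    raised.  Pass ``theta_fixed`` to profile: only the effects are estimated.
    """
    config = config or EstimationConfig()
    N = panel.n_nodes
    y, Z_theta, Z_a, offset, pair_index = _build_design(panel, q, config)
    flags = _separation_flags(y, pair_index, N)

    if theta_fixed is not None:
        tv = theta_fixed.as_vector()
        if tv.size != Z_theta.shape[1]:
            raise ValueError(
                f"theta_fixed dim {tv.size} != design dim {Z_theta.shape[1]}"
            )
        offset = offset + Z_theta @ tv
        Z = Z_a
    else:
        Z = np.hstack([Z_theta, Z_a])

    phi, ll, converged, n_iter, grad_norm = _newton(
        y, Z, offset, config.ridge, config.tolerance, config.max_iter
    )

    P_theta = 0 if theta_fixed is not None else Z_theta.shape[1]
    d = panel.n_covariates
    if theta_fixed is not None:
        theta_hat = theta_fixed
    else:
        theta_hat = ModelParams(alpha=phi[:q], beta=phi[q:P_theta])
    u = phi[P_theta:]
    a = np.concatenate([u, [-u.sum()]])
    a_hat = FixedEffects(a, pair_rule="additive")

    diagnostics = {"separation_nodes": flags, "grad_norm": grad_norm}
    information = std_errors = None
    if compute_information and theta_fixed is None and P_theta > 0 and converged:
        try:
            information = _profile_information(y, Z_theta, Z_a, offset, phi, config.ridge)
            std_errors = np.sqrt(np.diag(np.linalg.inv(information)))
        except np.linalg.LinAlgError:
            diagnostics["information_error"] = "singular Hessian"
    return FitResult(
        theta_hat=theta_hat,
        a_hat=a_hat,
        loglik=float(ll),
        information=information,
        std_errors=std_errors,
        converged=converged,
        n_iter=n_iter,
        diagnostics=diagnostics,
        q=q,
        config=config,
    )


def _profile_information(y, Z_theta, Z_a, offset, phi, ridge):
    """Observed profile information in theta (Schur complement of -Hessian)."""
    P_theta = Z_theta.shape[1]
    eta = offset + np.hstack([Z_theta, Z_a]) @ phi
    w = expit(eta) * (1.0 - expit(eta))
    Htt = (Z_theta * w[:, None]).T @ Z_theta
    Hta = (Z_theta * w[:, None]).T @ Z_a
    Haa = (Z_a * w[:, None]).T @ Z_a
    Haa[np.diag_indices_from(Haa)] += ridge + 1e-10
    sol = np.linalg.solve(Haa, Hta.T)
    I = Htt - Hta @ sol
    cond = np.linalg.cond(Haa)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(f"effects Hessian ill-conditioned (cond={cond:.2e})")
    return 0.5 * (I + I.T)


def profile_loglik(
    panel: NetworkPanel, q: int, theta: ModelParams, config: EstimationConfig | None = None
) -> tuple[float, FixedEffects]:
    """max over a_N of the log-likelihood with theta held fixed."""
    fit = fit_mle(panel, q=q, config=config, theta_fixed=theta, compute_information=False)
    return fit.loglik, fit.a_hat


def information_matrix(panel: NetworkPanel, fit: FitResult) -> np.ndarray:
    """Recompute the observed profile information at the fitted parameters.

    Raises on a (near-)singular effects Hessian, reporting its condition
    number.  ``fit.std_errors`` are the square roots of the inverse diagonal.
    """
    config = fit.config
    y, Z_theta, Z_a, offset, _ = _build_design(panel, fit.q, config)
    u = fit.a_hat.node_effects[:-1]
    phi = np.concatenate([fit.theta_hat.as_vector(), u])
    return _profile_information(y, Z_theta, Z_a, offset, phi, config.ridge)


def split_panel_jackknife(
    panel: NetworkPanel, q: int = 1, config: EstimationConfig | None = None
) -> tuple[ModelParams, FitResult]:
    """Split-panel jackknife over time: theta_tilde = 2 theta_hat - mean(halves).

    Removes the leading O(1/T) dynamic-panel bias of the joint MLE.  Each
    half-panel keeps its own q presample lags within the half.  Returns the
    corrected parameters together with the full-panel fit.
    """
    T = panel.n_periods
    if T < 2 * (q + 1):
        raise ValueError(f"need T >= 2(q+1) for the split-panel jackknife; got T={T}")
    full = fit_mle(panel, q=q, config=config)
    half = T // 2
    fit1 = fit_mle(panel.subpanel(range(1, half + 1)), q=q, config=config, compute_information=False)
    fit2 = fit_mle(panel.subpanel(range(half + 1, T + 1)), q=q, config=config, compute_information=False)
    corrected = 2.0 * full.theta_hat.as_vector() - 0.5 * (
        fit1.theta_hat.as_vector() + fit2.theta_hat.as_vector()
    )
    return ModelParams(alpha=corrected[:q], beta=corrected[q:]), full


# ---------------------------------------------------------------------------
# kernel estimators
# ---------------------------------------------------------------------------

def _kernel_K(u: np.ndarray, kind: str) -> np.ndarray:
    if kind == "epanechnikov":
        return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0)
    if kind == "gaussian_truncated":
        # compact support on [-3, 3] so K(x) = 0 beyond a finite bound
        return np.where(np.abs(u) <= 3.0, np.exp(-0.5 * u**2), 0.0)
    raise ValueError(f"unknown kernel: {kind!r}")


def _bandwidth(values: np.ndarray, override: float | None, N: int) -> float:
    if override is not None:
        if override <= 0:
            raise ValueError("bandwidth must be positive")
        return float(override)
    sd = float(np.std(values))
    if sd == 0.0:
        sd = 1.0
    return 1.06 * sd * N ** (-0.2)


def _kernel_weights(panel: NetworkPanel, x: float, config: EstimationConfig, component: int):
    if panel.covariates is None:
        raise ValueError("kernel estimators need node covariates")
    X = panel.covariates[:, :, component]          # (T, N)
    h = _bandwidth(X, config.bandwidth_h, panel.n_nodes)
    K = _kernel_K((x - X) / h, config.kernel_K)
    tot = K.sum()
    if tot == 0.0:
        raise ValueError("empty kernel neighborhood: query outside covariate support")
    return K / tot


def delta_matrix(
    panel: NetworkPanel, x: float, config: EstimationConfig | None = None, component: int = 0
) -> np.ndarray:
    """All dyadic contrasts delta_ij(x) at once, as an antisymmetric matrix.

    Because the kernel weight attached to partner (l, t) does not depend on
    the dyad, delta_ij(x) = v_i(x) - v_j(x) with
    v_i(x) = sum_{l,t} C_il,t Ktilde(x - X_l,t); weights sum to one over all
    partner-period pairs.
    """
    config = config or EstimationConfig()
    W = _kernel_weights(panel, x, config, component)       # (T, N)
    v = np.einsum("til,tl->i", panel.adjacency.astype(float), W)
    return v[:, None] - v[None, :]


def kernel_delta(
    panel: NetworkPanel,
    i: int,
    j: int,
    x: float,
    t_window: tuple[int, int] | None = None,
    config: EstimationConfig | None = None,
    component: int = 0,
) -> float:
    """delta_ij(x): kernel-smoothed expected contrast C_il,t - C_jl,t.

    Self-normalized Nadaraya-Watson average over partner nodes l and periods
    t (optionally restricted to the 1-based inclusive window ``t_window``)
    with kernel weights centered at the query covariate value x.  Rows i and
    j identical implies delta = 0; always delta_ij = -delta_ji.
    """
    config = config or EstimationConfig()
    sub = panel if t_window is None else panel.subpanel(range(t_window[0], t_window[1] + 1))
    W = _kernel_weights(sub, x, config, component)
    contrast = sub.adjacency[:, i, :].astype(float) - sub.adjacency[:, j, :].astype(float)
    return float((contrast * W).sum())


def estimate_fixed_effect(
    panel: NetworkPanel,
    l: int,
    theta: ModelParams,
    config: EstimationConfig | None = None,
    component: int = 0,
) -> float:
    """Kernel estimate of node l's effect from the homophily structure.

    A_l(theta) = (1/N) * sum_{i<j, l not in {i,j}} w_ij s_ij / sum w_ij with
    w_ij = L(delta_ij(x_l) / sigma_N) (Gaussian L), so pairs that behave
    alike toward nodes with covariates near x_l dominate, and
    s_ij = mean_t (1/2)[(iota'X_il,t)(X_jl,t'beta) + (iota'X_jl,t)(X_il,t'beta)],
    the symmetrized scalar collapse of the pairwise homophily contribution
    involving l.  Only the covariate (beta) block of theta enters: the
    persistence block multiplies lagged links, not covariates.

    The estimand is the covariate-predictable component of heterogeneity;
    effects orthogonal to the covariates are invisible to this estimator.
    """
    config = config or EstimationConfig()
    N, T = panel.n_nodes, panel.n_periods
    if not 0 <= l < N:
        raise ValueError(f"node {l} outside 0..{N - 1}")
    if panel.covariates is None:
        raise ValueError("kernel estimators need node covariates")
    x_l = float(panel.covariates[:, l, component].mean())
    dm = delta_matrix(panel, x_l, config, component)
    iu = np.triu_indices(N, 1)
    keep = (iu[0] != l) & (iu[1] != l)
    dvals = dm[iu][keep]
    sigma = _bandwidth(dm[iu], config.bandwidth_sigma, N)
    w = np.exp(-0.5 * (dvals / sigma) ** 2)
    if w.sum() == 0.0 or not np.isfinite(w.sum()):
        raise ValueError("degenerate kernel weights in fixed-effect estimation")

    beta = theta.beta
    d = panel.n_covariates
    if beta.size != d:
        raise ValueError(f"beta dim {beta.size} != covariate dim {d}")
    s = np.zeros(len(iu[0]))
    for t in range(T):
        X = panel.covariates[t]                      # (N, d)
        X_il = X * X[l]                              # product transform rows vs l
        u_vec = X_il.sum(axis=1)                     # iota' X_il
        w_vec = X_il @ beta                          # X_il' beta
        s += 0.5 * (u_vec[iu[0]] * w_vec[iu[1]] + u_vec[iu[1]] * w_vec[iu[0]])
    s = s[keep] / T
    return float((w @ s) / (N * w.sum()))


def estimate_all_fixed_effects(
    panel: NetworkPanel, theta: ModelParams, config: EstimationConfig | None = None
) -> np.ndarray:
    """Kernel fixed-effect estimates for every node, centered to sum zero."""
    est = np.array([estimate_fixed_effect(panel, l, theta, config) for l in range(panel.n_nodes)])
    return est - est.mean()
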