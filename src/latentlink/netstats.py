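"""Descriptive network statistics and two null-hypothesis tests.

* ``summarize`` -- degree mean/SD, local clustering (Watts-Strogatz average,
  degree-<2 nodes contributing 0), global transitivity and density for one
  period of a panel.
* ``randomness_test`` -- chi-square goodness of fit of the degree
  distribution against a Poisson law with ML-estimated mean, the degree
  signature of an Erdos-Renyi graph; a small p-value indicates the degrees
  are incompatible with purely random link formation.  A Monte Carlo variant
  compares the same statistic against matched ER graphs.
* ``modularity_null_test`` -- permutation test of a partition's
  Newman-Girvan modularity against a degree-preserving rewired ensemble
  (double-edge swaps), isolating mesoscale structure from the degree
  sequence.  The add-one estimator keeps p in (0, 1].
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .model import NetworkPanel

__all__ = [
    "NetworkSummary",
    "summarize",
    "panel_graph",
    "randomness_test",
    "RandomnessTestResult",
    "modularity_null_test",
    "ModularityTestResult",
]


@dataclass
class NetworkSummary:
    mean_degree: float
    degree_sd: float
    clustering_mean: float
    clustering_sd: float
    density: float
    transitivity: float
    degree_sequence: np.ndarray

    def as_row(self) -> dict:
        return {
            "mean_degree": self.mean_degree,
            "degree_sd": self.degree_sd,
            "clustering_mean": self.clustering_mean,
            "clustering_sd": self.clustering_sd,
            "density": self.density,
            "transitivity": self.transitivity,
        }


def panel_graph(panel: NetworkPanel, period: int | None = None) -> nx.Graph:
    """networkx view of one period (1-based; default final period)."""
    t = panel.n_periods if period is None else period
    G = nx.from_numpy_array(panel.adjacency[t - 1])
    return G


def summarize(panel: NetworkPanel, period: int | None = None) -> NetworkSummary:
    """Degree, clustering and density summary of one period.

    density = mean_degree / (N - 1) for a simple undirected graph; the local
    clustering coefficient of nodes with degree < 2 is counted as 0, not
    excluded.
    """
    if panel.n_nodes < 2:
        raise ValueError("need at least 2 nodes to summarize")
    t = panel.n_periods if period is None else period
    G = panel_graph(panel, t)
    deg = panel.degree_sequence(t).astype(float)
    clust = np.array(list(nx.clustering(G).values()))
    return NetworkSummary(
        mean_degree=float(deg.mean()),
        degree_sd=float(deg.std()),
        clustering_mean=float(clust.mean()),
        clustering_sd=float(clust.std()),
        density=float(deg.mean() / (panel.n_nodes - 1)),
        transitivity=float(nx.transitivity(G)),
        degree_sequence=deg.astype(int),
    )


@dataclass
class RandomnessTestResult:
    statistic: float
    dof: int
    p_value: float
    n_bins: int
    method: str


def _pool_poisson_bins(degrees: np.ndarray, lam: float, min_expected: float = 5.0):
    """Observed/expected counts with adjacent bins pooled so expected >= 5."""
    n = degrees.size
    kmax = int(degrees.max())
    ks = np.arange(kmax + 1)
    probs = stats.poisson.pmf(ks, lam)
    probs = np.append(probs, max(1.0 - probs.sum(), 0.0))    # tail bin > kmax
    obs = np.append(np.bincount(degrees, minlength=kmax + 1), 0.0)
    exp = n * probs
    pooled_obs, pooled_exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            pooled_obs.append(acc_o)
            pooled_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and pooled_exp:
        pooled_obs[-1] += acc_o
        pooled_exp[-1] += acc_e
    return np.array(pooled_obs), np.array(pooled_exp)


def randomness_test(
    degree_sequence: Sequence[int],
    method: Literal["chi2", "monte_carlo"] = "chi2",
    n_replicates: int = 200,
    seed: int = 0,
) -> RandomnessTestResult:
    """Test the degree distribution against the Erdos-Renyi (Poisson) null.

    ``chi2``: goodness-of-fit statistic with bins pooled to expected counts
    >= 5 and dof = bins - 2 (one for the total, one for the estimated mean).
    ``monte_carlo``: the same statistic referred to its distribution over ER
    graphs matched on N and mean degree.
    """
    degrees = np.asarray(degree_sequence, dtype=int)
    if degrees.size < 2:
        raise ValueError("need at least two nodes")
    lam = float(degrees.mean())
    obs, exp = _pool_poisson_bins(degrees, lam)
    if len(obs) < 2:
        raise ValueError("fewer than 2 pooled bins: degree distribution degenerate")
    statistic = float(((obs - exp) ** 2 / exp).sum())
    dof = max(len(obs) - 2, 1)
    if method == "chi2":
        p = float(stats.chi2.sf(statistic, dof))
        return RandomnessTestResult(statistic, dof, p, len(obs), "chi2")
    # Monte Carlo reference: matched ER graphs
    from .simulate import erdos_renyi

    N = degrees.size
    p_edge = lam / (N - 1)
    rng = np.random.default_rng(seed)
    null_stats = []
    for _ in range(n_replicates):
        g = erdos_renyi(N, p_edge, seed=int(rng.integers(2**31 - 1)))
        d = g.degree_sequence(1)
        o, e = _pool_poisson_bins(d, float(d.mean()))
        if len(o) >= 2:
            null_stats.append(float(((o - e) ** 2 / e).sum()))
    null_stats = np.asarray(null_stats)
    p = float((1 + (null_stats >= statistic).sum()) / (1 + len(null_stats)))
    return RandomnessTestResult(statistic, dof, p, len(obs), "monte_carlo")


@dataclass
class ModularityTestResult:
    q_observed: float
    q_null: np.ndarray
    p_value: float
    n_replicates: int


def modularity_null_test(
    panel_or_graph,
    partition: Sequence[Sequence[int]],
    n_replicates: int = 1000,
    seed: int = 0,
    period: int | None = None,
    swaps_per_edge: int = 10,
) -> ModularityTestResult:
    """Degree-preserving permutation test of partition modularity.

    Each replicate rewires the graph by ``swaps_per_edge * |E|`` double-edge
    swaps (degree sequence preserved exactly) and re-evaluates the
    Newman-Girvan modularity Q of the *same* partition;
    p = (1 + #{Q_null >= Q_obs}) / (1 + R).
    """
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    G = panel_or_graph if isinstance(panel_or_graph, nx.Graph) else panel_graph(panel_or_graph, period)
    communities = [set(c) for c in partition]
    covered = set().union(*communities) if communities else set()
    if covered != set(G.nodes):
        raise ValueError("partition must cover every node exactly")
    q_obs = nx.community.modularity(G, communities)
    m = G.number_of_edges()
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    q_null = np.empty(n_replicates)
    for r in range(n_replicates):
        H = G.copy()
        nx.double_edge_swap(
            H, nswap=swaps_per_edge * m, max_tries=100 * swaps_per_edge * m,
            seed=int(rng.integers(2**31 - 1)),
        )
        if dict(H.degree()) != dict(G.degree()):
            raise AssertionError("rewiring altered the degree sequence")
        q_null[r] = nx.community.modularity(H, communities)
    p = float((1 + (q_null >= q_obs).sum()) / (1 + n_replicates))
    return ModularityTestResult(q_obs, q_null, p, n_replicates)
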