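"""Co-occurrence network construction and evaluation against a reference.

The application pipeline treats taxa as nodes and samples as observation
periods.  Relative abundances are the node covariates: under the product
homophily transform, two taxa whose abundance profiles rise and fall together
receive a large positive association and hence a high link propensity.

An inferred signed network is scored against a reference interaction network
by classifying every unordered pair over the shared node set:

* TP -- edge in both networks with the same sign;
* FP -- inferred edge absent from the reference;
* FN -- reference edge absent from the inference;
* TN -- absent from both.

A shared edge whose signs disagree counts as one FP and one FN (the reference
definition only classifies same-sign agreement; mismatches are documented as
both an erroneous detection and a missed interaction).  When two taxa carry
associations of both signs, the sign with the larger absolute value is the
net sign.  From the counts: sensitivity TP/(TP+FN), specificity TN/(TN+FP),
precision TP/(TP+FP), F1 the harmonic mean of precision and sensitivity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .otu import OTUTable

__all__ = [
    "SignedNetwork",
    "ConfusionCounts",
    "association_matrix",
    "build_cooccurrence",
    "confusion",
    "classification_metrics",
    "f1_score",
    "jaccard_similarity",
    "mean_pairwise_jaccard",
    "detect_communities",
]


@dataclass
class SignedNetwork:
    """Undirected signed graph: one +/-1 sign per unordered node pair."""

    nodes: list
    edges: dict = field(default_factory=dict)   # {(i, j) with i < j: +1 or -1}

    def __post_init__(self):
        clean = {}
        for (i, j), s in self.edges.items():
            if i == j:
                raise ValueError("self-edges are not allowed")
            key = (i, j) if i < j else (j, i)
            if s not in (1, -1):
                raise ValueError("edge sign must be +1 or -1")
            clean[key] = s
        self.edges = clean

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set:
        return set(self.edges)

    def to_graph(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.nodes)
        for (i, j), s in self.edges.items():
            G.add_edge(i, j, sign=s)
        return G

    @classmethod
    def from_signed_values(cls, nodes: Sequence, values: Mapping[tuple, Iterable[float]]) -> "SignedNetwork":
        """Resolve multiple signed contributions per pair by the net-sign rule:
        the contribution with the larger absolute value decides the sign."""
        edges = {}
        for pair, vals in values.items():
            vals = list(vals)
            top = max(vals, key=abs)
            edges[pair] = 1 if top >= 0 else -1
        return cls(list(nodes), edges)


def association_matrix(table: OTUTable) -> np.ndarray:
    """Centered relative-abundance association (Pearson r across samples)."""
    rel = table.relative_abundance()
    centered = rel - rel.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    sd[sd == 0.0] = np.inf          # constant profiles associate with nothing
    Z = centered / sd[:, None]
    R = (Z @ Z.T) / rel.shape[1]
    np.fill_diagonal(R, 0.0)
    return R


def build_cooccurrence(
    table: OTUTable,
    probabilities: np.ndarray | None = None,
    threshold: float | str = "median_mad",
) -> SignedNetwork:
    """Signed co-occurrence network from an OTU table.

    Edge presence is gated by a score matrix: fitted pairwise link
    probabilities when supplied, otherwise the absolute association.  The
    default rule keeps pairs whose score exceeds the across-pair median plus
    one MAD; pass a float for an absolute cutoff.  Edge signs always come
    from the centered association.
    """
    if table.n_taxa < 3:
        raise ValueError("need at least 3 taxa to build a network")
    assoc = association_matrix(table)
    if probabilities is not None:
        score = np.asarray(probabilities, dtype=float)
        if score.shape != assoc.shape:
            raise ValueError("probabilities must be (n_taxa, n_taxa)")
    else:
        score = np.abs(assoc)
    iu = np.triu_indices(table.n_taxa, 1)
    vals = score[iu]
    if threshold == "median_mad":
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        cut = med + mad
    else:
        cut = float(threshold)
    edges = {}
    for i, j, s, a in zip(iu[0], iu[1], vals, assoc[iu]):
        if s > cut:
            edges[(int(i), int(j))] = 1 if a >= 0 else -1
    return SignedNetwork(list(range(table.n_taxa)), edges)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")


def confusion(inferred: SignedNetwork, truth: SignedNetwork) -> ConfusionCounts:
    """Classify every unordered pair over the shared node set.

    A shared edge with mismatched signs contributes one FP *and* one FN, so
    tp + tn + max(fp, fn) can undercount; the conservation identity checked
    in the tests is tp + tn + fp + fn - (#sign mismatches) = C(n, 2).
    """
    shared = set(inferred.nodes) & set(truth.nodes)
    if not shared:
        raise ValueError("inferred and truth networks share no nodes")
    inf_edges = {p: s for p, s in inferred.edges.items() if p[0] in shared and p[1] in shared}
    tru_edges = {p: s for p, s in truth.edges.items() if p[0] in shared and p[1] in shared}
    tp = fp = fn = 0
    for p, s in inf_edges.items():
        if p in tru_edges:
            if s == tru_edges[p]:
                tp += 1
            else:
                fp += 1
                fn += 1
        else:
            fp += 1
    for p in tru_edges:
        if p not in inf_edges:
            fn += 1
    n = len(shared)
    total_pairs = n * (n - 1) // 2
    mismatches = sum(
        1 for p, s in inf_edges.items() if p in tru_edges and s != tru_edges[p]
    )
    tn = total_pairs - (tp + fp + fn - mismatches)
    return ConfusionCounts(tp, fp, fn, tn)


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def classification_metrics(counts: ConfusionCounts) -> dict:
    """Sensitivity, specificity, precision and F1; NaN flags zero denominators."""
    sens = _safe_ratio(counts.tp, counts.tp + counts.fn)
    spec = _safe_ratio(counts.tn, counts.tn + counts.fp)
    prec = _safe_ratio(counts.tp, counts.tp + counts.fp)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1_score(prec, sens),
    }


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean 2ps/(p+s); NaN when undefined."""
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        return math.nan
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def jaccard_similarity(set_a: Iterable, set_b: Iterable) -> float:
    """|A n B| / |A u B|; NaN when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return math.nan
    return len(a & b) / len(union)


def mean_pairwise_jaccard(collections: Sequence[Iterable]) -> float:
    """Average Jaccard similarity over all unordered pairs of memberships."""
    sets = [set(c) for c in collections]
    if len(sets) < 2:
        raise ValueError("need at least two membership sets")
    vals = [
        jaccard_similarity(sets[i], sets[j])
        for i in range(len(sets))
        for j in range(i + 1, len(sets))
    ]
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.mean(vals)) if vals else math.nan


def detect_communities(network: SignedNetwork | nx.Graph, seed: int = 0) -> list[set]:
    """Modularity-maximizing partition via the (seeded) Louvain heuristic."""
    G = network.to_graph() if isinstance(network, SignedNetwork) else network
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    return [set(c) for c in nx.community.louvain_communities(G, seed=seed)]
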