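"""Singleton filter, co-occurrence construction, confusion metrics, communities."""
import math

import numpy as np
import pytest

from latentlink import (
    OTUTable,
    SignedNetwork,
    build_cooccurrence,
    classification_metrics,
    confusion,
    detect_communities,
    f1_score,
    filter_singletons,
    jaccard_similarity,
    mean_pairwise_jaccard,
    synthetic_otu_table,
)
from latentlink.cooccur import ConfusionCounts, association_matrix


def table_from(counts):
    counts = np.asarray(counts)
    return OTUTable(counts, [f"A;B;C;t{i}" for i in range(counts.shape[0])],
                    [f"S{j}" for j in range(counts.shape[1])])


class TestSingletonFilter:
    def test_definition_boundary(self):
        tab = table_from([[1, 0, 0], [1, 1, 0], [3, 2, 1]])
        filt, removed = filter_singletons(tab)
        assert removed == 1
        assert filt.n_taxa == 2
        assert filt.taxonomy[0].endswith("t1")  # total 2 retained

    def test_generator_ground_truth(self):
        tab = synthetic_otu_table(n_taxa=60, n_samples=8, n_singletons=10, seed=0)
        _, removed = filter_singletons(tab)
        assert removed == 10

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            filter_singletons(OTUTable(np.zeros((0, 3), dtype=int), [], ["a", "b", "c"]))


class TestBuildCooccurrence:
    def test_identical_profiles_linked_positive(self):
        rng = np.random.default_rng(0)
        base = rng.integers(5, 50, size=10)
        counts = rng.integers(0, 30, size=(6, 10))
        counts[0] = base
        counts[1] = base * 2          # same relative profile as taxon 0
        net = build_cooccurrence(table_from(counts))
        assert net.edges.get((0, 1)) == 1

    def test_unit_threshold_empty_network(self):
        tab = synthetic_otu_table(n_taxa=20, n_samples=8, n_singletons=0, seed=1)
        net = build_cooccurrence(tab, threshold=1.0)
        assert net.n_edges == 0

    def test_net_sign_resolution(self):
        net = SignedNetwork.from_signed_values(
            [0, 1], {(0, 1): [0.8, -0.3]}
        )
        assert net.edges[(0, 1)] == 1
        net = SignedNetwork.from_signed_values(
            [0, 1], {(0, 1): [0.2, -0.9]}
        )
        assert net.edges[(0, 1)] == -1

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            build_cooccurrence(table_from([[1, 2], [3, 4]]))


class TestConfusion:
    def test_perfect_inference(self):
        truth = SignedNetwork([0, 1, 2, 3], {(0, 1): 1, (2, 3): -1})
        c = confusion(truth, truth)
        assert (c.fp, c.fn) == (0, 0)
        assert c.tp == 2
        assert c.tn == 4  # remaining pairs of C(4,2)=6

    def test_empty_inference(self):
        truth = SignedNetwork([0, 1, 2], {(0, 1): 1, (1, 2): 1})
        inferred = SignedNetwork([0, 1, 2])
        c = confusion(inferred, truth)
        assert (c.tp, c.fp) == (0, 0)
        assert c.fn == 2

    def test_five_node_hand_instance_with_sign_flip(self):
        nodes = list(range(5))
        truth = SignedNetwork(nodes, {(0, 1): 1, (1, 2): -1, (3, 4): 1})
        inferred = SignedNetwork(nodes, {(0, 1): 1, (1, 2): 1, (0, 4): -1})
        # enumeration oracle over all C(5,2)=10 pairs
        tp = fp = fn = tn = 0
        for i in range(5):
            for j in range(i + 1, 5):
                ti, inf = truth.edges.get((i, j)), inferred.edges.get((i, j))
                if inf is not None and ti is not None:
                    if inf == ti:
                        tp += 1
                    else:
                        fp += 1
                        fn += 1
                elif inf is not None:
                    fp += 1
                elif ti is not None:
                    fn += 1
                else:
                    tn += 1
        c = confusion(inferred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn) == (1, 2, 2, 6)

    def test_pair_conservation_up_to_sign_mismatches(self):
        rng = np.random.default_rng(2)
        nodes = list(range(8))
        def random_net(seed):
            r = np.random.default_rng(seed)
            edges = {}
            for i in range(8):
                for j in range(i + 1, 8):
                    u = r.random()
                    if u < 0.4:
                        edges[(i, j)] = 1 if u < 0.2 else -1
            return SignedNetwork(nodes, edges)
        for s in range(5):
            a, b = random_net(s), random_net(100 + s)
            c = confusion(a, b)
            mismatches = sum(
                1 for p, sgn in a.edges.items() if p in b.edges and b.edges[p] != sgn
            )
            assert c.tp + c.fp + c.fn + c.tn - mismatches == 28  # C(8,2)

    def test_disjoint_node_sets_rejected(self):
        with pytest.raises(ValueError, match="share no nodes"):
            confusion(SignedNetwork([0, 1]), SignedNetwork([2, 3]))


class TestClassificationMetrics:
    @pytest.mark.parametrize("precision,sensitivity,expected", [
        (0.503, 0.895, 0.644),   # mid-morning sample
        (0.501, 0.896, 0.643),   # early afternoon
        (0.490, 0.900, 0.635),   # evening
        (0.494, 0.891, 0.636),   # late evening
        (0.496, 0.906, 0.641),   # overnight
    ])
    def test_f1_worked_examples(self, precision, sensitivity, expected):
        assert round(f1_score(precision, sensitivity), 3) == expected

    def test_f1_equals_inputs_when_equal(self):
        for s in (0.1, 0.5, 0.9):
            assert f1_score(s, s) == pytest.approx(s)

    def test_f1_between_min_and_max(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p, s = rng.uniform(0.05, 0.95, 2)
            f = f1_score(p, s)
            assert min(p, s) <= f <= max(p, s)

    def test_zero_denominators_flagged(self):
        m = classification_metrics(ConfusionCounts(0, 0, 0, 10))
        assert math.isnan(m["sensitivity"]) and math.isnan(m["precision"])
        assert math.isnan(m["f1"])
        assert m["specificity"] == 1.0

    def test_counts_from_metrics_roundtrip(self):
        c = ConfusionCounts(30, 10, 5, 55)
        m = classification_metrics(c)
        assert m["sensitivity"] == pytest.approx(30 / 35)
        assert m["specificity"] == pytest.approx(55 / 65)
        assert m["precision"] == pytest.approx(30 / 40)


class TestJaccard:
    def test_basic_cases(self):
        assert jaccard_similarity({1, 2}, {1, 2}) == 1.0
        assert jaccard_similarity({1, 2}, {3, 4}) == 0.0
        assert jaccard_similarity({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_both_empty_flagged(self):
        assert math.isnan(jaccard_similarity(set(), set()))

    def test_pairwise_average(self):
        sets = [{1, 2}, {1, 2}, {3}]
        # pairs: (1,1), (0), (0) -> mean 1/3
        assert mean_pairwise_jaccard(sets) == pytest.approx(1 / 3)


class TestCommunities:
    def test_two_disjoint_cliques(self):
        edges = {}
        for block in (range(5), range(5, 10)):
            block = list(block)
            for i in range(len(block)):
                for j in range(i + 1, len(block)):
                    edges[(block[i], block[j])] = 1
        net = SignedNetwork(list(range(10)), edges)
        part = detect_communities(net, seed=0)
        assert sorted(map(sorted, part)) == [list(range(5)), list(range(5, 10))]

    def test_deterministic_under_seed(self):
        tab = synthetic_otu_table(n_taxa=60, n_samples=12, n_singletons=5, seed=4,
                                  community_structure={"n_blocks": 2, "strength": 1.5,
                                                       "block_size": 12})
        filt, _ = filter_singletons(tab)
        net = build_cooccurrence(filt)
        p1 = detect_communities(net, seed=7)
        p2 = detect_communities(net, seed=7)
        assert sorted(map(sorted, p1)) == sorted(map(sorted, p2))

    def test_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(10):
            tab = synthetic_otu_table(
                n_taxa=120, n_samples=19, n_singletons=20, seed=seed,
                community_structure={"n_blocks": 3, "strength": 1.5, "block_size": 15},
            )
            filt, _ = filter_singletons(tab)
            blocks = filt.metadata["block"]
            net = build_cooccurrence(filt)
            label = {n: k for k, c in enumerate(detect_communities(net, seed=seed)) for n in c}
            members = np.flatnonzero(blocks >= 0)
            aris.append(adjusted_rand_score(blocks[members],
                                            [label[i] for i in members]))
        assert np.median(aris) >= 0.8

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_communities(SignedNetwork([], {}), seed=0)


def build_planted_truth(filt):
    """All within-block pairs with positive sign: the planted interaction network."""
    blocks = filt.metadata["block"]
    edges = {}
    for b in np.unique(blocks[blocks >= 0]):
        members = np.flatnonzero(blocks == b)
        for ii in range(len(members)):
            for jj in range(ii + 1, len(members)):
                edges[(int(members[ii]), int(members[jj]))] = 1
    return SignedNetwork(list(range(filt.n_taxa)), edges)


def test_end_to_end_beats_shuffled_baseline():
    """Planted co-abundance must be easier to detect than its shuffled control."""
    for seed in range(3):
        tab = synthetic_otu_table(
            n_taxa=120, n_samples=19, n_singletons=20, seed=seed,
            community_structure={"n_blocks": 3, "strength": 1.5, "block_size": 15},
        )
        filt, _ = filter_singletons(tab)
        truth = build_planted_truth(filt)
        planted = classification_metrics(confusion(build_cooccurrence(filt), truth))
        rng = np.random.default_rng(seed + 999)
        shuffled_counts = np.array([rng.permutation(row) for row in filt.counts])
        shuf = OTUTable(shuffled_counts, filt.taxonomy, filt.sample_ids)
        control = classification_metrics(confusion(build_cooccurrence(shuf), truth))
        assert planted["sensitivity"] > control["sensitivity"]
        assert planted["f1"] > control["f1"]
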