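"""Louvain, modularity, z-Rand, label agreement, sweep and selection."""

import itertools

import numpy as np
import networkx as nx
import pytest

import hipponet as hn
from hipponet.communities import (
    DegenerateGraphError,
    SelectionError,
    louvain_dense,
    modularity_dense,
    score_peaks,
    sweep_gamma,
    zrand_from_labels,
)
from conftest import random_symmetric_nonnegative


def fc_from_array(w, prefix="n"):
    ids = [f"{prefix}{i}" for i in range(w.shape[0])]
    return hn.FCMatrix(node_ids=ids, values=np.asarray(w, float), nonnegative=True)


def set_partitions(n):
    """All partitions of range(n) as label arrays (restricted growth strings)."""
    def rec(i, labels, k):
        if i == n:
            yield np.array(labels)
            return
        for lab in range(k + 1):
            yield from rec(i + 1, labels + [lab], max(k, lab + 1))
    yield from rec(0, [], 0)


def exhaustive_max_modularity(w, gamma=1.0):
    best = -np.inf
    best_labels = None
    for labels in set_partitions(w.shape[0]):
        q = modularity_dense(w, labels, gamma)
        if q > best:
            best, best_labels = q, labels
    return best, best_labels


def brute_force_modularity(w, labels, gamma):
    """Direct double-loop over the defining sum."""
    k = w.sum(axis=1)
    two_m = w.sum()
    q = 0.0
    for i in range(len(labels)):
        for j in range(len(labels)):
            if labels[i] == labels[j]:
                q += w[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


class TestModularity:
    def test_two_disjoint_dyads(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        p = hn.Partition(labels={"n0": 1, "n1": 1, "n2": 2, "n3": 2})
        assert hn.modularity(fc_from_array(w), p, 1.0) == pytest.approx(0.5)

    def test_single_community_is_zero(self):
        rng = np.random.default_rng(0)
        w = random_symmetric_nonnegative(rng, 7)
        labels = np.zeros(7, dtype=int)
        assert modularity_dense(w, labels, 1.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = random_symmetric_nonnegative(rng, 8)
        labels = rng.integers(0, 3, size=8)
        assert modularity_dense(w, labels, 1.3) == pytest.approx(
            brute_force_modularity(w, labels, 1.3), abs=1e-12
        )

    def test_matches_networkx(self):
        """Independent cross-check at gamma=1 against networkx."""
        rng = np.random.default_rng(3)
        w = random_symmetric_nonnegative(rng, 8)
        labels = rng.integers(0, 3, size=8)
        g = nx.from_numpy_array(w)
        comms = [
            {i for i in range(8) if labels[i] == lab} for lab in np.unique(labels)
        ]
        expected = nx.algorithms.community.modularity(g, comms, weight="weight")
        assert modularity_dense(w, labels, 1.0) == pytest.approx(expected, abs=1e-10)

    def test_degenerate_graph(self):
        with pytest.raises(DegenerateGraphError):
            modularity_dense(np.zeros((3, 3)), np.zeros(3, dtype=int), 1.0)

    def test_negative_weights_rejected(self):
        w = np.array([[0.0, -0.5], [-0.5, 0.0]])
        fc = hn.FCMatrix(node_ids=["a", "b"], values=w)
        p = hn.Partition(labels={"a": 1, "b": 1})
        with pytest.raises(ValueError, match="nonnegative"):
            hn.modularity(fc, p, 1.0)


def clique_pair(n_clique=5, bridge=0.01):
    n = 2 * n_clique
    w = np.zeros((n, n))
    for block in (slice(0, n_clique), slice(n_clique, n)):
        w[block, block] = 1.0
    np.fill_diagonal(w, 0.0)
    w[0, n_clique] = w[n_clique, 0] = bridge
    return w


class TestLouvain:
    def test_single_clique_one_community(self):
        w = np.ones((5, 5))
        np.fill_diagonal(w, 0.0)
        p = hn.louvain(fc_from_array(w), 1.0, seed=0)
        assert p.n_communities == 1

    def test_two_cliques_split(self):
        w = clique_pair()
        labels = louvain_dense(w, 1.0, np.random.default_rng(0))
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:5])) == 1 and len(np.unique(labels[5:])) == 1

    def test_large_gamma_all_singletons(self):
        rng = np.random.default_rng(4)
        w = random_symmetric_nonnegative(rng, 6)
        k = w.sum(1)
        two_m = w.sum()
        # choose gamma so the chance term dominates every edge weight
        gamma = 1.01 * (w.max() * two_m) / np.outer(k, k)[w > 0].min()
        labels = louvain_dense(w, gamma, np.random.default_rng(0))
        assert len(np.unique(labels)) == 6
        # verify: no merge of any pair increases Q at this gamma
        base = modularity_dense(w, labels, gamma)
        for i, j in itertools.combinations(range(6), 2):
            merged = labels.copy()
            merged[j] = merged[i]
            assert modularity_dense(w, merged, gamma) <= base + 1e-12

    def test_seed_deterministic(self):
        rng = np.random.default_rng(5)
        w = random_symmetric_nonnegative(rng, 12)
        p1 = hn.louvain(fc_from_array(w), 1.0, seed=42)
        p2 = hn.louvain(fc_from_array(w), 1.0, seed=42)
        assert p1.labels == p2.labels

    @pytest.mark.parametrize("seed", range(10))
    def test_single_node_local_optimum(self, seed):
        """No single-node reassignment may increase Q (checked exhaustively)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        w = random_symmetric_nonnegative(rng, n)
        labels = louvain_dense(w, 1.0, np.random.default_rng(seed))
        q0 = modularity_dense(w, labels, 1.0)
        targets = list(np.unique(labels)) + [labels.max() + 1]
        for i in range(n):
            for lab in targets:
                if lab == labels[i]:
                    continue
                moved = labels.copy()
                moved[i] = lab
                assert modularity_dense(w, moved, 1.0) <= q0 + 1e-10

    def test_negative_weight_rejected(self):
        w = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError, match="nonnegative"):
            louvain_dense(w, 1.0, np.random.default_rng(0))


def random_partition(rng, n, k):
    return rng.integers(0, k, size=n)


class TestZrand:
    def test_self_positive_and_symmetric(self):
        rng = np.random.default_rng(0)
        l1 = random_partition(rng, 60, 4)
        l2 = random_partition(rng, 60, 4)
        assert zrand_from_labels(l1, l1) > 0
        assert zrand_from_labels(l1, l2) == pytest.approx(
            zrand_from_labels(l2, l1), abs=1e-12
        )

    def test_label_permutation_invariance_exact(self):
        rng = np.random.default_rng(1)
        l1 = random_partition(rng, 40, 4)
        l2 = random_partition(rng, 40, 3)
        l2_renamed = np.array([10, 7, 99])[l2]
        assert zrand_from_labels(l1, l2) == zrand_from_labels(l1, l2_renamed)

    def test_node_reorder_invariance(self):
        rng = np.random.default_rng(2)
        nodes = [f"n{i}" for i in range(30)]
        p1 = hn.Partition(labels=dict(zip(nodes, random_partition(rng, 30, 3))))
        p2 = hn.Partition(labels=dict(zip(nodes, random_partition(rng, 30, 4))))
        z = hn.zrand(p1, p2)
        order = rng.permutation(30)
        p1s = hn.Partition(labels={nodes[i]: p1.labels[nodes[i]] for i in order})
        assert hn.zrand(p1s, p2) == pytest.approx(z, abs=1e-12)

    def test_degenerate_partitions_score_zero(self):
        ones = np.zeros(10, dtype=int)
        assert zrand_from_labels(ones, ones) == 0.0
        singletons = np.arange(10)
        assert zrand_from_labels(singletons, singletons) == 0.0

    def test_node_set_mismatch(self):
        p1 = hn.Partition(labels={"a": 1, "b": 1, "c": 2, "d": 2})
        p2 = hn.Partition(labels={"a": 1, "b": 1, "c": 2, "e": 2})
        with pytest.raises(ValueError):
            hn.zrand(p1, p2)

    def test_variance_matches_permutation_oracle(self):
        """Analytic pair-count variance vs. explicit permutations, 12 nodes."""
        rng = np.random.default_rng(3)
        l1 = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3])
        l2 = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 0, 1, 2])
        n = len(l1)

        def pair_count(a, b):
            table = np.zeros((a.max() + 1, b.max() + 1))
            np.add.at(table, (a, b), 1)
            return (table * (table - 1) / 2).sum()

        draws = np.array(
            [pair_count(l1, l2[rng.permutation(n)]) for _ in range(40000)]
        )
        # reconstruct the analytic variance from the z-score definition
        m = n * (n - 1) / 2
        m1 = pair_count(l1, l1)
        m2 = pair_count(l2, l2)
        w = pair_count(l1, l2)
        z = zrand_from_labels(l1, l2)
        analytic_var = ((w - m1 * m2 / m) / z) ** 2
        assert analytic_var == pytest.approx(draws.var(ddof=1), rel=0.05)
        assert draws.mean() == pytest.approx(m1 * m2 / m, rel=0.02)


class TestLabelAgreement:
    def test_identical_partitions(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(20)]
        p = hn.Partition(labels=dict(zip(nodes, random_partition(rng, 20, 3))))
        assert hn.label_agreement(p, p) == 1.0

    def test_one_of_twenty_moved(self):
        nodes = [f"n{i:02d}" for i in range(20)]
        labels = {n: (1 if i < 10 else 2) for i, n in enumerate(nodes)}
        p1 = hn.Partition(labels=dict(labels))
        labels["n00"] = 2
        p2 = hn.Partition(labels=labels)
        assert hn.label_agreement(p1, p2) == pytest.approx(0.95)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_matching(self, seed):
        """Optimal community matching vs. brute force over assignments."""
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(30)]
        l1 = random_partition(rng, 30, 4)
        l2 = random_partition(rng, 30, 4)
        p1 = hn.Partition(labels=dict(zip(nodes, l1)))
        p2 = hn.Partition(labels=dict(zip(nodes, l2)))
        k1, k2 = len(np.unique(l1)), len(np.unique(l2))
        table = np.zeros((k1, k2))
        u1 = {v: i for i, v in enumerate(np.unique(l1))}
        u2 = {v: i for i, v in enumerate(np.unique(l2))}
        for a, b in zip(l1, l2):
            table[u1[a], u2[b]] += 1
        best = 0
        for perm in itertools.permutations(range(k2), min(k1, k2)):
            best = max(best, sum(table[i, j] for i, j in enumerate(perm) if i < k1))
        assert hn.label_agreement(p1, p2) == pytest.approx(best / 30)


class TestSweepAndSelect:
    def test_reference_grid_arithmetic(self):
        from hipponet.communities import WHOLE_BRAIN_GAMMA_GRID

        assert len(WHOLE_BRAIN_GAMMA_GRID) == 361
        assert WHOLE_BRAIN_GAMMA_GRID[0] == 1.0
        assert WHOLE_BRAIN_GAMMA_GRID[-1] == 2.8

    def test_unique_optimum_two_iterations(self):
        w = clique_pair()
        rec = sweep_gamma(fc_from_array(w), 1.0, 2, seed=0)
        assert np.array_equal(rec.partitions[0], rec.partitions[1])
        self_z = zrand_from_labels(rec.partitions[0], rec.partitions[0])
        assert rec.mean_zrand == pytest.approx([self_z, self_z])
        assert np.allclose(rec.weighted_score, rec.q_values * rec.mean_zrand)

    def test_no_passing_gamma_raises_with_reasons(self):
        w = clique_pair()
        fc = fc_from_array(w)
        # both seed sets live in the same clique -> same modal community
        crit = hn.SelectionCriteria(
            sensory_seed_sets={"visual": ["n0"], "auditory": ["n1"]}
        )
        with pytest.raises(SelectionError, match="visual and auditory"):
            hn.sweep_and_select(fc, [1.0], 4, crit, seed=0)

    def test_deterministic_given_seed(self):
        w = clique_pair()
        fc = fc_from_array(w)
        crit = hn.SelectionCriteria(require_separation=False)
        s1 = hn.sweep_and_select(fc, [0.8, 1.0], 4, crit, seed=9)
        s2 = hn.sweep_and_select(fc, [0.8, 1.0], 4, crit, seed=9)
        assert s1.chosen_gamma == s2.chosen_gamma
        assert s1.chosen_partition.labels == s2.chosen_partition.labels


class TestScorePeaks:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ([1.0, 2.0, 3.0], [2]),  # monotone rising -> right endpoint
            ([3.0, 2.0, 1.0], [0]),  # monotone falling -> left endpoint
            ([1.0, 3.0, 2.0, 4.0, 1.0], [1, 3]),
            ([2.0, 2.0, 2.0], [0]),  # flat -> argmax fallback
        ],
    )
    def test_peak_rule(self, scores, expected):
        assert score_peaks(np.array(scores)) == expected


class TestPartitionSubnetwork:
    def test_too_small_community_rejected(self):
        w = clique_pair()
        fc = fc_from_array(w)
        labels = {f"n{i}": (1 if i < 8 else 2) for i in range(10)}
        with pytest.raises(ValueError, match="need at least 3"):
            hn.partition_subnetwork(fc, hn.Partition(labels=labels), 2, [1.0], 4, seed=0)

    def test_all_zero_rows_reported(self):
        w = clique_pair()
        w[7, :] = 0.0
        w[:, 7] = 0.0
        fc = fc_from_array(w)
        labels = {f"n{i}": (1 if i < 5 else 2) for i in range(10)}
        with pytest.raises(ValueError, match="n7"):
            hn.partition_subnetwork(fc, hn.Partition(labels=labels), 2, [1.0], 4, seed=0)
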