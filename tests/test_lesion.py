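"""Shortest paths, virtual lesions, nulls, matched controls, participation."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import floyd_warshall

import hipponet as hn
from hipponet.lesion import (
    MatchingError,
    _length_graph,
    participation_from_dense,
    proportional_threshold,
)
from conftest import random_symmetric_nonnegative


def fc_from_array(w, prefix="n"):
    ids = [f"{prefix}{i}" for i in range(w.shape[0])]
    return hn.FCMatrix(node_ids=ids, values=np.asarray(w, float), nonnegative=True)


def chain_fc(weights):
    n = len(weights) + 1
    w = np.zeros((n, n))
    for i, wt in enumerate(weights):
        w[i, i + 1] = w[i + 1, i] = wt
    return fc_from_array(w)


class TestShortestPaths:
    def test_unit_chain(self):
        geo = hn.shortest_path_matrix(chain_fc([1.0, 1.0]))
        assert geo.values[0, 2] == pytest.approx(2.0)

    def test_half_weight_edge(self):
        geo = hn.shortest_path_matrix(chain_fc([0.5]))
        assert geo.values[0, 1] == pytest.approx(2.0)

    def test_zero_weight_is_no_edge(self):
        geo = hn.shortest_path_matrix(chain_fc([1.0, 0.0]))
        assert np.isinf(geo.values[0, 2])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_floyd_warshall(self, seed):
        rng = np.random.default_rng(seed)
        w = random_symmetric_nonnegative(rng, 8)
        w[w < 0.3] = 0.0  # sparsify so some pairs route indirectly
        geo = hn.shortest_path_matrix(fc_from_array(w))
        oracle = floyd_warshall(_length_graph(w), directed=False)
        assert np.allclose(geo.values, oracle, atol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetry_and_triangle_inequality(self, seed):
        rng = np.random.default_rng(10 + seed)
        w = random_symmetric_nonnegative(rng, 10)
        g = hn.shortest_path_matrix(fc_from_array(w)).values
        assert np.allclose(g, g.T, atol=1e-12)
        for i in range(10):
            for j in range(10):
                for k in range(10):
                    assert g[i, j] <= g[i, k] + g[k, j] + 1e-10

    @pytest.mark.parametrize("seed", range(3))
    def test_lesion_monotonicity(self, seed):
        """Removing nodes never shortens any remaining geodesic."""
        rng = np.random.default_rng(20 + seed)
        w = random_symmetric_nonnegative(rng, 12)
        fc = fc_from_array(w)
        full = hn.shortest_path_matrix(fc)
        removed = ["n0", "n5"]
        lesioned = hn.shortest_path_matrix(fc, removed=removed)
        idx_full = full.index_of(lesioned.node_ids)
        assert np.all(
            lesioned.values >= full.values[np.ix_(idx_full, idx_full)] - 1e-10
        )

    def test_negative_weights_rejected(self):
        w = np.array([[0.0, -1.0], [-1.0, 0.0]])
        fc = hn.FCMatrix(node_ids=["a", "b"], values=w)
        with pytest.raises(ValueError, match="nonnegative"):
            hn.shortest_path_matrix(fc)


class TestSetwisePathLength:
    def test_chain_endpoints(self):
        geo = hn.shortest_path_matrix(chain_fc([1.0, 1.0]))
        res = hn.setwise_path_length(geo, ["n0"], ["n2"])
        assert res.mean_length == pytest.approx(2.0)
        assert res.disconnected_fraction == 0.0

    def test_separate_components_fully_disconnected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        geo = hn.shortest_path_matrix(fc_from_array(w))
        res = hn.setwise_path_length(geo, ["n0", "n1"], ["n2", "n3"])
        assert res.disconnected_fraction == 1.0

    def test_matches_pairwise_average_oracle(self):
        rng = np.random.default_rng(1)
        w = random_symmetric_nonnegative(rng, 9)
        geo = hn.shortest_path_matrix(fc_from_array(w))
        a, b = ["n0", "n1", "n2"], ["n3", "n4", "n5", "n6"]
        res = hn.setwise_path_length(geo, a, b)
        vals = [geo.values[geo.index_of([u])[0], geo.index_of([v])[0]] for u in a for v in b]
        assert res.mean_length == pytest.approx(np.mean(vals), abs=1e-12)
        assert res.n_pairs == 12

    def test_empty_or_overlapping_sets_rejected(self):
        geo = hn.shortest_path_matrix(chain_fc([1.0, 1.0]))
        with pytest.raises(ValueError):
            hn.setwise_path_length(geo, [], ["n0"])
        with pytest.raises(ValueError):
            hn.setwise_path_length(geo, ["n0"], ["n0", "n1"])


def star_subjects(n_subjects=4, jitter=0.0):
    """Graphs where a-b traffic can route via hub h or detour d."""
    subs = []
    for s in range(n_subjects):
        w = np.zeros((5, 5))
        ids = ["a", "b", "h", "d", "x"]
        # direct-ish route via hub, weaker route via detour node
        w[0, 2] = w[2, 0] = 1.0 + jitter * s
        w[1, 2] = w[2, 1] = 1.0
        w[0, 3] = w[3, 0] = 0.2
        w[1, 3] = w[3, 1] = 0.2
        w[2, 4] = w[4, 2] = 0.5
        subs.append(hn.FCMatrix(node_ids=ids, values=w, subject_id=f"s{s}", nonnegative=True))
    return subs


class TestLesionCompare:
    def test_irrelevant_lesion_leaves_length_unchanged(self):
        subs = star_subjects(2, jitter=0.1)
        part = hn.Partition(labels={"a": 1, "b": 2, "h": 3, "d": 4, "x": 5})
        out = hn.lesion_compare(
            subs, part, ["a"], ["b"], {"hub": ["h"], "leaf": ["x"]}, focal="hub"
        )
        pl = out.path_lengths.pivot(index="subject", columns="removed_set", values="path_length")
        # removing the leaf x does not touch any a-b geodesic
        base = [1 / (1 + 0.1 * s) + 1.0 for s in range(2)]
        assert np.allclose(pl["leaf"].to_numpy(), base)
        # removing the hub forces the 0.2-weight detour
        assert np.allclose(pl["hub"].to_numpy(), 10.0)

    def test_zero_variance_flagged_not_crash(self, caplog):
        subs = star_subjects(3, jitter=0.0)  # identical subjects
        part = hn.Partition(labels={"a": 1, "b": 2, "h": 3, "d": 4, "x": 5})
        with caplog.at_level("WARNING", logger="hipponet"):
            out = hn.lesion_compare(
                subs, part, ["a"], ["b"], {"hub": ["h"], "leaf": ["x"]}, focal="hub"
            )
        assert np.isnan(out.comparisons["t"]).all()

    def test_candidate_overlapping_source_rejected(self):
        subs = star_subjects(2)
        part = hn.Partition(labels={"a": 1, "b": 2, "h": 3, "d": 4, "x": 5})
        with pytest.raises(ValueError, match="overlaps"):
            hn.lesion_compare(subs, part, ["a"], ["b"], {"bad": ["a", "h"]}, focal="bad")


class TestRandomRemovalNull:
    def test_pool_too_small_rejected(self):
        subs = star_subjects(2)
        with pytest.raises(ValueError, match="unprotected"):
            hn.random_removal_null(subs, ["a"], ["b"], ["h"], k=5, n_iter=10, seed=0)

    def test_seed_deterministic(self):
        rng = np.random.default_rng(0)
        w = random_symmetric_nonnegative(rng, 20)
        subs = [fc_from_array(w)]
        kw = dict(k=3, n_iter=50, seed=7)
        r1 = hn.random_removal_null(subs, ["n0"], ["n1"], ["n2"], **kw)
        r2 = hn.random_removal_null(subs, ["n0"], ["n1"], ["n2"], **kw)
        assert np.array_equal(r1.z_per_subject, r2.z_per_subject)

    def test_self_null_calibration(self):
        """A focal set drawn from the null's own distribution scores z ~ 0.

        Exchangeability makes E[z] exactly 0; 100 independent focal draws
        put the Monte-Carlo standard error well below the 0.15 bound.
        """
        rng = np.random.default_rng(1)
        zs = []
        for s in range(100):
            w = random_symmetric_nonnegative(rng, 30)
            w[w < 0.5] = 0.0
            subs = [fc_from_array(w)]
            focal = [f"n{i}" for i in rng.choice(np.arange(4, 30), 5, replace=False)]
            res = hn.random_removal_null(
                subs, ["n0", "n1"], ["n2", "n3"], focal, k=5, n_iter=200, seed=100 + s
            )
            zs.append(res.z_per_subject[0])
        assert abs(np.nanmean(zs)) < 0.15


class TestDistanceMatchedControls:
    def test_feasible_set_satisfies_constraints(self, node_table, truth):
        nets = truth.network_nodes
        refs = {"VIS": nets["VIS"], "DMN": nets["DMN"]}
        controls = hn.distance_matched_controls(
            node_table, nets["MTN"], refs, size=20, seed=0,
            candidates=node_table.cortical_ids,
        )
        assert len(controls) == 20
        assert not set(controls) & set(nets["MTN"])
        assert not set(controls) & set(nets["VIS"]) and not set(controls) & set(nets["DMN"])
        # constraint oracle: mean distance to each reference inside the band
        idx = node_table.frame.set_index("node_id")
        for ref_nodes in refs.values():
            ref_c = idx.loc[ref_nodes, ["x_mm", "y_mm", "z_mm"]].to_numpy()
            def mean_d(nodes):
                c = idx.loc[list(nodes), ["x_mm", "y_mm", "z_mm"]].to_numpy()
                return np.linalg.norm(c[:, None] - ref_c[None], axis=2).mean(axis=1)
            focal_d = mean_d(nets["MTN"])
            lo, hi = focal_d.mean() - focal_d.std(ddof=1), focal_d.mean() + focal_d.std(ddof=1)
            assert lo <= mean_d(controls).mean() <= hi

    def test_infeasible_reference_raises(self, node_table, truth):
        frame = node_table.frame.copy()
        # push the focal network unreachably far from everything else
        focal = truth.network_nodes["MTN"]
        frame.loc[frame.node_id.isin(focal), ["x_mm", "y_mm", "z_mm"]] += 10000.0
        far = hn.NodeTable(frame=frame)
        with pytest.raises(MatchingError):
            hn.distance_matched_controls(
                far, focal, {"VIS": truth.network_nodes["VIS"]}, size=20, seed=0,
                candidates=far.cortical_ids,
            )


class TestParticipation:
    def test_all_within_community_is_zero(self):
        w = clique = np.ones((4, 4))
        np.fill_diagonal(w, 0.0)
        fc = fc_from_array(w)
        p = hn.Partition(labels={f"n{i}": 1 for i in range(4)})
        res = hn.participation_coefficient(fc, p, densities=[1.0], strength_percentile_cut=0.0)
        assert np.allclose(res.pc_by_density.to_numpy(), 0.0)

    def test_even_split_two_communities(self):
        # node n0 has equal strength into communities {n1} and {n2}
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = 0.5
        fc = fc_from_array(w)
        p = hn.Partition(labels={"n0": 1, "n1": 1, "n2": 2})
        res = hn.participation_coefficient(fc, p, densities=[1.0], strength_percentile_cut=0.0)
        assert res.pc_by_density.loc["n0", 1.0] == pytest.approx(0.5)

    @pytest.mark.parametrize("density", [0.1, 0.5, 1.0])
    def test_matches_direct_formula_oracle(self, density):
        rng = np.random.default_rng(3)
        w = random_symmetric_nonnegative(rng, 20)
        labels = rng.integers(0, 4, size=20)
        wt = proportional_threshold(w, density)
        pc = participation_from_dense(wt, labels)
        for i in range(20):
            k_i = wt[i].sum()
            if k_i == 0:
                assert np.isnan(pc[i])
                continue
            acc = sum(
                (wt[i, labels == lab].sum() / k_i) ** 2 for lab in np.unique(labels)
            )
            assert pc[i] == pytest.approx(1.0 - acc, abs=1e-12)

    def test_threshold_keeps_exact_edge_count(self):
        rng = np.random.default_rng(4)
        w = random_symmetric_nonnegative(rng, 12)
        wt = proportional_threshold(w, 0.25)
        n_pairs = 12 * 11 // 2
        assert (wt[np.triu_indices(12, 1)] > 0).sum() == round(0.25 * n_pairs)
        kept = wt[wt > 0]
        assert np.all(np.isin(kept, w))  # weights retained, not binarized

    def test_global_rescale_invariance(self):
        rng = np.random.default_rng(5)
        w = random_symmetric_nonnegative(rng, 15)
        labels = rng.integers(0, 3, size=15)
        pc1 = participation_from_dense(w, labels)
        pc2 = participation_from_dense(7.5 * w, labels)
        assert np.allclose(pc1, pc2, atol=1e-12)

    def test_low_strength_nodes_excluded(self):
        rng = np.random.default_rng(6)
        w = random_symmetric_nonnegative(rng, 16)
        w[0, :] *= 0.01
        w[:, 0] *= 0.01
        np.fill_diagonal(w, 0.0)
        fc = fc_from_array(w)
        p = hn.Partition(labels={f"n{i}": i % 3 + 1 for i in range(16)})
        res = hn.participation_coefficient(fc, p, densities=[0.2])
        assert res.excluded_low_strength["n0"]
        assert np.isnan(res.pc_mean["n0"])

    def test_isolated_node_nan_at_density(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 0.9
        w[0, 4] = w[4, 0] = 0.1
        fc = fc_from_array(w)
        p = hn.Partition(labels={f"n{i}": 1 + i // 3 for i in range(5)})
        res = hn.participation_coefficient(
            fc, p, densities=[0.2], strength_percentile_cut=0.0
        )
        assert np.isnan(res.pc_by_density.loc["n4", 0.2])

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            proportional_threshold(np.zeros((3, 3)), 0.0)
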