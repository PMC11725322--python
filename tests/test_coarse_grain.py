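import numpy as np
import pytest
import scipy.sparse as sp

from metaspot.coarse_grain import (
    MergeTree,
    MetaspotPartition,
    aggregate,
    cut_tree,
    greedy_tree,
    load_tree,
    round_half_up,
    save_tree,
    walktrap_tree,
)
from metaspot.metaspot_graph import SpatialGraph
from metaspot.spatial_io import SpotMatrix

from oracles import best_two_partition, is_connected, modularity, pair_counting_ari


def graph_from(edge_weights, n):
    """SpatialGraph from {(u, v): weight}; unit spatial lengths."""
    edges = np.array(sorted(edge_weights))
    w = np.array([edge_weights[tuple(e)] for e in edges], dtype=float)
    return SpatialGraph(
        n_spots=n, edges=edges, length=np.ones(len(edges)), weight=w
    )


def two_cliques(k=4, bridge=0.01):
    """Two k-cliques with internal weight 1 joined by one weak edge."""
    ew = {}
    for base in (0, k):
        for i in range(k):
            for j in range(i + 1, k):
                ew[(base + i, base + j)] = 1.0
    ew[(k - 1, k)] = bridge
    return graph_from(ew, 2 * k)


def random_weighted_knn(seed, n=40, k=3):
    from metaspot.metaspot_graph import spatial_knn
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    g = spatial_knn(rng.uniform(0, 10, size=(n, 2)), k=k)
    return replace(g, weight=rng.uniform(0.01, 1.0, g.n_edges))


class TestWalktrap:
    def test_two_cliques_recovered_at_two_cluster_cut(self):
        g = two_cliques(k=4)
        part = cut_tree(walktrap_tree(g), gamma=4)  # 8 spots / 4 → 2 metaspots
        assert part.n_metaspots == 2
        expected = np.array([0] * 4 + [1] * 4)
        assert pair_counting_ari(part.membership, expected) == 1.0
        # exhaustive modularity oracle agrees with this split
        best, unique = best_two_partition(g.edges, g.weight, g.n_spots)
        assert unique
        assert pair_counting_ari(best, expected) == 1.0

    def test_igraph_cross_check_on_structured_graph(self):
        igraph = pytest.importorskip("igraph")
        g = two_cliques(k=4)
        ours = cut_tree(walktrap_tree(g, steps=4), gamma=4).membership
        G = igraph.Graph(n=g.n_spots, edges=[tuple(e) for e in g.edges])
        ref = G.community_walktrap(weights=list(g.weight), steps=4).as_clustering(2)
        assert pair_counting_ari(ours, ref.membership) == 1.0

    def test_edgeless_graph_all_singletons(self):
        g = SpatialGraph(n_spots=5, edges=np.empty((0, 2)), length=np.empty(0))
        tree = walktrap_tree(g)
        assert tree.merges == []
        part = cut_tree(tree, gamma=5)
        assert part.n_metaspots == 5

    def test_connected_graph_full_merge_count(self):
        g = random_weighted_knn(seed=0, n=10, k=3)
        assert len(walktrap_tree(g).merges) == 9

    def test_deterministic(self):
        g = random_weighted_knn(seed=1)
        assert walktrap_tree(g).merges == walktrap_tree(g).merges

    def test_zero_weight_edges_still_mergeable(self):
        # two nodes joined only by a weight-0 edge end up merged at γ = n
        ew = {(0, 1): 0.0, (1, 2): 1.0}
        g = graph_from(ew, 3)
        part = cut_tree(walktrap_tree(g), gamma=3)
        assert part.n_metaspots == 1


class TestGreedy:
    def test_two_triangles_recovered(self):
        ew = {}
        for base in (0, 3):
            for i in range(3):
                for j in range(i + 1, 3):
                    ew[(base + i, base + j)] = 1.0
        ew[(2, 3)] = 0.01
        g = graph_from(ew, 6)
        part = cut_tree(greedy_tree(g), gamma=3)
        assert part.n_metaspots == 2
        expected = np.array([0, 0, 0, 1, 1, 1])
        assert pair_counting_ari(part.membership, expected) == 1.0
        best, unique = best_two_partition(g.edges, g.weight, g.n_spots)
        assert unique and pair_counting_ari(best, expected) == 1.0

    def test_single_edge_one_merge(self):
        g = graph_from({(0, 1): 1.0}, 2)
        assert len(greedy_tree(g).merges) == 1

    def test_star_graph_full_agglomeration(self):
        ew = {(0, i): 1.0 for i in range(1, 5)}
        tree = greedy_tree(graph_from(ew, 5))
        assert len(tree.merges) == 4
        assert cut_tree(tree, gamma=5).n_metaspots == 1

    def test_matches_igraph_fastgreedy_exactly(self):
        """Our greedy agglomeration is the canonical CNM procedure: its
        2-cluster cut coincides with igraph's fastgreedy on random sparse
        weighted graphs."""
        igraph = pytest.importorskip("igraph")
        rng = np.random.default_rng(0)
        from metaspot.metaspot_graph import spatial_knn
        from dataclasses import replace

        checked = 0
        for _ in range(40):
            n = int(rng.integers(5, 9))
            g = spatial_knn(rng.uniform(0, 3, size=(n, 2)), k=2)
            G = igraph.Graph(n=n, edges=[tuple(e) for e in g.edges])
            w = rng.uniform(0.05, 1.0, g.n_edges)
            if not G.is_connected():
                continue
            gw = replace(g, weight=w)
            ours = cut_tree(greedy_tree(gw), gamma=n / 2).membership
            ref = G.community_fastgreedy(weights=list(w)).as_clustering(2)
            assert pair_counting_ari(ours, ref.membership) == 1.0
            checked += 1
        assert checked >= 25


class TestCutTree:
    def test_gamma_one_is_identity(self):
        g = random_weighted_knn(seed=2, n=20)
        part = cut_tree(walktrap_tree(g), gamma=1)
        assert part.n_metaspots == 20
        assert part.gamma_effective == 1.0

    def test_gamma_n_single_metaspot_when_connected(self):
        g = two_cliques()
        part = cut_tree(walktrap_tree(g), gamma=8)
        assert part.n_metaspots == 1

    def test_gamma_below_one_rejected(self):
        g = two_cliques()
        with pytest.raises(ValueError, match="gamma"):
            cut_tree(walktrap_tree(g), gamma=0.5)

    def test_round_half_up_rule(self):
        assert round_half_up(909.75) == 910
        assert round_half_up(2.5) == 3
        g = random_weighted_knn(seed=3, n=10, k=3)
        part = cut_tree(walktrap_tree(g), gamma=4)  # 10/4 = 2.5 → 3
        assert part.n_metaspots == 3

    def test_clamped_to_component_count(self, caplog):
        # two disconnected edges: γ = 4 would want 1 metaspot, graph has 2
        ew = {(0, 1): 1.0, (2, 3): 1.0}
        tree = walktrap_tree(graph_from(ew, 4))
        import logging

        with caplog.at_level(logging.WARNING, logger="metaspot.coarse_grain"):
            part = cut_tree(tree, gamma=4)
        assert part.n_metaspots == 2
        assert any("clamping" in r.message for r in caplog.records)

    def test_recut_does_not_modify_tree(self):
        g = random_weighted_knn(seed=4)
        tree = walktrap_tree(g)
        before = list(tree.merges)
        cut_tree(tree, gamma=2)
        cut_tree(tree, gamma=8)
        assert tree.merges == before

    @pytest.mark.parametrize("method", ["walktrap", "greedy"])
    def test_nesting_and_monotonicity_across_gamma(self, method):
        g = random_weighted_knn(seed=5, n=64, k=3)
        tree = walktrap_tree(g) if method == "walktrap" else greedy_tree(g)
        prev = None
        prev_n = np.inf
        for gamma in (1, 2, 4, 8, 16):
            part = cut_tree(tree, gamma)
            assert part.n_metaspots <= prev_n
            if prev is not None:
                # coarsening: spots sharing a metaspot at smaller γ still
                # share one at larger γ
                mapping = {}
                for s in range(part.n_spots):
                    key = prev.membership[s]
                    mapping.setdefault(key, part.membership[s])
                    assert mapping[key] == part.membership[s]
            prev, prev_n = part, part.n_metaspots

    @pytest.mark.parametrize("method", ["walktrap", "greedy"])
    def test_every_cut_spatially_connected(self, method):
        for seed in range(3):
            g = random_weighted_knn(seed=seed, n=50, k=3)
            tree = walktrap_tree(g) if method == "walktrap" else greedy_tree(g)
            edges = [tuple(e) for e in g.edges]
            for gamma in (2, 5, 10):
                part = cut_tree(tree, gamma)
                for members in part.members():
                    assert is_connected(members, edges)


class TestAggregate:
    def make_sm(self, counts, coords):
        counts = sp.csc_matrix(counts)
        return SpotMatrix(
            counts=counts,
            gene_ids=[f"g{i}" for i in range(counts.shape[0])],
            spot_ids=[f"s{i}" for i in range(counts.shape[1])],
            coords=coords,
        )

    def test_counts_sum_and_centroid(self):
        sm = self.make_sm(
            np.array([[1, 0], [0, 3], [2, 2]]), np.array([[0.0, 0], [2, 0]])
        )
        p = MetaspotPartition(membership=np.array([0, 0]), gamma_requested=2)
        msm = aggregate(sm, p)
        np.testing.assert_array_equal(msm.counts.toarray().ravel(), [1, 3, 4])
        np.testing.assert_allclose(msm.centroids[0], [1.0, 0.0])

    def test_three_member_centroid(self):
        sm = self.make_sm(
            np.ones((2, 3), dtype=int), np.array([[0.0, 0], [2, 0], [1, 3]])
        )
        p = MetaspotPartition(membership=np.array([0, 0, 0]), gamma_requested=3)
        msm = aggregate(sm, p)
        np.testing.assert_allclose(msm.centroids[0], [1.0, 1.0])
        assert msm.sizes.tolist() == [3]

    def test_count_conservation_random_fixture(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 8, size=(30, 40))
        sm = self.make_sm(counts, rng.uniform(0, 5, size=(40, 2)))
        p = MetaspotPartition.compact(rng.integers(0, 7, size=40), gamma_requested=1)
        msm = aggregate(sm, p)
        np.testing.assert_array_equal(
            np.asarray(msm.counts.sum(axis=1)).ravel(), counts.sum(axis=1)
        )
        assert msm.sizes.sum() == 40
        assert msm.counts.dtype == sm.counts.dtype

    def test_membership_mismatch_rejected(self):
        sm = self.make_sm(np.ones((2, 3), dtype=int), np.zeros((3, 2)))
        p = MetaspotPartition(membership=np.array([0, 1]), gamma_requested=1)
        with pytest.raises(ValueError, match="partition covers"):
            aggregate(sm, p)


class TestMergeTreeValidation:
    def test_double_merge_rejected(self):
        with pytest.raises(ValueError, match="twice"):
            MergeTree(n_leaves=3, merges=[(0, 1, 3), (0, 2, 4)])

    def test_save_load_round_trip(self, tmp_path):
        g = random_weighted_knn(seed=7, n=15)
        tree = greedy_tree(g)
        save_tree(tree, tmp_path / "t.json")
        back = load_tree(tmp_path / "t.json")
        assert back.merges == tree.merges
        assert back.method == "greedy"
        assert back.n_leaves == 15
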