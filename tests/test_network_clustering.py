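"""Correlation network construction, modularity, Louvain, centralities."""

import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from careflow.network_clustering import (
    CorrelationMatrix,
    Partition,
    WeightedNetwork,
    build_network,
    centralities,
    cluster_correlation_summary,
    correlation_matrix,
    heatmap_order,
    hierarchical_cluster,
    louvain_cluster,
    modularity,
    pearson_correlation,
)


def net_from_matrix(W):
    W = np.asarray(W, dtype=float)
    return WeightedNetwork(ids=list(range(len(W))), w=W)


def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [block + [first]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_best_q(net):
    n = len(net.ids)
    best = -np.inf
    for part in set_partitions(list(range(n))):
        labels = np.zeros(n, dtype=int)
        for k, block in enumerate(part):
            for i in block:
                labels[i] = k
        best = max(best, modularity(net, labels))
    return best


class TestPearson:
    def test_self_correlation(self):
        x = np.array([0.5, 0.25, 0.25] + [0.0] * 12)
        assert pearson_correlation(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_negative_affine_image(self):
        x = np.arange(15.0)
        assert pearson_correlation(x, -2.0 * x + 3.0) == pytest.approx(-1.0, abs=1e-12)

    def test_raw_sum_form_matches_covariance_form(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x, y = rng.random(15), rng.random(15)
            textbook = (
                ((x - x.mean()) * (y - y.mean())).sum()
                / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            )
            assert pearson_correlation(x, y) == pytest.approx(textbook, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation(np.ones(15), np.arange(15.0))


class TestBuildNetwork:
    def corr(self, c):
        C = np.array([[1.0, c], [c, 1.0]])
        return CorrelationMatrix(ids=["a", "b"], c=C)

    @pytest.mark.parametrize("c,w", [(0.0, 2.0), (-1.0, 1.0), (1.0, 3.0)])
    def test_offset_transform_endpoints(self, c, w):
        assert build_network(self.corr(c)).w[0, 1] == pytest.approx(w)

    def test_offset_at_most_one_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            build_network(self.corr(0.0), transform_offset=1.0)

    def test_complete_graph_no_cutoff(self):
        rng = np.random.default_rng(1)
        C = np.corrcoef(rng.random((6, 15)))
        net = build_network(CorrelationMatrix(list(range(6)), C))
        off = net.w[~np.eye(6, dtype=bool)]
        assert (off > 0).all()


class TestModularity:
    def random_net(self, seed, n=7):
        rng = np.random.default_rng(seed)
        C = np.corrcoef(rng.random((n, 12)))
        return build_network(CorrelationMatrix(list(range(n)), C))

    def test_all_in_one_is_exactly_zero(self):
        for seed in range(5):
            net = self.random_net(seed)
            assert modularity(net, np.zeros(len(net.ids), dtype=int)) == 0.0

    def test_singletons_closed_form(self):
        net = self.random_net(11)
        k = net.w.sum(axis=1)
        two_m = k.sum()
        expected = -(k**2).sum() / two_m**2
        got = modularity(net, np.arange(len(net.ids)))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_two_cliques_against_double_sum_oracle(self):
        W = np.zeros((6, 6))
        for block in ([0, 1, 2], [3, 4, 5]):
            for i, j in itertools.combinations(block, 2):
                W[i, j] = W[j, i] = 1.0
        W[2, 3] = W[3, 2] = 0.1
        net = net_from_matrix(W)
        labels = np.array([0, 0, 0, 1, 1, 1])
        k = W.sum(axis=1)
        two_m = k.sum()
        oracle = sum(
            (W[i, j] - k[i] * k[j] / two_m)
            for i in range(6) for j in range(6)
            if labels[i] == labels[j]
        ) / two_m
        assert modularity(net, labels) == pytest.approx(oracle, abs=1e-12)


class TestLouvain:
    def test_two_cliques_with_light_bridge(self):
        W = np.zeros((10, 10))
        for block in (range(5), range(5, 10)):
            for i, j in itertools.combinations(block, 2):
                W[i, j] = W[j, i] = 1.0
        W[4, 5] = W[5, 4] = 0.05
        net = net_from_matrix(W)
        part = louvain_cluster(net, seed=0)
        labels = part.labels_for(net.ids)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[9]
        assert part.q == pytest.approx(exhaustive_best_q(net), abs=1e-9)

    def test_determinism_under_same_seed(self):
        rng = np.random.default_rng(3)
        C = np.corrcoef(rng.random((12, 15)))
        net = build_network(CorrelationMatrix(list(range(12)), C))
        a = louvain_cluster(net, seed=7)
        b = louvain_cluster(net, seed=7)
        assert a.assignment == b.assignment and a.q == b.q

    def test_negative_weight_rejected(self):
        W = np.array([[0.0, -0.5], [-0.5, 0.0]])
        with pytest.raises(ValueError, match="positive"):
            louvain_cluster(net_from_matrix(W))

    def test_disconnected_graph_rejected(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        with pytest.raises(ValueError, match="connected"):
            louvain_cluster(net_from_matrix(W))

    def test_matches_exhaustive_optimum_on_small_correlation_networks(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            C = np.clip(np.corrcoef(rng.random((n, 6))), -1, 1)
            net = build_network(CorrelationMatrix(list(range(n)), C))
            part = louvain_cluster(net, seed=int(rng.integers(1 << 30)))
            assert part.q == pytest.approx(exhaustive_best_q(net), abs=1e-9)

    def test_label_equivariance_under_node_permutation(self):
        rng = np.random.default_rng(8)
        C = np.corrcoef(rng.random((9, 15)))
        net = build_network(CorrelationMatrix([f"n{i}" for i in range(9)], C))
        part = louvain_cluster(net, seed=5)
        perm = rng.permutation(9)
        ids2 = [net.ids[i] for i in perm]
        net2 = WeightedNetwork(ids=ids2, w=net.w[np.ix_(perm, perm)])
        part2 = louvain_cluster(net2, seed=5)
        groups1 = {frozenset(m) for m in part.communities().values()}
        groups2 = {frozenset(m) for m in part2.communities().values()}
        assert groups1 == groups2


class TestPlantedRecovery:
    def test_three_archetypes_recovered(self, planted_result):
        res = planted_result
        truth = res.truth.center_archetype
        labels_true = [truth[c] for c in res.network.ids]
        labels_got = [res.partition.assignment[c] for c in res.network.ids]
        assert res.partition.n_communities == 3
        assert adjusted_rand_score(labels_true, labels_got) >= 0.9

    def test_clustering_robust_to_weight_transforms(self, planted_result):
        res = planted_result
        base = res.partition.labels_for(res.network.ids)
        cases = {
            "affine_x100": (2.0, lambda w: w * 100.0),
            "square": (2.0, np.square),
            "cube": (2.0, lambda w: w**3),
            "offset3": (3.0, None),
        }
        for name, (offset, post) in cases.items():
            net = build_network(res.corr, offset, post)
            part = louvain_cluster(net, seed=11)
            ari = adjusted_rand_score(base, part.labels_for(net.ids))
            threshold = 1.0 if name == "affine_x100" else 0.9
            assert ari >= threshold, name

    def test_independent_louvain_implementation_agrees(self, planted_result):
        """Cross-check against networkx's Louvain on the same weighted graph."""
        res = planted_result
        G = res.network.to_networkx()
        comms = nx.algorithms.community.louvain_communities(G, weight="weight", seed=4)
        labels_nx = {n: k for k, c in enumerate(comms) for n in c}
        ari = adjusted_rand_score(
            [labels_nx[n] for n in res.network.ids],
            [res.partition.assignment[n] for n in res.network.ids],
        )
        assert ari >= 0.9


class TestHierarchy:
    def test_depth_capped_at_three(self, planted_result):
        assert [p.level for p in planted_result.partitions] == [1, 2, 3]

    def test_homogeneous_community_stays_whole(self):
        # uniform complete graph: no internal structure, Louvain keeps it as one
        W = np.full((6, 6), 2.0)
        np.fill_diagonal(W, 0.0)
        net = net_from_matrix(W)
        part = Partition(assignment={i: 0 for i in range(6)}, q=0.0)
        levels = hierarchical_cluster(net, part, max_depth=2)
        assert levels[1].n_communities == 1

    def test_nested_subarchetypes_split_at_level_two(self):
        # one level-1 block containing two planted sub-blocks
        W = np.full((8, 8), 1.2)
        for block in (range(4), range(4, 8)):
            for i, j in itertools.combinations(block, 2):
                W[i, j] = W[j, i] = 2.8
        np.fill_diagonal(W, 0.0)
        net = net_from_matrix(W)
        part = Partition(assignment={i: 0 for i in range(8)}, q=0.0)
        levels = hierarchical_cluster(net, part, max_depth=2)
        labels = levels[1].labels_for(net.ids)
        assert len(set(labels)) == 2
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1


class TestCentralities:
    def test_star_graph_hub_dominates(self):
        n = 6
        W = np.zeros((n, n))
        W[0, 1:] = W[1:, 0] = 1.0
        rep = centralities(net_from_matrix(W))
        df = rep.frame().set_index("node")
        assert df.loc[0, "degree"] == df["degree"].max()
        assert df.loc[0, "betweenness"] == df["betweenness"].max()
        assert (df.loc[1:, "betweenness"] == 0).all()

    def test_path_middle_node_betweenness(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 1.0
        rep = centralities(net_from_matrix(W))
        df = rep.frame().set_index("node")
        assert df.loc[1, "betweenness"] == pytest.approx(1.0)  # normalized

    def test_per_cluster_scopes_present(self, planted_result):
        rep = planted_result.centrality
        assert "network" in rep.scopes
        assert sum(s.startswith("cluster_") for s in rep.scopes) == 3
        for df in rep.scopes.values():
            assert df["degree_percentile"].between(0, 100).all()


class TestCorrelationSummaries:
    def test_identical_spectra_clusters_intra_one(self):
        C = np.ones((4, 4))
        corr = CorrelationMatrix(list(range(4)), C)
        part = Partition({0: 0, 1: 0, 2: 1, 3: 1}, 0.0)
        intra, inter = cluster_correlation_summary(corr, part)
        assert intra == {0: 1.0, 1: 1.0}

    def test_zero_matrix_all_zero(self):
        C = np.eye(4)
        corr = CorrelationMatrix(list(range(4)), C)
        part = Partition({0: 0, 1: 0, 2: 1, 3: 1}, 0.0)
        intra, inter = cluster_correlation_summary(corr, part)
        assert intra == {0: 0.0, 1: 0.0} and inter == {(0, 1): 0.0}

    def test_hand_matrix_against_enumeration(self):
        C = np.array(
            [[1.0, 0.6, -0.2, 0.1],
             [0.6, 1.0, 0.0, -0.4],
             [-0.2, 0.0, 1.0, 0.3],
             [0.1, -0.4, 0.3, 1.0]]
        )
        corr = CorrelationMatrix(["A", "B", "C", "D"], C)
        part = Partition({"A": 0, "B": 0, "C": 1, "D": 1}, 0.0)
        intra, inter = cluster_correlation_summary(corr, part)
        assert intra[0] == pytest.approx(0.6)
        assert intra[1] == pytest.approx(0.3)
        assert inter[(0, 1)] == pytest.approx(np.mean([-0.2, 0.1, 0.0, -0.4]))

    def test_singleton_cluster_intra_is_nan(self):
        corr = CorrelationMatrix(list(range(3)), np.eye(3))
        part = Partition({0: 0, 1: 0, 2: 1}, 0.0)
        intra, _ = cluster_correlation_summary(corr, part)
        assert np.isnan(intra[1])


class TestHeatmapOrder:
    def test_clusters_are_block_contiguous(self, planted_result):
        res = planted_result
        order = heatmap_order(res.corr, res.partition)
        labels = [res.partition.assignment[n] for n in order]
        changes = sum(a != b for a, b in zip(labels, labels[1:]))
        assert changes == res.partition.n_communities - 1

    def test_invariant_to_input_row_permutation(self, planted_result):
        res = planted_result
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(res.corr.ids))
        corr2 = CorrelationMatrix(
            [res.corr.ids[i] for i in perm], res.corr.c[np.ix_(perm, perm)]
        )
        assert heatmap_order(corr2, res.partition) == heatmap_order(res.corr, res.partition)

    def test_block_diagonal_dominance(self, planted_result):
        res = planted_result
        intra, inter = cluster_correlation_summary(res.corr, res.partition)
        assert min(intra.values()) > max(inter.values())


class TestProfileTransforms:
    def test_raw_transform_is_degenerate_under_dominant_share(self, planted_result):
        """On realistic spectra sharing a dominant component, raw-share
        correlations are uniformly near +1 — the reason deviation profiles are
        the default."""
        import pandas as pd
        from careflow.synthetic_registry import default_archetype_spectra
        from careflow.reference import SERIES_TYPES

        A = np.array(default_archetype_spectra())
        df = pd.DataFrame(A, columns=list(SERIES_TYPES))
        raw = correlation_matrix(df, transform="raw")
        off = raw.c[~np.eye(3, dtype=bool)]
        assert off.min() > 0.99

    def test_zscore_transform_separates_planted_styles(self, planted_result):
        intra, inter = cluster_correlation_summary(
            planted_result.corr, planted_result.partition
        )
        assert min(intra.values()) > 0
        assert max(inter.values()) < 0
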