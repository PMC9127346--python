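import numpy as np
import pytest

import oracles
from adeeg import (
    BrainNetwork,
    PLVMatrix,
    betweenness,
    characteristic_path_length,
    clustering_coefficient,
    compute_metrics,
    from_plv,
    global_efficiency,
    local_efficiency,
    network_feature_vector,
)


def _net(adj, labels=None):
    labels = labels or tuple(str(i) for i in range(adj.shape[0]))
    return BrainNetwork(np.asarray(adj, dtype=float), labels)


def complete_graph(n):
    a = np.ones((n, n))
    np.fill_diagonal(a, 0.0)
    return a


def star_graph(n):
    a = np.zeros((n, n))
    a[0, 1:] = a[1:, 0] = 1.0
    return a


@pytest.fixture(scope="module")
def two_branch_network():
    """Two parallel two-edge relay branches from a source to a sink."""
    adj = np.zeros((4, 4))
    for a, b in [(0, 1), (1, 2), (0, 3), (3, 2)]:
        adj[a, b] = adj[b, a] = 1.0
    return _net(adj, ("F1", "2", "F3", "4"))


class TestConstruction:
    def test_from_plv_zeroes_diagonal(self):
        plv = PLVMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), 100, ("A", "B"))
        net = from_plv(plv)
        assert net.adjacency[0, 0] == 0.0
        assert net.adjacency[0, 1] == 0.5

    def test_reciprocal_edge_length(self):
        plv = PLVMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), 100, ("A", "B"))
        net = from_plv(plv)
        assert net.path_lengths()[0, 1] == pytest.approx(2.0)

    def test_hop_count_mode(self):
        plv = PLVMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), 100, ("A", "B"))
        net = from_plv(plv, length_mode="hops")
        assert net.path_lengths()[0, 1] == pytest.approx(1.0)

    def test_path_lengths_match_exhaustive_enumeration(self, rng):
        for _ in range(10):
            adj = oracles.random_graph(rng, 5)
            net = _net(adj)
            expected = oracles.distance_matrix(adj)
            got = net.path_lengths()
            finite = np.isfinite(expected)
            assert np.array_equal(np.isfinite(got), finite)
            assert np.abs(got[finite] - expected[finite]).max() < 1e-12


class TestClustering:
    def test_complete_graph_is_one(self):
        net = _net(complete_graph(5))
        for node in net.node_labels:
            assert clustering_coefficient(net, node) == pytest.approx(1.0)

    def test_star_center_is_zero(self):
        net = _net(star_graph(5))
        assert clustering_coefficient(net, "0") == 0.0

    def test_matches_double_sum_oracle(self, rng):
        for _ in range(10):
            adj = oracles.random_graph(rng, 6)
            net = _net(adj)
            for i, node in enumerate(net.node_labels):
                assert clustering_coefficient(net, node) == pytest.approx(
                    oracles.clustering(adj, i), abs=1e-12
                )

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            clustering_coefficient(_net(complete_graph(3)), "zz")


class TestPathAndEfficiency:
    def test_complete_unit_graph(self):
        net = _net(complete_graph(6))
        assert characteristic_path_length(net) == pytest.approx(1.0)
        assert global_efficiency(net) == pytest.approx(1.0)
        for node in net.node_labels:
            assert local_efficiency(net, node) == pytest.approx(1.0)

    def test_three_node_path_graph_by_hand(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = 1.0
        # ordered pairs: 0-1:1, 0-2:2, 1-0:1, 1-2:1, 2-0:2, 2-1:1 -> 8/6
        assert characteristic_path_length(_net(adj)) == pytest.approx(4 / 3)

    def test_disconnected_graph_efficiency_zero(self):
        net = _net(np.zeros((4, 4)))
        assert global_efficiency(net) == 0.0
        assert characteristic_path_length(net) == np.inf

    def test_star_center_local_efficiency_zero(self):
        net = _net(star_graph(5))
        assert local_efficiency(net, "0") == 0.0

    def test_efficiency_at_least_reciprocal_path_length(self, rng):
        """Jensen: mean(1/L) >= 1/mean(L) on connected graphs."""
        checked = 0
        while checked < 100:
            adj = oracles.random_graph(rng, 5, zero_prob=0.1)
            net = _net(adj)
            if not np.all(np.isfinite(
                    net.path_lengths()[~np.eye(5, dtype=bool)])):
                continue
            assert global_efficiency(net) >= \
                1.0 / characteristic_path_length(net) - 1e-12
            checked += 1

    def test_matches_oracles_on_random_graphs(self, rng):
        for _ in range(10):
            adj = oracles.random_graph(rng, 6)
            net = _net(adj)
            assert characteristic_path_length(net) == pytest.approx(
                oracles.char_path_length(adj), abs=1e-12
            )
            assert global_efficiency(net) == pytest.approx(
                oracles.global_efficiency(adj), abs=1e-12
            )
            for i, node in enumerate(net.node_labels):
                assert local_efficiency(net, node) == pytest.approx(
                    oracles.local_efficiency(adj, i), abs=1e-12
                )


class TestBetweenness:
    def test_relay_node_on_path_graph(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = 1.0
        assert betweenness(_net(adj), "1") == pytest.approx(1.0)

    def test_star_closed_form(self):
        n = 6
        net = _net(star_graph(n))
        assert betweenness(net, "0") == pytest.approx((n - 1) * (n - 2) / 2)
        for leaf in net.node_labels[1:]:
            assert betweenness(net, leaf) == 0.0

    def test_two_branch_network_splits_traffic(self, two_branch_network):
        assert betweenness(two_branch_network, "2") == pytest.approx(0.5)
        assert betweenness(two_branch_network, "4") == pytest.approx(0.5)

    def test_worked_example_normalization(self, two_branch_network):
        """The relay node carries half of the source-sink traffic."""
        assert betweenness(two_branch_network, "2",
                           normalization="traffic_share") == pytest.approx(0.5)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(10):
            adj = oracles.random_graph(rng, 6)
            net = _net(adj)
            for i, node in enumerate(net.node_labels):
                assert betweenness(net, node) == pytest.approx(
                    oracles.betweenness(adj, i), abs=1e-12
                )


class TestFeatureVectorAndEquivariance:
    def test_layout_and_length(self, rng):
        adj = oracles.random_graph(rng, 4, zero_prob=0.0)
        vec = network_feature_vector(_net(adj))
        assert vec.shape == (3 * 4 + 2,)

    def test_complete_graph_composition(self):
        n = 5
        vec = network_feature_vector(_net(complete_graph(n)))
        expected = np.concatenate([np.ones(n), [1.0, 1.0], np.ones(n),
                                   np.zeros(n)])
        assert np.allclose(vec, expected)

    def test_node_relabeling_equivariance(self, rng):
        adj = oracles.random_graph(rng, 5, zero_prob=0.1)
        perm = rng.permutation(5)
        net = _net(adj)
        pnet = _net(adj[np.ix_(perm, perm)])
        m = compute_metrics(net)
        pm = compute_metrics(pnet)
        assert pm.char_path_length == pytest.approx(m.char_path_length,
                                                    abs=1e-12)
        assert pm.global_efficiency == pytest.approx(m.global_efficiency,
                                                     abs=1e-12)
        assert np.allclose(pm.clustering, m.clustering[perm], atol=1e-12)
        assert np.allclose(pm.betweenness, m.betweenness[perm], atol=1e-9)
        assert np.allclose(pm.local_efficiency, m.local_efficiency[perm],
                           atol=1e-12)
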