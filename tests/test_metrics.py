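"""Graph metrics on closed-form fixtures plus independent-oracle checks."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from netplast import (betweenness, char_path_length, clustering, degree,
                      global_efficiency, global_metrics, local_efficiency,
                      nodal_metrics, shortest_paths)
from conftest import (complete_graph, net_from_edges, path_graph, random_graph,
                      star_graph, two_triangles)


def brute_force_betweenness(net) -> np.ndarray:
    """Enumerate every shortest path of every pair explicitly (oracle)."""
    a = net.values
    n = a.shape[0]
    dist = shortest_paths(net)
    b = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(dist[s, t]):
            continue
        # depth-first enumeration of all geodesics from s to t
        paths = []
        stack = [(s, (s,))]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for w in np.flatnonzero(a[v]):
                if dist[s, w] == len(path) and dist[w, t] == dist[s, t] - len(path):
                    stack.append((w, path + (w,)))
        for path in paths:
            for v in path[1:-1]:
                b[v] += 1.0 / len(paths)
    return b


class TestClosedFormFixtures:
    def test_complete_graph(self):
        net = complete_graph(4)
        assert np.all(degree(net) == 3)
        assert np.all(clustering(net) == 1.0)
        pl = char_path_length(net)
        assert pl.network == pytest.approx(1.0)
        assert global_efficiency(net).network == pytest.approx(1.0)
        assert np.all(betweenness(net) == 0.0)

    def test_star_graph(self):
        net = star_graph(4)
        k = degree(net)
        assert k[0] == 4 and np.all(k[1:] == 1)
        assert np.all(clustering(net) == 0.0)
        assert betweenness(net)[0] == pytest.approx(6.0)  # C(4,2) leaf pairs
        assert np.all(betweenness(net)[1:] == 0.0)
        assert local_efficiency(net).network == 0.0

    def test_path_graph_three_nodes(self):
        net = path_graph(3)
        dist = shortest_paths(net)
        assert dist[0, 2] == 2
        pl = char_path_length(net)
        assert pl.per_node[1] == pytest.approx(1.0)
        assert pl.per_node[0] == pl.per_node[2] == pytest.approx(1.5)
        assert pl.network == pytest.approx(4.0 / 3.0)
        assert betweenness(net)[1] == pytest.approx(1.0)
        assert global_efficiency(net).network == pytest.approx((1 + 1 + 0.5) / 3)

    def test_k4_minus_edge_clustering(self):
        net = net_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)])
        c = clustering(net)
        assert c[0] == pytest.approx(2 / 3)
        assert c[1] == pytest.approx(2 / 3)
        assert c[2] == c[3] == pytest.approx(1.0)

    def test_triangle_and_disconnected_triangles_local_efficiency(self):
        tri = net_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert local_efficiency(tri).network == pytest.approx(1.0)
        assert local_efficiency(two_triangles()).network == pytest.approx(1.0)

    def test_disconnected_pairs_infinite_and_efficiency_zero(self):
        net = two_triangles()
        dist = shortest_paths(net)
        assert np.isinf(dist[0, 3])
        assert char_path_length(net).n_unreachable_pairs == 9
        empty = net_from_edges(3, [])
        assert global_efficiency(empty).network == 0.0
        assert np.isnan(char_path_length(empty).network)
        assert char_path_length(empty).has_isolated

    def test_empty_network_degrees(self):
        net = net_from_edges(4, [])
        assert np.all(degree(net) == 0)
        assert np.all(clustering(net) == 0.0)


class TestOracleAgreement:
    """Every metric must match networkx (and betweenness the brute-force
    all-paths enumeration) exactly on random small graphs."""

    def test_against_networkx_and_brute_force(self, small_graph_zoo):
        import networkx as nx

        for net in small_graph_zoo[:120]:
            g = nx.from_numpy_array(net.values)
            n = net.n_nodes
            assert np.array_equal(degree(net), [d for _, d in g.degree()])
            assert np.allclose(clustering(net),
                               [nx.clustering(g, i) for i in range(n)], atol=1e-12)
            # distances
            dist = shortest_paths(net)
            nx_dist = dict(nx.all_pairs_shortest_path_length(g))
            for i in range(n):
                for j in range(n):
                    expected = nx_dist[i].get(j, np.inf)
                    assert dist[i, j] == expected
            b = betweenness(net)
            nx_b = nx.betweenness_centrality(g, normalized=False)
            assert np.allclose(b, [nx_b[i] / 1.0 for i in range(n)], atol=1e-12)
            assert np.allclose(b, brute_force_betweenness(net), atol=1e-12)
            assert global_efficiency(net).network == pytest.approx(
                nx.global_efficiency(g), abs=1e-12)
            assert local_efficiency(net).network == pytest.approx(
                nx.local_efficiency(g), abs=1e-12)

    def test_char_path_length_matches_networkx_on_connected(self, small_graph_zoo):
        import networkx as nx

        for net in small_graph_zoo:
            g = nx.from_numpy_array(net.values)
            if net.n_nodes < 2 or not nx.is_connected(g):
                continue
            assert char_path_length(net).network == pytest.approx(
                nx.average_shortest_path_length(g), abs=1e-12)


class TestProperties:
    @given(seed=st.integers(0, 10_000))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        net = random_graph(rng, 7, 0.45)
        perm = rng.permutation(7)
        permuted = net.values[np.ix_(perm, perm)]
        from netplast import BinaryNetwork
        nm1 = nodal_metrics(net)
        nm2 = nodal_metrics(BinaryNetwork(permuted))
        for name, v in nm1.as_dict().items():
            assert np.allclose(np.asarray(v, dtype=float)[perm],
                               nm2.as_dict()[name], atol=1e-12, equal_nan=True), name

    @given(seed=st.integers(0, 10_000))
    def test_bounds(self, seed):
        rng = np.random.default_rng(seed)
        net = random_graph(rng, 8, rng.random())
        n = net.n_nodes
        assert np.all((clustering(net) >= 0) & (clustering(net) <= 1))
        assert 0 <= global_efficiency(net).network <= 1
        assert 0 <= local_efficiency(net).network <= 1
        assert np.all(betweenness(net) <= (n - 1) * (n - 2) / 2 + 1e-12)

    @given(seed=st.integers(0, 10_000))
    def test_adding_edge_never_increases_distances(self, seed):
        rng = np.random.default_rng(seed)
        net = random_graph(rng, 8, 0.3)
        a = net.values.copy()
        absent = np.argwhere(np.triu(a == 0, 1))
        if absent.size == 0:
            return
        i, j = absent[rng.integers(len(absent))]
        before = shortest_paths(net)
        a[i, j] = a[j, i] = 1
        after = shortest_paths(a)
        assert np.all(after <= before + 1e-12)

    def test_global_metrics_consistency(self):
        rng = np.random.default_rng(11)
        net = random_graph(rng, 20, 0.2)
        gm = global_metrics(net)
        assert gm.mean_degree == pytest.approx(degree(net).mean())
        assert gm.n_edges == net.n_edges
        assert gm.mean_clustering == pytest.approx(clustering(net).mean())
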