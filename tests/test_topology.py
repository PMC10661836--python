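"""Topology statistics: closed-form examples and networkx oracle equivalence.

networkx is used strictly as the independent oracle; the implementation
under test computes every statistic from its own BFS/Brandes machinery.
"""

import math
import random

import networkx as nx
import pytest

from keynet import (
    ScoredEdge,
    ScoredNetwork,
    betweenness,
    closeness,
    degree,
    local_clustering,
    network_topology,
)

from conftest import complete_graph, net_from_edges, star_graph


class TestNodeStatistics:
    def test_degree_star_center(self):
        star = star_graph(4)
        assert degree(star, "HUB") == 4
        assert degree(star, "L0") == 1

    def test_degree_complete_graph(self):
        k5 = complete_graph(5)
        assert all(degree(k5, v) == 4 for v in k5.nodes)

    def test_degree_isolated_node(self):
        net = ScoredNetwork("iso", nodes=["A"])
        assert degree(net, "A") == 0

    def test_degree_unknown_node_errors(self, path3):
        with pytest.raises(KeyError):
            degree(path3, "Z")

    def test_closeness_path(self, path3):
        assert closeness(path3, "B") == 1.0
        assert closeness(path3, "A") == pytest.approx(1 / 1.5)

    def test_closeness_complete(self):
        k4 = complete_graph(4)
        assert all(closeness(k4, v) == 1.0 for v in k4.nodes)

    def test_closeness_isolated_zero(self):
        net = net_from_edges([("A", "B")], nodes=["C"])
        assert closeness(net, "C") == 0.0

    def test_betweenness_path_center(self, path3):
        assert betweenness(path3, "B") == pytest.approx(1.0)

    def test_betweenness_tree_leaf_zero(self):
        tree = net_from_edges([("R", "A"), ("R", "B"), ("A", "C")])
        assert betweenness(tree, "C") == 0.0
        assert betweenness(tree, "B") == 0.0

    def test_betweenness_complete_zero(self):
        k5 = complete_graph(5)
        bc = betweenness(k5)
        assert all(v == 0.0 for v in bc.values())

    def test_local_clustering_triangle_vs_path(self):
        tri = net_from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        assert local_clustering(tri, "A") == 1.0
        path = net_from_edges([("A", "B"), ("B", "C")])
        assert local_clustering(path, "B") == 0.0


class TestNetworkTopology:
    def test_complete_graph_k5(self):
        rep = network_topology(complete_graph(5))
        assert rep.avg_neighbors == 4.0
        assert rep.density == 1.0
        assert rep.char_path_length == 1.0
        assert rep.heterogeneity == 0.0
        assert rep.centralization == 0.0
        assert rep.clustering_coefficient == 1.0

    def test_near_complete_k10_minus_edge(self):
        """Dense 10-node graph: density 44/45, path length 46/45, CV(degree) ~0.05."""
        net = complete_graph(10)
        full = ScoredNetwork("k10m1", nodes=net.nodes)
        edges = net.edges
        for e in edges[1:]:
            full.add_edge(ScoredEdge(e.a, e.b, e.combined))
        rep = network_topology(full)
        assert rep.n_edges_undirected == 44
        assert rep.avg_neighbors == pytest.approx(8.8)
        assert rep.density == pytest.approx(44 / 45)
        assert round(rep.density, 2) == 0.98
        assert rep.char_path_length == pytest.approx(46 / 45)
        assert round(rep.char_path_length, 2) == 1.02
        assert round(rep.heterogeneity, 2) == 0.05
        assert round(rep.centralization, 2) == 0.03

    def test_six_node_seven_edge_bridged_triangles(self):
        """Degree sequence (3,3,2,2,2,2): density 0.47, CV 0.20, centralization 0.20."""
        net = net_from_edges(
            [("B", "G"), ("B", "R"), ("G", "R"),
             ("O", "C"), ("C", "S"), ("O", "S"),
             ("B", "S")]
        )
        rep = network_topology(net)
        assert sorted(net.degrees().values(), reverse=True) == [3, 3, 2, 2, 2, 2]
        assert round(rep.avg_neighbors, 1) == 2.3
        assert rep.density == pytest.approx(7 / 15)
        assert round(rep.density, 2) == 0.47
        assert round(rep.heterogeneity, 2) == 0.20
        assert rep.centralization == pytest.approx(0.20)
        assert rep.char_path_length == pytest.approx(27 / 15)

    def test_star_heterogeneity_and_centralization(self):
        rep = network_topology(star_graph(4))
        # degrees (4,1,1,1,1): mean 1.6, population variance 1.44
        assert rep.heterogeneity == pytest.approx(math.sqrt(1.44) / 1.6)
        assert rep.heterogeneity == pytest.approx(0.75)
        assert rep.centralization == pytest.approx(1.0)

    def test_disconnected_flagged_and_paths_over_connected_pairs(self):
        net = net_from_edges([("A", "B"), ("C", "D")])
        rep = network_topology(net)
        assert not rep.connected
        assert rep.char_path_length == 1.0
        assert rep.diameter == 1

    def test_single_node(self):
        rep = network_topology(ScoredNetwork("one", nodes=["A"]))
        assert rep.n_nodes == 1
        assert rep.centralization == 0.0
        assert rep.char_path_length == 0.0


# ---------------------------------------------------------------------------
# oracle equivalence on random connected graphs
# ---------------------------------------------------------------------------

def _random_connected(seed, n_max=8):
    rnd = random.Random(seed)
    n = rnd.randint(3, n_max)
    g = nx.gnp_random_graph(n, rnd.uniform(0.3, 0.9), seed=seed)
    while not nx.is_connected(g) or g.number_of_edges() == 0:
        seed += 1000
        g = nx.gnp_random_graph(n, rnd.uniform(0.3, 0.9), seed=seed)
    net = ScoredNetwork(f"rnd{seed}", nodes=[f"V{i}" for i in g.nodes])
    for u, v in g.edges:
        net.add_edge(ScoredEdge(f"V{u}", f"V{v}", 900))
    return net, nx.relabel_nodes(g, {i: f"V{i}" for i in g.nodes})


@pytest.mark.parametrize("seed", range(30))
def test_centrality_oracle_equivalence(seed):
    """Closeness, betweenness, path length and diameter match networkx to 1e-9."""
    net, g = _random_connected(seed)
    nx_close = nx.closeness_centrality(g)
    nx_betw = nx.betweenness_centrality(g, normalized=True)
    bc = betweenness(net)
    for v in net.nodes:
        assert closeness(net, v) == pytest.approx(nx_close[v], abs=1e-9)
        assert bc[v] == pytest.approx(nx_betw[v], abs=1e-9)
        assert local_clustering(net, v) == pytest.approx(nx.clustering(g, v), abs=1e-9)
    rep = network_topology(net)
    assert rep.char_path_length == pytest.approx(nx.average_shortest_path_length(g), abs=1e-9)
    assert rep.diameter == nx.diameter(g)
    assert rep.clustering_coefficient == pytest.approx(nx.average_clustering(g), abs=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_label_permutation_invariance(seed):
    """Relabeling nodes leaves every whole-network statistic unchanged."""
    net, _ = _random_connected(seed)
    rnd = random.Random(seed + 1)
    perm = net.nodes[:]
    rnd.shuffle(perm)
    mapping = dict(zip(net.nodes, perm))
    relabeled = ScoredNetwork("perm", nodes=perm)
    for e in net.edges:
        relabeled.add_edge(ScoredEdge(mapping[e.a], mapping[e.b], e.combined))
    a, b = network_topology(net), network_topology(relabeled)
    for field in ("n_nodes", "n_edges_undirected", "avg_neighbors", "density",
                  "diameter", "char_path_length", "clustering_coefficient",
                  "heterogeneity", "centralization"):
        assert getattr(a, field) == pytest.approx(getattr(b, field), abs=1e-12)


@pytest.mark.parametrize("n", [3, 4, 6])
def test_regular_and_extremal_invariants(n):
    """Regular graphs: CV 0; complete: centralization 0 and path length 1; star: 1."""
    cycle = net_from_edges([(f"C{i}", f"C{(i + 1) % n}") for i in range(n)])
    assert network_topology(cycle).heterogeneity == 0.0
    comp = network_topology(complete_graph(n))
    assert comp.centralization == 0.0
    assert comp.char_path_length == 1.0
    assert network_topology(star_graph(n)).centralization == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(8))
def test_unit_path_length_iff_complete(seed):
    net, g = _random_connected(seed)
    rep = network_topology(net)
    n = rep.n_nodes
    is_complete = rep.n_edges_undirected == n * (n - 1) // 2
    assert (rep.char_path_length == 1.0) == is_complete
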