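"""Co-occurrence networks and the 16 structural metrics."""

import itertools
import random

import networkx as nx
import numpy as np
import pytest

import oracles as O
from psynet.cohort import Cohort, Outcome
from psynet.network import (
    EDGE_METRICS,
    METRICS,
    CooccurrenceNetwork,
    UnknownMetricError,
    build_network,
    compute_metric,
    edge_metric_node_means,
    shared_characteristics,
)


def _net_from_graph(G, outcome="IMPV", group_size=100):
    for u, v in G.edges:
        G.edges[u, v].setdefault("weight", 1.0)
    return CooccurrenceNetwork(outcome, G, group_size)


def oracle_values(nodes, edges, weights, metric):
    adj = O.adjacency(nodes, edges)
    if metric == "average_neighbor_degree":
        return O.bf_average_neighbor_degree(adj)
    if metric == "degree_centrality":
        return O.bf_degree_centrality(adj)
    if metric == "closeness_centrality":
        return O.bf_closeness(nodes, edges)
    if metric == "betweenness_centrality":
        return O.bf_betweenness(nodes, edges)
    if metric == "edge_betweenness_centrality":
        return O.bf_edge_betweenness(nodes, edges)
    if metric == "number_of_cliques":
        return O.bf_clique_metrics(adj)[0]
    if metric == "node_clique_number":
        return O.bf_clique_metrics(adj)[1]
    if metric == "triangles":
        return O.bf_triangles(adj)
    if metric == "clustering":
        return O.bf_clustering(adj)
    if metric == "all_pairs_node_connectivity":
        return O.bf_node_connectivity_mean(adj)
    if metric == "closeness_vitality":
        return O.bf_closeness_vitality(nodes, edges, weights)
    if metric == "square_clustering":
        return O.bf_square_clustering(adj)
    if metric == "edge_load":
        return O.bf_edge_load(nodes, edges)
    if metric == "effective_size":
        return O.bf_effective_size(adj)
    if metric == "constraint":
        return O.bf_constraint(adj)
    if metric == "edge_weight":
        return dict(weights)
    raise AssertionError(metric)


def random_small_graph(rng, nprng):
    n = rng.randint(3, 8)
    p = rng.choice([0.25, 0.4, 0.6, 0.8])
    nodes = [f"n{i}" for i in range(n)]
    edges = [
        tuple(sorted(e))
        for e in itertools.combinations(nodes, 2)
        if rng.random() < p
    ]
    weights = {e: round(float(nprng.uniform(0.1, 1.0)), 3) for e in edges}
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for u, v in edges:
        G.add_edge(u, v, weight=weights[(u, v)])
    return nodes, edges, weights, G


class TestSharedCharacteristics:
    def test_only_both_group_expression_included(self, labeled_cohort):
        # A: both groups; B: IMPV only; C: both; D: MC only
        assert shared_characteristics(labeled_cohort) == {"A", "C"}


class TestBuildNetwork:
    def test_hand_counted_weights(self, small_catalog, rec_factory):
        sets = [{"A", "B"}, {"A", "B", "C"}, {"A", "C"}, {"B"}]
        records = tuple(rec_factory(f"k{i}", s) for i, s in enumerate(sets))
        records += (rec_factory("m0", {"A", "B", "C"}),)
        labels = {f"k{i}": Outcome.IMPV for i in range(4)}
        labels["m0"] = Outcome.MC
        cohort = Cohort(small_catalog, records, labels)
        net = build_network(cohort, "IMPV", {"A", "B", "C"})
        w = {tuple(sorted((u, v))): wt for u, v, wt in net.edges}
        assert w == {("A", "B"): 0.5, ("A", "C"): 0.5, ("B", "C"): 0.25}

    def test_singleton_child_contributes_no_edges(self, small_catalog, rec_factory):
        records = (rec_factory("k0", {"A"}), rec_factory("m0", {"A"}))
        labels = {"k0": Outcome.IMPV, "m0": Outcome.MC}
        cohort = Cohort(small_catalog, records, labels)
        net = build_network(cohort, "IMPV", {"A"})
        assert net.graph.number_of_edges() == 0
        assert "A" in net.nodes  # isolated node retained


class TestMetricClosedForms:
    def test_complete_graph_k5(self):
        net = _net_from_graph(nx.complete_graph(5))
        assert set(compute_metric(net, "triangles").values.values()) == {6.0}
        assert set(compute_metric(net, "clustering").values.values()) == {1.0}
        assert set(compute_metric(net, "number_of_cliques").values.values()) == {1.0}
        assert set(compute_metric(net, "node_clique_number").values.values()) == {5.0}

    def test_path_p3_center(self):
        net = _net_from_graph(nx.path_graph(3))
        assert compute_metric(net, "clustering").values[1] == 0.0
        assert compute_metric(net, "triangles").values[1] == 0.0
        assert compute_metric(net, "degree_centrality").values[1] == pytest.approx(1.0)
        assert compute_metric(net, "betweenness_centrality").values[1] == pytest.approx(1.0)

    def test_star_k14_center(self):
        net = _net_from_graph(nx.star_graph(4))
        assert compute_metric(net, "node_clique_number").values[0] == 2.0
        assert compute_metric(net, "number_of_cliques").values[0] == 4.0

    def test_unknown_metric_rejected(self):
        net = _net_from_graph(nx.path_graph(3))
        with pytest.raises(UnknownMetricError):
            compute_metric(net, "pagerank")


class TestMetricOracles:
    @pytest.mark.parametrize("metric", METRICS)
    def test_small_random_graphs_match_brute_force(self, metric):
        rng = random.Random(99)
        nprng = np.random.default_rng(99)
        for _ in range(8):
            nodes, edges, weights, G = random_small_graph(rng, nprng)
            net = _net_from_graph(G)
            got = compute_metric(net, metric).values
            exp = oracle_values(nodes, edges, weights, metric)
            assert set(got) == set(exp)
            for k in got:
                assert got[k] == pytest.approx(exp[k], abs=1e-8), (metric, k)


class TestMetricProperties:
    def test_relabeling_invariance(self):
        rng = random.Random(3)
        nprng = np.random.default_rng(3)
        nodes, edges, weights, G = random_small_graph(rng, nprng)
        mapping = {n: f"z{i}" for i, n in enumerate(reversed(nodes))}
        H = nx.relabel_nodes(G, mapping)
        for metric in METRICS:
            a = compute_metric(_net_from_graph(G), metric).values
            b = compute_metric(_net_from_graph(H), metric).values
            if metric in EDGE_METRICS:
                remapped = {
                    tuple(sorted((mapping[u], mapping[v]))): val
                    for (u, v), val in a.items()
                }
            else:
                remapped = {mapping[k]: val for k, val in a.items()}
            for k in b:
                assert b[k] == pytest.approx(remapped[k], abs=1e-8), metric

    def test_triangle_sum_divisible_by_three(self, default_cohort):
        cohort, _ = default_cohort
        shared = shared_characteristics(cohort)
        net = build_network(cohort, "IMPV", shared)
        tri = compute_metric(net, "triangles").values
        assert int(sum(tri.values())) % 3 == 0

    def test_edge_weight_metric_equals_build_weights(self, default_cohort):
        cohort, _ = default_cohort
        shared = shared_characteristics(cohort)
        net = build_network(cohort, "MC", shared)
        dist = compute_metric(net, "edge_weight").values
        for u, v, w in net.edges:
            assert dist[tuple(sorted((u, v)))] == w

    def test_edge_metric_node_means(self):
        net = _net_from_graph(nx.path_graph(3))
        dist = compute_metric(net, "edge_weight")
        means = edge_metric_node_means(dist, net)
        assert means.kind == "node"
        assert set(means.values) == {0, 1, 2}
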