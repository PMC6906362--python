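"""Per-outcome co-occurrence networks and node-level structural metrics.

Nodes are the characteristics expressed in *both* outcome groups
(restricting to shared characteristics avoids biasing either network
with traits seen only once in the sample). An edge joins two
characteristics that co-occur within at least one child of the group,
weighted by the proportion of the group's children expressing both.

Sixteen metrics spanning connectivity, associativity and clustering are
computed at the node level (or per edge for the three edge-valued
metrics). Topological metrics use the unweighted skeleton; only
``edge_weight`` and ``closeness_vitality`` use the weights.

Conventions on disconnected graphs:

- closeness_centrality: computed within the reachable set and rescaled
  by its relative size (Wasserman-Faust).
- all_pairs_node_connectivity: unreachable pairs contribute 0; the
  per-node value is the mean connectivity to all other nodes.
- closeness_vitality: Wiener index restricted to reachable (finite)
  pairs, so the value stays finite when removing a cut vertex.
- number_of_cliques / node_clique_number: an isolated node forms its
  own maximal clique of size 1.
- effective_size / constraint: Burt's measures; isolated nodes get 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import Cohort, CohortValidationError, Outcome

METRICS = (
    "average_neighbor_degree",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "edge_betweenness_centrality",
    "number_of_cliques",
    "node_clique_number",
    "triangles",
    "clustering",
    "all_pairs_node_connectivity",
    "closeness_vitality",
    "square_clustering",
    "edge_load",
    "effective_size",
    "constraint",
    "edge_weight",
)

EDGE_METRICS = ("edge_betweenness_centrality", "edge_load", "edge_weight")


class UnknownMetricError(ValueError):
    pass


@dataclass(frozen=True)
class CooccurrenceNetwork:
    outcome: str  # "IMPV" or "MC"
    graph: nx.Graph  # nodes = shared characteristics; 'weight' edge attr
    group_size: int

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]


@dataclass(frozen=True)
class MetricDistribution:
    metric: str
    outcome: str
    values: dict  # node -> value, or (u, v) edge -> value
    kind: str  # "node" or "edge"

    def as_array(self) -> np.ndarray:
        return np.asarray(list(self.values.values()), dtype=float)


def shared_characteristics(cohort: Cohort) -> set[str]:
    """Ids expressed by at least one child in each outcome group."""
    if cohort.outcome_labels is None:
        raise CohortValidationError("shared characteristics require a labeled cohort")
    seen = {"IMPV": set(), "MC": set()}
    for r in cohort.records:
        seen[cohort.outcome_labels[r.child_id].value] |= r.characteristics
    if not any(seen.values()):
        return set()
    return seen["IMPV"] & seen["MC"]


def build_network(cohort: Cohort, outcome: Outcome | str, shared: set[str]) -> CooccurrenceNetwork:
    """Weighted co-occurrence graph over ``shared`` for one outcome group.

    Isolated shared characteristics are retained as nodes.
    """
    if not shared:
        raise CohortValidationError("shared characteristic set is empty")
    outcome = Outcome(outcome)
    members = [
        r for r in cohort.records if cohort.outcome_labels[r.child_id] is outcome
    ]
    n = len(members)
    if n == 0:
        raise CohortValidationError(f"outcome group {outcome.value} is empty")
    G = nx.Graph()
    # deterministic node order: catalog order restricted to shared
    G.add_nodes_from(c for c in cohort.catalog.ids if c in shared)
    pair_counts: dict[tuple[str, str], int] = {}
    for r in members:
        chars = sorted(r.characteristics & shared)
        for i in range(len(chars)):
            for j in range(i + 1, len(chars)):
                pair_counts[(chars[i], chars[j])] = pair_counts.get((chars[i], chars[j]), 0) + 1
    for (u, v), k in pair_counts.items():
        G.add_edge(u, v, weight=k / n)
    return CooccurrenceNetwork(outcome.value, G, n)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _canonical_edges(G: nx.Graph, values: dict) -> dict:
    """Collapse directed edge keys to sorted unordered pairs."""
    out = {}
    for (u, v), val in values.items():
        out[tuple(sorted((u, v)))] = val
    return out


def _finite_wiener(G: nx.Graph, weight: str | None) -> float:
    """Sum of shortest-path distances over reachable unordered pairs."""
    total = 0.0
    for _, dists in nx.all_pairs_dijkstra_path_length(G, weight=weight):
        total += sum(dists.values())
    return total / 2.0


def _closeness_vitality(G: nx.Graph) -> dict:
    """Weighted Wiener-index drop when a node is removed.

    Restricted to finite pairs so the value is defined at cut vertices.
    """
    base = _finite_wiener(G, "weight")
    out = {}
    for v in G.nodes:
        H = G.copy()
        H.remove_node(v)
        out[v] = base - _finite_wiener(H, "weight")
    return out


def _clique_metrics(G: nx.Graph) -> tuple[dict, dict]:
    n_cliques = {v: 0 for v in G.nodes}
    clique_num = {v: 0 for v in G.nodes}
    for clique in nx.find_cliques(G):
        for v in clique:
            n_cliques[v] += 1
            clique_num[v] = max(clique_num[v], len(clique))
    return n_cliques, clique_num


def compute_metric(net: CooccurrenceNetwork, metric: str) -> MetricDistribution:
    """One of the 16 structural metrics as a per-node (or per-edge)
    distribution on this network."""
    if metric not in METRICS:
        raise UnknownMetricError(f"unknown metric {metric!r}; expected one of {METRICS}")
    G = net.graph
    kind = "edge" if metric in EDGE_METRICS else "node"
    if metric == "average_neighbor_degree":
        values = nx.average_neighbor_degree(G)
    elif metric == "degree_centrality":
        values = nx.degree_centrality(G)
    elif metric == "closeness_centrality":
        values = nx.closeness_centrality(G)
    elif metric == "betweenness_centrality":
        values = nx.betweenness_centrality(G, normalized=True)
    elif metric == "edge_betweenness_centrality":
        values = _canonical_edges(G, nx.edge_betweenness_centrality(G, normalized=True))
    elif metric == "number_of_cliques":
        values = _clique_metrics(G)[0]
    elif metric == "node_clique_number":
        values = _clique_metrics(G)[1]
    elif metric == "triangles":
        values = nx.triangles(G)
    elif metric == "clustering":
        values = nx.clustering(G)
    elif metric == "all_pairs_node_connectivity":
        from networkx.algorithms.connectivity import all_pairs_node_connectivity

        conn = all_pairs_node_connectivity(G)
        n = G.number_of_nodes()
        values = {
            v: (sum(conn[v].values()) / (n - 1) if n > 1 else 0.0) for v in G.nodes
        }
    elif metric == "closeness_vitality":
        values = _closeness_vitality(G)
    elif metric == "square_clustering":
        values = nx.square_clustering(G)
    elif metric == "edge_load":
        raw = nx.edge_load_centrality(G)
        # nx reports each direction; keep one entry per unordered edge
        values = {tuple(sorted((u, v))): raw[(u, v)] for u, v in G.edges}
    elif metric == "effective_size":
        H = nx.Graph()  # strip weights: Burt measures on the skeleton
        H.add_nodes_from(G.nodes)
        H.add_edges_from(G.edges)
        values = {v: (0.0 if np.isnan(x) else float(x)) for v, x in nx.effective_size(H).items()}
    elif metric == "constraint":
        H = nx.Graph()
        H.add_nodes_from(G.nodes)
        H.add_edges_from(G.edges)
        values = {v: (0.0 if np.isnan(x) else float(x)) for v, x in nx.constraint(H).items()}
    elif metric == "edge_weight":
        values = {tuple(sorted((u, v))): d["weight"] for u, v, d in G.edges(data=True)}
    values = {k: float(v) for k, v in values.items()}
    if not all(np.isfinite(list(values.values()))):
        raise ValueError(f"metric {metric} produced non-finite values")
    return MetricDistribution(metric, net.outcome, values, kind)


def compute_all_metrics(net: CooccurrenceNetwork) -> dict[str, MetricDistribution]:
    return {m: compute_metric(net, m) for m in METRICS}


def edge_metric_node_means(dist: MetricDistribution, net: CooccurrenceNetwork) -> MetricDistribution:
    """Per-node mean of an edge-valued metric over incident edges."""
    if dist.kind != "edge":
        raise ValueError("expects an edge-valued metric distribution")
    acc: dict[str, list[float]] = {v: [] for v in net.graph.nodes}
    for (u, v), val in dist.values.items():
        acc[u].append(val)
        acc[v].append(val)
    values = {v: (float(np.mean(x)) if x else 0.0) for v, x in acc.items()}
    return MetricDistribution(dist.metric + "_node_mean", dist.outcome, values, "node")


def metrics_to_frame(dists: Iterable[MetricDistribution]) -> pd.DataFrame:
    """Long-format table: network, metric, element, value."""
    rows = []
    for d in dists:
        for el, val in d.values.items():
            rows.append(
                {
                    "network": d.outcome,
                    "metric": d.metric,
                    "element": el if isinstance(el, str) else "|".join(el),
                    "value": val,
                }
            )
    return pd.DataFrame(rows)


def write_network(net: CooccurrenceNetwork, graphml_path: str | Path,
                  tsv_path: str | Path | None = None) -> None:
    nx.write_graphml(net.graph, graphml_path)
    if tsv_path:
        rows = [{"source": u, "target": v, "weight": w} for u, v, w in net.edges]
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
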