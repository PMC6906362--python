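"""Independent brute-force oracles for small graphs and probabilities.

Everything here is implemented from first principles (Floyd-Warshall
distances, exhaustive subset/path enumeration, literal textbook
formulas) without calling networkx or the package under test, so the
dual-route metric checks never collapse onto a single implementation.
Intended for graphs of at most ~8 nodes.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

INF = float("inf")


def adjacency(nodes, edges):
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def bf_distances(nodes, edges, weights=None):
    """All-pairs shortest-path distances by Floyd-Warshall."""
    dist = {u: {v: (0.0 if u == v else INF) for v in nodes} for u in nodes}
    for u, v in edges:
        w = 1.0 if weights is None else weights[tuple(sorted((u, v)))]
        dist[u][v] = min(dist[u][v], w)
        dist[v][u] = min(dist[v][u], w)
    for k in nodes:
        for i in nodes:
            for j in nodes:
                alt = dist[i][k] + dist[k][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt
    return dist


def bf_all_shortest_paths(adj, dist, s, t):
    """Every shortest s-t path, via the distance-decrement recursion."""
    if dist[s][t] == INF:
        return []
    paths = []

    def extend(path):
        v = path[-1]
        if v == t:
            paths.append(list(path))
            return
        for w in adj[v]:
            if dist[s][w] == dist[s][v] + 1 and dist[w][t] == dist[v][t] - 1:
                extend(path + [w])

    extend([s])
    return paths


def bf_degree_centrality(adj):
    n = len(adj)
    return {v: (len(adj[v]) / (n - 1) if n > 1 else 0.0) for v in adj}


def bf_average_neighbor_degree(adj):
    out = {}
    for v, nbrs in adj.items():
        out[v] = sum(len(adj[u]) for u in nbrs) / len(nbrs) if nbrs else 0.0
    return out


def bf_closeness(nodes, edges):
    """Wasserman-Faust closeness: reachable-set scaling on components."""
    dist = bf_distances(nodes, edges)
    n = len(nodes)
    out = {}
    for v in nodes:
        reach = [dist[v][u] for u in nodes if u != v and dist[v][u] < INF]
        if not reach or sum(reach) == 0:
            out[v] = 0.0
        else:
            out[v] = (len(reach) / sum(reach)) * (len(reach) / (n - 1))
    return out


def bf_betweenness(nodes, edges):
    """Normalized betweenness from exhaustive shortest-path enumeration."""
    adj = adjacency(nodes, edges)
    dist = bf_distances(nodes, edges)
    n = len(nodes)
    acc = {v: Fraction(0) for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = bf_all_shortest_paths(adj, dist, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            acc[v] += Fraction(through, len(paths))
    if n < 3:
        return {v: 0.0 for v in nodes}
    scale = Fraction(2, (n - 1) * (n - 2))
    return {v: float(acc[v] * scale) for v in nodes}


def bf_edge_betweenness(nodes, edges):
    """Normalized edge betweenness over unordered node pairs."""
    adj = adjacency(nodes, edges)
    dist = bf_distances(nodes, edges)
    n = len(nodes)
    keys = [tuple(sorted(e)) for e in edges]
    acc = {e: Fraction(0) for e in keys}
    for s, t in itertools.combinations(nodes, 2):
        paths = bf_all_shortest_paths(adj, dist, s, t)
        if not paths:
            continue
        for e in keys:
            u, v = e
            through = sum(
                1
                for p in paths
                if any({p[i], p[i + 1]} == {u, v} for i in range(len(p) - 1))
            )
            acc[e] += Fraction(through, len(paths))
    scale = Fraction(2, n * (n - 1)) if n > 1 else Fraction(0)
    return {e: float(acc[e] * scale) for e in keys}


def bf_maximal_cliques(adj):
    """All maximal cliques by exhaustive subset enumeration."""
    nodes = sorted(adj)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(v in adj[u] for u, v in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    return [
        c for c in cliques
        if not any(c < other for other in cliques)
    ]


def bf_clique_metrics(adj):
    cliques = bf_maximal_cliques(adj)
    n_cliques = {v: sum(1 for c in cliques if v in c) for v in adj}
    clique_num = {v: max((len(c) for c in cliques if v in c), default=0) for v in adj}
    return n_cliques, clique_num


def bf_triangles(adj):
    out = {}
    for v in adj:
        out[v] = sum(
            1 for u, w in itertools.combinations(adj[v], 2) if w in adj[u]
        )
    return out


def bf_clustering(adj):
    tri = bf_triangles(adj)
    out = {}
    for v in adj:
        k = len(adj[v])
        out[v] = 2 * tri[v] / (k * (k - 1)) if k >= 2 else 0.0
    return out


def bf_square_clustering(adj):
    """Quadrilateral clustering (Lind/Zhang additive-potential formula).

    Per neighbor pair (u, w): q squares, potential
    (k_u - 1 - q - theta) + (k_w - 1 - q - theta) + q, theta = 1 if
    u and w are adjacent.
    """
    out = {}
    for v in adj:
        num = 0
        den = 0
        for u, w in itertools.combinations(sorted(adj[v]), 2):
            q = len((adj[u] & adj[w]) - {v})
            theta = 1 if w in adj[u] else 0
            eta = 1 + q + theta
            num += q
            den += (len(adj[u]) - eta) + (len(adj[w]) - eta) + q
        out[v] = num / den if den > 0 else 0.0
    return out


def _max_disjoint_paths(adj, s, t):
    """Max internally-vertex-disjoint s-t paths by exhaustive packing."""
    # enumerate all simple s-t paths as frozensets of internal nodes
    internals = []

    def walk(v, visited, inner):
        if v == t:
            internals.append(frozenset(inner))
            return
        for w in adj[v]:
            if w not in visited:
                walk(w, visited | {w}, inner + ([w] if w != t else []))

    walk(s, {s}, [])
    bound = min(len(adj[s]), len(adj[t]))
    best = 0

    def pack(i, used, count):
        nonlocal best
        best = max(best, count)
        if best >= bound or i >= len(internals):
            return
        # prune: even taking all remaining cannot beat best
        if count + (len(internals) - i) <= best:
            return
        for j in range(i, len(internals)):
            p = internals[j]
            if not (p & used):
                pack(j + 1, used | p, count + 1)
                if best >= bound:
                    return

    internals.sort(key=len)
    pack(0, frozenset(), 0)
    return best


def bf_node_connectivity_mean(adj):
    """Per-node mean pairwise vertex connectivity (0 for unreachable)."""
    nodes = sorted(adj)
    n = len(nodes)
    kappa = {}
    for s, t in itertools.combinations(nodes, 2):
        kappa[(s, t)] = _max_disjoint_paths(adj, s, t)
    out = {}
    for v in nodes:
        if n == 1:
            out[v] = 0.0
            continue
        total = sum(kappa[tuple(sorted((v, u)))] for u in nodes if u != v)
        out[v] = total / (n - 1)
    return out


def bf_finite_wiener(nodes, edges, weights):
    dist = bf_distances(nodes, edges, weights)
    return sum(
        dist[u][v]
        for u, v in itertools.combinations(nodes, 2)
        if dist[u][v] < INF
    )


def bf_closeness_vitality(nodes, edges, weights):
    """Finite-pair Wiener-index drop per removed node (weighted)."""
    base = bf_finite_wiener(nodes, edges, weights)
    out = {}
    for v in nodes:
        rest_nodes = [u for u in nodes if u != v]
        rest_edges = [e for e in edges if v not in e]
        out[v] = base - bf_finite_wiener(rest_nodes, rest_edges, weights)
    return out


def bf_edge_load(nodes, edges):
    """Source-summed shortest-path load on edges.

    Convention: per source, every directed edge starts with one unit;
    load flowing back from each node splits equally over its
    shortest-path predecessors, discounted by the predecessor's own
    in-degree in the shortest-path DAG.
    """
    adj = adjacency(nodes, edges)
    dist = bf_distances(nodes, edges)
    total = {}
    for u, v in edges:
        total[(u, v)] = 0.0
        total[(v, u)] = 0.0
    for source in nodes:
        pred = {source: []}
        for v in nodes:
            if v != source and dist[source][v] < INF:
                pred[v] = [w for w in adj[v] if dist[source][w] == dist[source][v] - 1]
        between = {}
        for u, v in edges:
            between[(u, v)] = 1.0
            between[(v, u)] = 1.0
        order = sorted(pred, key=lambda v: dist[source][v], reverse=True)
        for v in order:
            for w in pred[v]:
                if w in pred:
                    num = len(pred[w])
                    for x in pred[w]:
                        between[(w, x)] += between[(v, w)] / num
                        between[(x, w)] += between[(w, v)] / num
        for e in between:
            total[e] += between[e]
    return {tuple(sorted(e)): total[e] for e in total}


def bf_effective_size(adj):
    """Burt effective size; unweighted: deg - 2 * (ties among alters) / deg."""
    out = {}
    for v, nbrs in adj.items():
        k = len(nbrs)
        if k == 0:
            out[v] = 0.0  # convention for isolates
            continue
        ties = sum(1 for u, w in itertools.combinations(nbrs, 2) if w in adj[u])
        out[v] = k - 2 * ties / k
    return out


def bf_constraint(adj):
    """Burt constraint: sum over neighbors of (p_vw + sum_q p_vq p_qw)^2."""
    out = {}
    for v, nbrs in adj.items():
        if not nbrs:
            out[v] = 0.0  # convention for isolates
            continue
        p_v = {u: 1.0 / len(adj[v]) for u in nbrs}
        c = 0.0
        for w in nbrs:
            indirect = sum(
                p_v[q] * (1.0 / len(adj[q]))
                for q in nbrs
                if q != w and w in adj[q]
            )
            c += (p_v[w] + indirect) ** 2
        out[v] = c
    return out


# ---------------------------------------------------------------------------
# Probability oracles
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration (point-mass rule)."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def pmf(x):
        return (
            math.comb(row1, x)
            * math.comb(row2, col1 - x)
            / math.comb(n, col1)
        )

    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = pmf(a)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


def mc_prob_greater(a1, b1, a2, b2, n_draws, rng):
    """Monte-Carlo estimate of P(Beta(a1,b1) > Beta(a2,b2))."""
    x = rng.beta(a1, b1, n_draws)
    y = rng.beta(a2, b2, n_draws)
    return float((x > y).mean())
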