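"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the random walk is
solved as a dense linear system assembled by explicit loops, shortest paths
come from a hand-written breadth-first search, and the hypergeometric tail
is enumerated exactly with rational arithmetic.
"""

from collections import deque
from fractions import Fraction
from math import comb

import numpy as np


def bfs_distances(adj: dict, source):
    """Hand-written BFS distances from ``source``; adj maps node -> iterable of neighbors."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def graph_adjacency(graph) -> dict:
    return {v: sorted(graph.adj[v]) for v in graph.nodes}


def brute_force_avg_distance(graph, A, B) -> float:
    """Mean of d(a, b) over all pairs a in A, b in B with a != b, via BFS."""
    adj = graph_adjacency(graph)
    total, n_pairs = 0, 0
    for a in sorted(A):
        dist = bfs_distances(adj, a)
        for b in sorted(B):
            if b == a:
                continue
            total += dist[b]
            n_pairs += 1
    return total / n_pairs


def brute_force_closeness(graph) -> dict:
    """1 / mean BFS distance within the node's component; isolated nodes -> 0."""
    adj = graph_adjacency(graph)
    out = {}
    for v in graph.nodes:
        dist = bfs_distances(adj, v)
        others = [d for node, d in dist.items() if node != v]
        out[v] = (len(others) / sum(others)) if others else 0.0
    return out


def dense_rwr_scores(layer_graphs, nodes, seeds, restart, interlayer_jump):
    """Closed-form multiplex RWR: solve (I - (1-r) T) p = r s densely.

    States are ordered layer-major to match nothing in particular; the
    comparison is done per gene after aggregation.  Genes isolated within a
    layer put all transition mass on relocation; the instances used in tests
    never contain genes isolated in every layer.
    """
    nodes = sorted(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n, L = len(nodes), len(layer_graphs)
    delta = interlayer_jump if L > 1 else 0.0
    N = n * L
    T = np.zeros((N, N))
    for l, g in enumerate(layer_graphs):
        for v in nodes:
            col = l * n + idx[v]
            nbrs = sorted(g.adj[v]) if v in g else []
            if nbrs:
                for u in nbrs:
                    T[l * n + idx[u], col] += (1.0 - delta) / len(nbrs)
                jump = delta
            else:
                jump = 1.0 if L > 1 else 0.0
            if L > 1:
                for l2 in range(L):
                    if l2 != l:
                        T[l2 * n + idx[v], col] += jump / (L - 1)
    assert np.allclose(T.sum(axis=0), 1.0), "dense transition must be column-stochastic"
    s = np.zeros(N)
    seeds = sorted(seeds)
    for l in range(L):
        for g in seeds:
            s[l * n + idx[g]] = 1.0 / (len(seeds) * L)
    p = np.linalg.solve(np.eye(N) - (1.0 - restart) * T, restart * s)
    per_gene = p.reshape(L, n).mean(axis=0)
    per_gene = per_gene / per_gene.sum()
    return dict(zip(nodes, per_gene))


def exact_hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k), X ~ Hypergeometric(N, K, n), by exact enumeration."""
    return sum(
        (Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n)))
        for i in range(k, min(n, K) + 1)
    )


def random_multiplex(rng, max_nodes=30, max_layers=3, p=0.2):
    """A small random multiplex (list of edge sets) for oracle comparisons."""
    import networkx as nx

    n = int(rng.integers(4, max_nodes + 1))
    L = int(rng.integers(1, max_layers + 1))
    names = [f"N{i:02d}" for i in range(n)]
    while True:
        layers = []
        for _ in range(L):
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            layers.append(
                frozenset((names[min(a, b)], names[max(a, b)]) for a, b in g.edges)
            )
        if len({v for edges in layers for e in edges for v in e}) >= 4:
            return names, layers
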