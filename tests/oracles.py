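"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive: Floyd-Warshall all-pairs
shortest-path counting for the centralities, exact combinatorial
summation for the hypergeometric tail, and the literal step-up
recurrence for Benjamini-Hochberg. None of it shares code with the
package.
"""

from __future__ import annotations

import math
from fractions import Fraction

import networkx as nx
import numpy as np

INF = float("inf")


def floyd_warshall_path_counts(g: nx.Graph) -> tuple[list, np.ndarray, np.ndarray]:
    """All-pairs distances and shortest-path counts by Floyd-Warshall."""
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), INF)
    sigma = np.zeros((n, n))
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(sigma, 1.0)
    for u, v in g.edges:
        i, j = idx[u], idx[v]
        dist[i, j] = dist[j, i] = 1.0
        sigma[i, j] = sigma[j, i] = 1.0
    for k in range(n):
        for i in range(n):
            if i == k or dist[i, k] == INF:
                continue
            for j in range(n):
                if j in (i, k) or dist[k, j] == INF:
                    continue
                alt = dist[i, k] + dist[k, j]
                if alt < dist[i, j]:
                    dist[i, j] = alt
                    sigma[i, j] = sigma[i, k] * sigma[k, j]
                elif alt == dist[i, j]:
                    sigma[i, j] += sigma[i, k] * sigma[k, j]
    return nodes, dist, sigma


def brute_betweenness(g: nx.Graph) -> dict:
    """Pair-normalised betweenness by explicit enumeration over (s, t)."""
    nodes, dist, sigma = floyd_warshall_path_counts(g)
    n = len(nodes)
    out = {v: 0.0 for v in nodes}
    if n < 3:
        return out
    for vi, v in enumerate(nodes):
        total = 0.0
        for s in range(n):
            if s == vi:
                continue
            for t in range(s + 1, n):
                if t == vi or sigma[s, t] == 0:
                    continue
                if dist[s, vi] + dist[vi, t] == dist[s, t]:
                    total += sigma[s, vi] * sigma[vi, t] / sigma[s, t]
        out[v] = total / ((n - 1) * (n - 2) / 2)
    return out


def brute_closeness(g: nx.Graph) -> dict:
    """Component-wise closeness (m-1)/sum(d); isolated nodes get 0."""
    nodes, dist, _ = floyd_warshall_path_counts(g)
    out = {}
    for i, v in enumerate(nodes):
        reach = [d for d in dist[i] if d < INF]
        total = sum(reach)  # includes the 0 to itself
        m = len(reach)
        out[v] = (m - 1) / total if total > 0 else 0.0
    return out


def brute_degree(g: nx.Graph) -> dict:
    """Degree as adjacency row sums."""
    a = nx.to_numpy_array(g)
    return {v: int(a[i].sum()) for i, v in enumerate(g.nodes)}


def hypergeom_tail_enum(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exact rational summation of the PMF."""
    denom = math.comb(N, n)
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(total)


def bh_stepup(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg by the literal step-up recurrence."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adj[i] = running
    return adj
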