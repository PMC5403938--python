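"""Independent brute-force reference implementations.

These deliberately avoid igraph/networkx and any code path of the package:
clustering by explicit neighbor-pair counting, path length by hand-rolled
BFS, betweenness by explicit enumeration of every shortest path, ICC by
textbook ANOVA sums of squares, and BH by the stepwise definition.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(adj: np.ndarray, source: int) -> list[float]:
    n = adj.shape[0]
    dist = [float("inf")] * n
    dist[source] = 0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in range(n):
            if adj[u, v] and dist[v] == float("inf"):
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def clustering_oracle(adj: np.ndarray) -> list[float]:
    """C_i = realized neighbor links / possible neighbor links."""
    n = adj.shape[0]
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        links = sum(
            adj[a, b] for a, b in itertools.combinations(nbrs, 2)
        )
        out.append(2.0 * links / (k * (k - 1)))
    return out


def harmonic_lp_oracle(adj: np.ndarray) -> float:
    """Harmonic-mean path length; disconnected pairs contribute zero."""
    n = adj.shape[0]
    inv_sum = 0.0
    for s in range(n):
        dist = bfs_distances(adj, s)
        for t in range(n):
            if t != s and dist[t] != float("inf"):
                inv_sum += 1.0 / dist[t]
    return 1.0 / (inv_sum / (n * (n - 1)))


def _all_shortest_paths(adj: np.ndarray, s: int, t: int, dist: list[float]):
    """Every shortest s-t path, by DFS backwards through the BFS layering."""
    if dist[t] == float("inf"):
        return
    n = adj.shape[0]
    path = [t]

    def extend(node):
        if node == s:
            yield list(reversed(path))
            return
        for u in range(n):
            if adj[u, node] and dist[u] == dist[node] - 1:
                path.append(u)
                yield from extend(u)
                path.pop()

    yield from extend(t)


def betweenness_oracle(adj: np.ndarray) -> list[float]:
    """Freeman betweenness by explicit shortest-path enumeration.

    Each unordered pair {s, t} is counted once; every shortest path
    contributes 1/sigma_st to each of its interior nodes.
    """
    n = adj.shape[0]
    bc = [0.0] * n
    for s in range(n):
        dist = bfs_distances(adj, s)
        for t in range(s + 1, n):
            paths = list(_all_shortest_paths(adj, s, t, dist))
            if not paths:
                continue
            for p in paths:
                for node in p[1:-1]:
                    bc[node] += 1.0 / len(paths)
    return bc


def icc_oneway_oracle(x: np.ndarray) -> tuple[float, float]:
    """(ICC(1,1), F) by the explicit one-way ANOVA decomposition."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ssb = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ssw = sum((x[i, j] - x[i].mean()) ** 2 for i in range(n) for j in range(k))
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    icc = (msb - msw) / (msb + (k - 1) * msw)
    return icc, msb / msw


def bh_oracle(pvalues: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg rejections by the stepwise definition."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    cutoff = -1
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            cutoff = rank
    reject = np.zeros(m, dtype=bool)
    if cutoff > 0:
        reject[order[:cutoff]] = True
    return reject


def pearson_oracle(x, y) -> float:
    """Textbook covariance / SD formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def random_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    return (adj | adj.T).astype(np.uint8)
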