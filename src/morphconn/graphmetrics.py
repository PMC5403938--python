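"""Nodal and global graph measures on binary undirected networks.

Conventions:

* clustering ``Ci = 2*Ei / (ki*(ki-1))`` with ``Ci = 0`` for degree < 2;
  ``Cp`` is the unweighted mean of ``Ci`` over all nodes;
* characteristic path length ``Lp`` is the harmonic-mean distance
  ``Lp = [ (1/(N(N-1))) * sum_{i != j} 1/d(i,j) ]^-1`` with disconnected
  pairs contributing zero inverse distance, so ``Lp`` is finite on
  disconnected graphs;
* betweenness is unnormalized Freeman betweenness with each unordered pair
  counted once, so on 68 nodes hub values land in the tens-to-hundreds.

Shortest paths and betweenness accumulation are delegated to igraph's C
implementations; the test suite pins them against brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np

from .connectome import BinaryNetwork


@dataclass(frozen=True)
class MetricsRecord:
    """All graph measures of one network at one sparsity."""

    sparsity: float
    cp: float
    lp: float
    degree: np.ndarray
    clustering_i: np.ndarray
    betweenness: np.ndarray


def _to_igraph(net: BinaryNetwork) -> ig.Graph:
    iu, ju = np.nonzero(np.triu(net.adjacency, k=1))
    return ig.Graph(n=net.n_nodes, edges=list(zip(iu.tolist(), ju.tolist())))


def degree(net: BinaryNetwork) -> np.ndarray:
    """Per-node degree (row sums of the adjacency matrix)."""
    return net.adjacency.sum(axis=0).astype(np.int64)


def clustering(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their unweighted mean Cp."""
    g = _to_igraph(net)
    ci = np.asarray(g.transitivity_local_undirected(mode="zero"), dtype=float)
    return ci, float(ci.mean())


def characteristic_path_length(net: BinaryNetwork) -> float:
    """Harmonic-mean shortest-path length (hops); >= 1 for non-empty nets."""
    if net.edge_count == 0:
        raise ValueError("Lp is undefined for a network with no edges")
    g = _to_igraph(net)
    d = np.asarray(g.distances(), dtype=float)  # inf for disconnected pairs
    n = net.n_nodes
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(1.0 / (inv.sum() / (n * (n - 1))))


def betweenness(net: BinaryNetwork, normalized: bool = False) -> np.ndarray:
    """Freeman betweenness centrality, each unordered pair counted once.

    With ``normalized=True`` values are divided by (N-1)(N-2)/2, the
    maximum attainable on N nodes.
    """
    g = _to_igraph(net)
    bc = np.asarray(g.betweenness(), dtype=float)
    if normalized:
        n = net.n_nodes
        if n > 2:
            bc = bc / ((n - 1) * (n - 2) / 2)
    return bc


def compute_metrics(net: BinaryNetwork) -> MetricsRecord:
    """Degree, clustering, Cp, Lp and betweenness of one network."""
    ci, cp = clustering(net)
    return MetricsRecord(
        sparsity=net.sparsity,
        cp=cp,
        lp=characteristic_path_length(net),
        degree=degree(net),
        clustering_i=ci,
        betweenness=betweenness(net),
    )
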