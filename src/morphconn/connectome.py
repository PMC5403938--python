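"""Individual connectivity matrices and sparsity thresholding.

The regional descriptor is the standardized feature vector of a region;
connectivity between two regions is the Pearson correlation of their
feature vectors.  Absolute correlations are thresholded by *sparsity* - the
fraction of realized edges among all N(N-1)/2 undirected pairs - keeping
exactly the k strongest pairs, which makes edge sets nested across a
sparsity sweep.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix over regions."""

    values: np.ndarray
    regions: tuple[str, ...]
    absolute: bool = False
    subject_id: str | None = None
    session_id: int | None = None
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {v.shape}")
        if v.shape[0] != len(self.regions):
            raise ValueError("region labels do not match matrix size")
        if not np.allclose(v, v.T, atol=1e-10, rtol=0.0):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def n_regions(self) -> int:
        return len(self.regions)


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected, unweighted adjacency at a given sparsity."""

    adjacency: np.ndarray
    sparsity: float
    regions: tuple[str, ...]

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.trace(a) != 0:
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2


def round_half_up(x: float) -> int:
    """Round half away from zero (0.5 -> 1), unlike banker's rounding."""
    return int(math.floor(x + 0.5))


def feature_correlation_matrix(std: "object") -> ConnectivityMatrix:
    """Pearson correlation between every pair of regional feature vectors.

    ``std`` is a standardized :class:`~morphconn.features.SubjectFeatureMatrix`
    with at least three features.  Raises if any region's feature vector is
    constant (its correlation is undefined).
    """
    data = std.data
    values = data.to_numpy(dtype=float)
    n_regions, n_features = values.shape
    if n_features < 3:
        raise ValueError(
            f"need at least 3 features for a meaningful correlation, got {n_features}"
        )
    row_sd = values.std(axis=1)
    flat = np.flatnonzero(row_sd == 0)
    if flat.size:
        raise ValueError(
            f"region {data.index[flat[0]]!r} has a constant feature vector"
        )
    corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return ConnectivityMatrix(
        values=corr,
        regions=tuple(data.index),
        absolute=False,
        subject_id=getattr(std, "subject_id", None),
        session_id=getattr(std, "session_id", None),
        feature_names=tuple(data.columns),
    )


def absolute_matrix(c: ConnectivityMatrix) -> ConnectivityMatrix:
    """Element-wise absolute value, keeping both signs of strong coupling."""
    if c.absolute:
        raise ValueError("matrix is already in absolute form")
    return replace(c, values=np.abs(c.values), absolute=True)


def _ranked_pairs(c: ConnectivityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs ordered by |r| descending, ties (i, j) ascending."""
    n = c.n_regions
    iu, ju = np.triu_indices(n, k=1)
    r = c.values[iu, ju]
    order = np.lexsort((ju, iu, -r))
    return iu[order], ju[order]


def binarize_at_sparsity(c: ConnectivityMatrix, s: float) -> BinaryNetwork:
    """Keep the k = round(s * N(N-1)/2) strongest pairs as edges.

    The input must be an absolute-valued matrix.  k is rounded half away
    from zero; equal correlations are broken lexicographically by (i, j) so
    the edge set is a deterministic total-order prefix (hence nested in s).
    """
    if not c.absolute:
        raise ValueError("binarization requires the absolute-valued matrix")
    if not 0 < s <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {s}")
    n = c.n_regions
    total_pairs = n * (n - 1) // 2
    k = round_half_up(s * total_pairs)
    if k == 0:
        raise ValueError(f"sparsity {s} yields zero edges on {n} nodes")
    ri, rj = _ranked_pairs(c)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[ri[:k], rj[:k]] = 1
    adj |= adj.T
    return BinaryNetwork(adjacency=adj, sparsity=float(s), regions=c.regions)


def sparsity_grid(s_min: float = 0.20, s_max: float = 0.40, step: float = 0.01) -> list[float]:
    """The sparsity values of a sweep, robust to float step accumulation."""
    if s_min > s_max:
        raise ValueError("s_min must not exceed s_max")
    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = int(math.floor((s_max - s_min) / step + 1e-9)) + 1
    return [round(s_min + i * step, 10) for i in range(n_steps)]


def sparsity_sweep(
    c: ConnectivityMatrix,
    s_min: float = 0.20,
    s_max: float = 0.40,
    step: float = 0.01,
    warn_isolated: bool = True,
) -> list[BinaryNetwork]:
    """Binarize over a sparsity range (default 20-40% in 1% steps).

    Edge sets are nested across the sweep.  If the sparsest network has
    isolated nodes a warning (not an error) is emitted, since the intended
    minimum sparsity is the smallest that leaves no node isolated.
    """
    grid = sparsity_grid(s_min, s_max, step)
    n = c.n_regions
    total_pairs = n * (n - 1) // 2
    ri, rj = _ranked_pairs(c)
    nets = []
    for s in grid:
        k = round_half_up(s * total_pairs)
        if k == 0:
            raise ValueError(f"sparsity {s} yields zero edges on {n} nodes")
        adj = np.zeros((n, n), dtype=np.uint8)
        adj[ri[:k], rj[:k]] = 1
        adj |= adj.T
        nets.append(BinaryNetwork(adjacency=adj, sparsity=s, regions=c.regions))
    if warn_isolated:
        isolated = check_no_isolated_nodes(nets[0])
        if isolated:
            warnings.warn(
                f"isolated nodes at minimum sparsity {grid[0]}: {isolated}",
                stacklevel=2,
            )
    return nets


def check_no_isolated_nodes(net: BinaryNetwork) -> list[str]:
    """Labels of zero-degree nodes (empty list when none)."""
    deg = net.adjacency.sum(axis=0)
    return [net.regions[i] for i in np.flatnonzero(deg == 0)]


def edge_list(c: ConnectivityMatrix, net: BinaryNetwork) -> list[tuple[str, str, float]]:
    """(region_i, region_j, |r|) triples of a binarized network's edges."""
    iu, ju = np.nonzero(np.triu(net.adjacency, k=1))
    return [(net.regions[i], net.regions[j], float(c.values[i, j])) for i, j in zip(iu, ju)]


def network_from_adjacency(
    adjacency: np.ndarray, regions: Sequence[str] | None = None, sparsity: float | None = None
) -> BinaryNetwork:
    """Wrap a raw 0/1 adjacency matrix (helper for tests and null models)."""
    adjacency = np.asarray(adjacency, dtype=np.uint8)
    n = adjacency.shape[0]
    if regions is None:
        regions = tuple(f"n{i}" for i in range(n))
    if sparsity is None:
        sparsity = adjacency.sum() / (n * (n - 1)) if n > 1 else 0.0
    return BinaryNetwork(adjacency=adjacency, sparsity=float(sparsity), regions=tuple(regions))
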