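"""Matched random networks and small-world configurations.

The null ensemble preserves the number of nodes and edges; by default it
also preserves the full degree sequence via Maslov-Sneppen double-edge
swaps (the convention of the random-network comparisons this construction
follows), with a plain Erdos-Renyi G(n, m) option.  Small-worldness is
summarized by gamma = Cp/Cp_rand, lambda = Lp/Lp_rand and sigma =
gamma/lambda > 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectome import BinaryNetwork, network_from_adjacency
from .graphmetrics import characteristic_path_length, clustering


@dataclass(frozen=True)
class SmallWorldResult:
    """Observed vs matched-random clustering and path length."""

    gamma: float
    lam: float
    sigma: float
    cp: float
    lp: float
    cp_rand_mean: float
    cp_rand_sd: float
    lp_rand_mean: float
    lp_rand_sd: float
    n_null: int
    seed: int | None


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float


def random_network(
    net: BinaryNetwork,
    n_swaps: int | None = None,
    seed: int | np.random.Generator | None = None,
    model: str = "degree",
) -> BinaryNetwork:
    """A randomized network matched to ``net``.

    ``model="degree"`` (default) applies ``n_swaps`` attempted double-edge
    swaps (default 10x the edge count), preserving the degree sequence and
    avoiding self-loops and multi-edges.  ``model="er"`` draws an
    Erdos-Renyi graph with the same node and edge count only.  A rigid
    graph on which no swap succeeds triggers a warning, not an error.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = net.n_nodes
    m = net.edge_count
    if m < 2:
        raise ValueError("randomization needs at least 2 edges")

    if model == "er":
        total = n * (n - 1) // 2
        iu, ju = np.triu_indices(n, k=1)
        chosen = rng.choice(total, size=m, replace=False)
        adj = np.zeros((n, n), dtype=np.uint8)
        adj[iu[chosen], ju[chosen]] = 1
        adj |= adj.T
        return network_from_adjacency(adj, regions=net.regions, sparsity=net.sparsity)
    if model != "degree":
        raise ValueError(f"unknown null model {model!r}")

    if n_swaps is None:
        n_swaps = 10 * m
    adj = net.adjacency.copy()
    iu, ju = np.nonzero(np.triu(adj, k=1))
    edges = np.stack([iu, ju], axis=1)
    successes = 0
    if n_swaps > 0:
        pick = rng.integers(0, m, size=(n_swaps, 2))
        flip = rng.integers(0, 2, size=n_swaps)
        for t in range(n_swaps):
            e1, e2 = pick[t]
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if flip[t]:
                c, d = d, c
            # propose a-d and c-b
            if a == d or c == b:
                continue
            if adj[a, d] or adj[c, b]:
                continue
            adj[a, b] = adj[b, a] = 0
            adj[c, d] = adj[d, c] = 0
            adj[a, d] = adj[d, a] = 1
            adj[c, b] = adj[b, c] = 1
            edges[e1] = (a, d) if a < d else (d, a)
            edges[e2] = (c, b) if c < b else (b, c)
            successes += 1
        if successes == 0:
            warnings.warn(
                f"no successful edge swap in {n_swaps} attempts; "
                "returning the network unchanged (rigid graph?)",
                stacklevel=2,
            )
    return network_from_adjacency(adj, regions=net.regions, sparsity=net.sparsity)


def small_world(
    net: BinaryNetwork,
    n_null: int = 100,
    seed: int | None = None,
    n_swaps: int | None = None,
    model: str = "degree",
) -> SmallWorldResult:
    """gamma, lambda and sigma against an ensemble of matched nulls.

    ``Cp_rand`` and ``Lp_rand`` are means over ``n_null`` independent
    randomizations; sigma = gamma/lambda exactly.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    _, cp = clustering(net)
    lp = characteristic_path_length(net)
    rng = np.random.default_rng(seed)
    cps = np.empty(n_null)
    lps = np.empty(n_null)
    for i in range(n_null):
        null = random_network(net, n_swaps=n_swaps, seed=rng, model=model)
        _, cps[i] = clustering(null)
        lps[i] = characteristic_path_length(null)
    cp_rand = float(cps.mean())
    lp_rand = float(lps.mean())
    if cp_rand == 0:
        raise ValueError("null ensemble has zero mean clustering; gamma undefined")
    gamma = cp / cp_rand
    lam = lp / lp_rand
    return SmallWorldResult(
        gamma=gamma,
        lam=lam,
        sigma=gamma / lam,
        cp=cp,
        lp=lp,
        cp_rand_mean=cp_rand,
        cp_rand_sd=float(cps.std(ddof=1)) if n_null > 1 else 0.0,
        lp_rand_mean=lp_rand,
        lp_rand_sd=float(lps.std(ddof=1)) if n_null > 1 else 0.0,
        n_null=n_null,
        seed=seed,
    )


def compare_real_vs_null(real, null) -> TTestResult:
    """Classical pooled-variance independent two-sample t-test (two-sided)."""
    real = np.asarray(real, dtype=float)
    null = np.asarray(null, dtype=float)
    if real.size < 2 or null.size < 2:
        raise ValueError("both samples need at least 2 observations")
    if real.std(ddof=1) == 0 and null.std(ddof=1) == 0:
        if real.mean() == null.mean():
            return TTestResult(statistic=0.0, pvalue=1.0)
        raise ValueError("zero pooled variance with unequal means; t undefined")
    res = stats.ttest_ind(real, null, equal_var=True)
    return TTestResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


def fdr_correct(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up at level ``q``.

    Returns ``(reject, p_adjusted)`` arrays aligned with the input order.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        raise ValueError("empty p-value list")
    if ((pvalues < 0) | (pvalues > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return reject, p_adj
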