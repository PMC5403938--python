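"""One-way random-effects ICC for test-retest reliability.

The intraclass correlation used throughout is the variance-ratio form

    ICC = sigma2_between / (sigma2_between + sigma2_within)

estimated by one-way ANOVA: with n subjects and k sessions,
``MSB`` (between-subject mean square) and ``MSW`` (within-subject mean
square) give ``ICC(1,1) = (MSB - MSW) / (MSB + (k-1) * MSW)``,
``sigma2_within = MSW`` and ``sigma2_between = (MSB - MSW)/k`` (floored at
zero).  Significance is the F-test ``F = MSB/MSW`` on (n-1, n(k-1)) degrees
of freedom.  ICC > 0.75 is conventionally "excellent" and 0.6-0.75 "good".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ICCResult:
    icc: float
    icc_raw: float  # unfloored ICC(1,1); may be negative in small samples
    sigma2_between: float
    sigma2_within: float
    fstat: float
    p: float
    n_subjects: int
    n_sessions: int


def icc_oneway(measurements) -> ICCResult:
    """ICC(1,1) from an (n subjects x k sessions) measurement table.

    Requires n >= 3, k >= 2 and a complete table.  An all-identical table
    (zero total variance) is an error; zero within-subject variance with
    between-subject spread gives ICC exactly 1.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise ValueError("measurements must be a 2-D subjects x sessions table")
    n, k = x.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if k < 2:
        raise ValueError(f"need at least 2 sessions, got {k}")
    if np.isnan(x).any():
        raise ValueError("measurement table has missing cells")

    grand = x.mean()
    subj_means = x.mean(axis=1)
    ssb = k * ((subj_means - grand) ** 2).sum()
    ssw = ((x - subj_means[:, None]) ** 2).sum()
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msb == 0 and msw == 0:
        raise ValueError("all measurements identical; total variance is zero")

    if msw == 0:
        icc_raw = 1.0
        fstat = np.inf
        p = 0.0
    else:
        icc_raw = (msb - msw) / (msb + (k - 1) * msw)
        fstat = msb / msw
        p = float(stats.f.sf(fstat, n - 1, n * (k - 1)))
    sigma2_within = msw
    sigma2_between = max((msb - msw) / k, 0.0)
    icc = (
        sigma2_between / (sigma2_between + sigma2_within)
        if sigma2_between + sigma2_within > 0
        else 1.0
    )
    return ICCResult(
        icc=float(icc),
        icc_raw=float(icc_raw),
        sigma2_between=float(sigma2_between),
        sigma2_within=float(sigma2_within),
        fstat=float(fstat),
        p=p,
        n_subjects=n,
        n_sessions=k,
    )


def classify_reliability(icc: float) -> str:
    """Conventional reliability label: excellent / good / below-good.

    ``> 0.75`` is excellent; ``0.6`` to ``0.75`` inclusive is good.
    """
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    if icc > 0.75:
        return "excellent"
    if icc >= 0.6:
        return "good"
    return "below-good"


def icc_table(table: pd.DataFrame, value: str = "value") -> ICCResult:
    """ICC from a tidy (subject, session, value) table."""
    wide = table.pivot(index="subject", columns="session", values=value)
    if wide.isna().any().any():
        raise ValueError("incomplete subject x session table")
    return icc_oneway(wide.to_numpy())


def metric_reliability(
    cohort,
    metric: str = "Cp",
    sparsities: Sequence[float] | None = None,
    feature_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sparsity test-retest ICC of a graph metric over a two-session cohort.

    ``cohort`` is a sequence of feature matrices covering sessions 1 and 2
    of every subject; both sessions are pushed through the identical
    construction (z-score, correlation, absolute value, thresholding).

    ``metric`` is ``"Cp"``, ``"Lp"`` or ``"BC"``.  For BC, which is nodal,
    two conventions are reported: ``icc`` is the mean over nodes of the
    per-node ICC across subjects, and ``icc_of_mean`` is the ICC of the
    node-mean BC.  For global metrics the two coincide.

    Returns a DataFrame indexed by sparsity with columns ``icc``,
    ``icc_of_mean``, ``fstat``, ``p``, ``label``; the summary across the
    sweep is the column mean of ``icc``.
    """
    from .pipeline import cohort_bc_tensor, cohort_global_metrics

    if metric not in ("Cp", "Lp", "BC"):
        raise ValueError(f"metric must be Cp, Lp or BC, got {metric!r}")

    if metric in ("Cp", "Lp"):
        table = cohort_global_metrics(
            cohort, sparsities=sparsities, feature_subset=feature_subset
        )
        col = "cp" if metric == "Cp" else "lp"
        rows = []
        for s, group in table.groupby("sparsity"):
            res = icc_table(group.rename(columns={col: "value"}), value="value")
            rows.append(
                {
                    "sparsity": s,
                    "icc": res.icc,
                    "icc_of_mean": res.icc,
                    "fstat": res.fstat,
                    "p": res.p,
                    "label": classify_reliability(res.icc),
                }
            )
        return pd.DataFrame(rows).set_index("sparsity")

    tensor, subjects, sessions, sparsity_values = cohort_bc_tensor(
        cohort, sparsities=sparsities, feature_subset=feature_subset
    )
    if sessions != [1, 2]:
        raise ValueError("BC reliability needs exactly sessions 1 and 2")
    # tensor: (n_subjects, n_sessions, n_sparsities, n_nodes)
    rows = []
    for si, s in enumerate(sparsity_values):
        per_node = []
        for node in range(tensor.shape[3]):
            data = tensor[:, :, si, node]
            if np.allclose(data.std(), 0):
                continue  # uninformative node; no variance to apportion
            per_node.append(icc_oneway(data).icc)
        node_mean = tensor[:, :, si, :].mean(axis=2)
        res_mean = icc_oneway(node_mean)
        icc_nodal = float(np.mean(per_node)) if per_node else np.nan
        rows.append(
            {
                "sparsity": s,
                "icc": icc_nodal,
                "icc_of_mean": res_mean.icc,
                "fstat": res_mean.fstat,
                "p": res_mean.p,
                "label": classify_reliability(icc_nodal),
            }
        )
    return pd.DataFrame(rows).set_index("sparsity")
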