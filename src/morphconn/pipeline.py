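"""End-to-end helpers tying construction stages together for a cohort.

These functions implement the canonical flow: z-score features ->
feature-vector Pearson correlation -> absolute value -> sparsity sweep ->
graph metrics, applied uniformly to every subject/session of a cohort.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import (
    BinaryNetwork,
    ConnectivityMatrix,
    absolute_matrix,
    feature_correlation_matrix,
    sparsity_grid,
    sparsity_sweep,
)
from .features import SubjectFeatureMatrix, zscore_features
from .graphmetrics import betweenness, characteristic_path_length, clustering


def build_connectivity(
    matrix: SubjectFeatureMatrix, feature_subset: Sequence[str] | None = None
) -> ConnectivityMatrix:
    """Absolute feature-vector correlation matrix of one subject/session."""
    if feature_subset is not None:
        matrix = matrix.subset(feature_subset)
    std = matrix if matrix.standardized else zscore_features(matrix)
    return absolute_matrix(feature_correlation_matrix(std))


def subject_networks(
    matrix: SubjectFeatureMatrix,
    sparsities: Sequence[float] | None = None,
    feature_subset: Sequence[str] | None = None,
    warn_isolated: bool = False,
) -> list[BinaryNetwork]:
    """Binary networks of one subject/session over the sparsity sweep."""
    grid = list(sparsities) if sparsities is not None else sparsity_grid()
    conn = build_connectivity(matrix, feature_subset)
    return sparsity_sweep(
        conn, s_min=grid[0], s_max=grid[-1],
        step=grid[1] - grid[0] if len(grid) > 1 else 0.01,
        warn_isolated=warn_isolated,
    )


def cohort_global_metrics(
    cohort: Sequence[SubjectFeatureMatrix],
    sparsities: Sequence[float] | None = None,
    feature_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tidy table of Cp and Lp per subject, session and sparsity."""
    grid = list(sparsities) if sparsities is not None else sparsity_grid()
    rows = []
    for m in cohort:
        for net in subject_networks(m, grid, feature_subset):
            _, cp = clustering(net)
            rows.append(
                {
                    "subject": m.subject_id,
                    "session": m.session_id,
                    "sparsity": net.sparsity,
                    "cp": cp,
                    "lp": characteristic_path_length(net),
                }
            )
    return pd.DataFrame(rows)


def cohort_bc_tensor(
    cohort: Sequence[SubjectFeatureMatrix],
    sparsities: Sequence[float] | None = None,
    feature_subset: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str], list[int], list[float]]:
    """Nodal betweenness for a whole cohort.

    Returns ``(tensor, subjects, sessions, sparsities)`` with tensor shape
    (n_subjects, n_sessions, n_sparsities, n_nodes); subject and session
    axes follow the sorted unique ids found in the cohort.
    """
    grid = list(sparsities) if sparsities is not None else sparsity_grid()
    subjects = sorted({m.subject_id for m in cohort})
    sessions = sorted({m.session_id for m in cohort})
    n_nodes = cohort[0].data.shape[0]
    tensor = np.full((len(subjects), len(sessions), len(grid), n_nodes), np.nan)
    for m in cohort:
        i = subjects.index(m.subject_id)
        t = sessions.index(m.session_id)
        for si, net in enumerate(subject_networks(m, grid, feature_subset)):
            tensor[i, t, si] = betweenness(net)
    if np.isnan(tensor).any():
        raise ValueError("cohort is missing subject/session combinations")
    return tensor, subjects, sessions, grid
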