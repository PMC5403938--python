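from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from morphconn.atlas import FEATURE_NAMES, desikan_killiany
from morphconn.connectome import network_from_adjacency
from morphconn.features import SubjectFeatureMatrix
from morphconn.synthcohort import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def atlas():
    return desikan_killiany()


@pytest.fixture(scope="session")
def small_cohort():
    """10 subjects x 2 sessions, default generator conditions."""
    cohort, _ = generate_cohort(SynthConfig(n_subjects=10, seed=42))
    return cohort


@pytest.fixture
def subject_matrix(small_cohort) -> SubjectFeatureMatrix:
    return small_cohort[0]


def write_aparc_fixture(
    path: Path,
    hemisphere: str,
    seed: int = 0,
    drop_region: str | None = None,
    permute_columns: bool = False,
    corrupt_cell: tuple[str, str] | None = None,
    extra_column: bool = False,
) -> Path:
    """Write a synthetic well-formed aparc.stats file, optionally mutated."""
    atlas = desikan_killiany()
    rng = np.random.default_rng(seed)
    structnames = atlas.structnames(hemisphere)
    columns = list(FEATURE_NAMES)
    if permute_columns:
        columns = list(rng.permutation(columns))
    header_cols = ["StructName"] + columns + (["ExtraCol"] if extra_column else [])
    lines = [
        "# Table of FreeSurfer cortical parcellation anatomical statistics",
        "# ColHeaders " + " ".join(header_cols),
    ]
    value_rng = np.random.default_rng(seed)  # values independent of layout
    for name in structnames:
        values = {
            feat: abs(value_rng.normal(10.0, 2.0)) + 0.5 for feat in FEATURE_NAMES
        }
        if name == drop_region:
            continue
        cells = [name]
        for col in columns:
            if corrupt_cell == (name, col):
                cells.append("not_a_number")
            else:
                cells.append(f"{values[col]:.6f}")
        if extra_column:
            cells.append("999")
        lines.append(" ".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def aparc_pair(tmp_path):
    lh = write_aparc_fixture(tmp_path / "lh.aparc.stats", "lh", seed=1)
    rh = write_aparc_fixture(tmp_path / "rh.aparc.stats", "rh", seed=2)
    return lh, rh


def net_from_edges(n: int, edges) -> "object":
    adj = np.zeros((n, n), dtype=np.uint8)
    for a, b in edges:
        adj[a, b] = adj[b, a] = 1
    return network_from_adjacency(adj)


def toy_feature_matrix(values: np.ndarray, regions=None) -> SubjectFeatureMatrix:
    values = np.asarray(values, dtype=float)
    n, f = values.shape
    regions = regions or [f"r{i}" for i in range(n)]
    data = pd.DataFrame(values, index=regions, columns=list(FEATURE_NAMES[:f]))
    return SubjectFeatureMatrix(subject_id="toy", session_id=1, data=data)
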