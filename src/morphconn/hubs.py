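"""Betweenness-centrality hub identification and stability.

A node is a hub when its betweenness strictly exceeds the network mean plus
one (sample) standard deviation of betweenness.  Nodal betweenness is
aggregated two ways before the rule is applied:

* ``msp_bc`` - mean over the sparsity sweep, per subject ("mean-sparsity"
  BC): which regions hub for a given individual;
* ``msj_bc`` - mean over subjects, per sparsity ("mean-subject" BC): which
  regions hub at a given threshold.

Stability is reported as the proportion of sparsities (or subjects) in
which each region passes the hub rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class HubStabilityResult:
    """Per-region hub proportions across sparsities and across subjects."""

    sparsity_proportion: pd.Series  # fraction of sparsities hubbed (msjBC calls)
    subject_proportion: pd.Series  # fraction of subjects hubbed (mspBC calls)
    min_proportion: float

    def stable_regions(self, axis: str = "subjects") -> list[str]:
        prop = (
            self.subject_proportion if axis == "subjects" else self.sparsity_proportion
        )
        return list(prop.index[prop > self.min_proportion])


def msp_bc(bc_by_sparsity: np.ndarray) -> np.ndarray:
    """Mean nodal BC over the sparsity sweep (one subject).

    ``bc_by_sparsity`` has shape (n_sparsities, n_nodes); every sparsity of
    the sweep must be present (NaN rows are rejected).
    """
    bc = np.asarray(bc_by_sparsity, dtype=float)
    if bc.ndim != 2:
        raise ValueError("expected a (n_sparsities, n_nodes) array")
    if np.isnan(bc).any():
        raise ValueError("missing BC values for part of the sparsity sweep")
    return bc.mean(axis=0)


def msj_bc(bc_by_subject: np.ndarray) -> np.ndarray:
    """Mean nodal BC over subjects (one sparsity)."""
    bc = np.asarray(bc_by_subject, dtype=float)
    if bc.ndim != 2 or bc.shape[0] < 1:
        raise ValueError("expected a (n_subjects, n_nodes) array with >= 1 subject")
    return bc.mean(axis=0)


def identify_hubs(bc_vector, regions=None, ddof: int = 1) -> list:
    """Nodes whose BC strictly exceeds mean(BC) + SD(BC).

    The SD is the sample standard deviation (``ddof=1``) over nodes; with a
    constant vector the hub set is empty (strict inequality).  Returns
    region labels when ``regions`` is given, otherwise node indices.
    """
    bc = np.asarray(bc_vector, dtype=float)
    if bc.size < 2:
        raise ValueError("hub rule needs at least 2 nodes")
    threshold = bc.mean() + bc.std(ddof=ddof)
    idx = np.flatnonzero(bc > threshold)
    if regions is None:
        return idx.tolist()
    return [regions[i] for i in idx]


def grand_mean_bc(bc_tensor: np.ndarray) -> np.ndarray:
    """Nodal BC averaged over both subjects and sparsities.

    ``bc_tensor`` has shape (n_subjects, n_sparsities, n_nodes).  Because
    the cohort is complete, averaging sparsities first (mspBC) then
    subjects equals averaging subjects first (msjBC) then sparsities.
    """
    bc = np.asarray(bc_tensor, dtype=float)
    if bc.ndim != 3:
        raise ValueError("expected a (n_subjects, n_sparsities, n_nodes) tensor")
    return bc.mean(axis=(0, 1))


def hub_stability(
    bc_tensor: np.ndarray,
    regions,
    min_proportion: float = 0.2,
    ddof: int = 1,
) -> HubStabilityResult:
    """Hub-call proportions across sparsities and subjects.

    For each sparsity, hubs are called on the subject-mean BC (msjBC); the
    sparsity proportion of a region is the fraction of sparsities in which
    it is a hub.  For each subject, hubs are called on the sparsity-mean BC
    (mspBC); the subject proportion is the fraction of subjects for which
    it is a hub.
    """
    bc = np.asarray(bc_tensor, dtype=float)
    if bc.ndim != 3:
        raise ValueError("expected a (n_subjects, n_sparsities, n_nodes) tensor")
    n_subjects, n_sparsities, n_nodes = bc.shape
    regions = list(regions)
    if len(regions) != n_nodes:
        raise ValueError("region labels do not match tensor")

    sparsity_hits = np.zeros(n_nodes)
    for s in range(n_sparsities):
        hubs = identify_hubs(msj_bc(bc[:, s, :]), ddof=ddof)
        sparsity_hits[hubs] += 1
    subject_hits = np.zeros(n_nodes)
    for i in range(n_subjects):
        hubs = identify_hubs(msp_bc(bc[i]), ddof=ddof)
        subject_hits[hubs] += 1

    return HubStabilityResult(
        sparsity_proportion=pd.Series(sparsity_hits / n_sparsities, index=regions),
        subject_proportion=pd.Series(subject_hits / n_subjects, index=regions),
        min_proportion=min_proportion,
    )


def bc_similarity(vectors, method: str = "pearson") -> np.ndarray:
    """Pairwise similarity (proximity) matrix of nodal BC vectors.

    ``method`` is ``"pearson"`` (default), ``"cosine"`` or ``"euclidean"``
    (negative distances, so larger still means more similar).  Constant
    vectors are rejected for the correlation measure.
    """
    mat = np.asarray(vectors, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need at least two BC vectors")
    if method == "pearson":
        sd = mat.std(axis=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            raise ValueError(f"vector {flat[0]} is constant; correlation undefined")
        sim = np.corrcoef(mat)
        np.fill_diagonal(sim, 1.0)
        return sim
    if method == "cosine":
        norms = np.linalg.norm(mat, axis=1)
        if (norms == 0).any():
            raise ValueError("zero vector; cosine similarity undefined")
        return (mat @ mat.T) / np.outer(norms, norms)
    if method == "euclidean":
        diff = mat[:, None, :] - mat[None, :, :]
        return -np.sqrt((diff**2).sum(axis=2))
    raise ValueError(f"unknown similarity method {method!r}")
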