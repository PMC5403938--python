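"""Reading and writing of the package's on-disk formats.

Supported inputs are FreeSurfer ``?h.aparc.stats`` regional-statistics files
(the tabular output of surface reconstruction; the reconstruction itself is
out of scope) and cohort manifest CSVs.  Outputs are labeled TSV matrices
and BrainNet Viewer ``.node``/``.edge`` files for surface rendering.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .atlas import (
    FEATURE_NAMES,
    POSITIVE_FEATURES,
    AtlasDefinition,
    desikan_killiany,
    dk_centroids,
)

if TYPE_CHECKING:  # pragma: no cover
    from .connectome import BinaryNetwork
    from .features import SubjectFeatureMatrix


class AparcFormatError(ValueError):
    """The file does not follow the aparc.stats column layout."""


class AparcParseError(ValueError):
    """The file parses but its contents violate atlas expectations."""


class MatrixFormatError(ValueError):
    """A matrix file or matrix argument violates the format contract."""


@dataclass(frozen=True)
class RegionalFeatureTable:
    """Morphometric features of the 34 regions of one hemisphere.

    ``data`` is indexed by FreeSurfer ``StructName`` in canonical
    (alphabetical) order with the nine feature columns in canonical order.
    """

    hemisphere: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.hemisphere not in ("lh", "rh"):
            raise ValueError(f"hemisphere must be 'lh' or 'rh', got {self.hemisphere!r}")


def read_aparc_stats(
    path: str | Path, hemisphere: str, atlas: AtlasDefinition | None = None
) -> RegionalFeatureTable:
    """Parse a FreeSurfer ``?h.aparc.stats`` file into a feature table.

    Parsing is column-name driven via the ``# ColHeaders`` line, so any
    column permutation of a valid file yields an identical table; unknown
    extra columns are ignored.

    Parameters
    ----------
    path
        Path to the stats file.
    hemisphere
        ``"lh"`` or ``"rh"``; which hemisphere the file is expected to hold.
    atlas
        Parcellation to validate against (default: Desikan-Killiany).

    Raises
    ------
    AparcFormatError
        If the ``ColHeaders`` line is absent or required columns are missing.
    AparcParseError
        If regions are missing/unknown or cells are non-numeric/non-positive.
    """
    atlas = atlas or desikan_killiany()
    if hemisphere not in ("lh", "rh"):
        raise ValueError(f"hemisphere must be 'lh' or 'rh', got {hemisphere!r}")
    path = Path(path)
    colheaders: list[str] | None = None
    rows: list[list[str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.startswith("ColHeaders"):
                colheaders = body.split()[1:]
            continue
        rows.append(stripped.split())
    if colheaders is None:
        raise AparcFormatError(f"{path}: no '# ColHeaders' line found")
    missing_cols = [c for c in ("StructName", *FEATURE_NAMES) if c not in colheaders]
    if missing_cols:
        raise AparcFormatError(f"{path}: missing columns {missing_cols}")

    raw = pd.DataFrame(rows, columns=colheaders)
    table = raw.set_index("StructName")[list(FEATURE_NAMES)]
    for col in FEATURE_NAMES:
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = table.index[bad][0]
            raise AparcParseError(
                f"{path}: non-numeric value {table.loc[row, col]!r} "
                f"in row {row!r}, column {col!r}"
            )
        table[col] = converted

    expected = atlas.structnames(hemisphere)
    missing = sorted(set(expected) - set(table.index))
    if missing:
        raise AparcParseError(f"{path}: missing regions {missing}")
    unknown = sorted(set(table.index) - set(expected))
    if unknown:
        raise AparcParseError(f"{path}: unknown regions {unknown}")
    if table.index.has_duplicates:
        dups = sorted(table.index[table.index.duplicated()])
        raise AparcParseError(f"{path}: duplicated regions {dups}")
    table = table.loc[expected]

    for col in POSITIVE_FEATURES:
        if (table[col] <= 0).any():
            row = table.index[table[col] <= 0][0]
            raise AparcParseError(
                f"{path}: {col} must be strictly positive, got "
                f"{table.loc[row, col]} in row {row!r}"
            )
    return RegionalFeatureTable(hemisphere=hemisphere, data=table)


def assemble_subject_features(
    lh: RegionalFeatureTable,
    rh: RegionalFeatureTable,
    atlas: AtlasDefinition | None = None,
    subject_id: str = "subject",
    session_id: int = 1,
) -> "SubjectFeatureMatrix":
    """Stack two hemisphere tables into a 68 x 9 subject feature matrix."""
    from .features import SubjectFeatureMatrix

    atlas = atlas or desikan_killiany()
    if lh.hemisphere == rh.hemisphere:
        raise ValueError(f"both tables tagged {lh.hemisphere!r}; need lh and rh")
    if lh.hemisphere != "lh":
        raise ValueError("first argument must be the lh table")
    lh_part = lh.data.copy()
    lh_part.index = ["lh_" + n for n in lh_part.index]
    rh_part = rh.data.copy()
    rh_part.index = ["rh_" + n for n in rh_part.index]
    data = pd.concat([lh_part, rh_part]).loc[list(atlas.region_names)]
    return SubjectFeatureMatrix(
        subject_id=subject_id, session_id=session_id, data=data
    )


def split_by_hemisphere(
    matrix: "SubjectFeatureMatrix",
) -> tuple[RegionalFeatureTable, RegionalFeatureTable]:
    """Inverse of :func:`assemble_subject_features`."""
    parts = []
    for hemi in ("lh", "rh"):
        mask = [r.startswith(hemi + "_") for r in matrix.data.index]
        block = matrix.data.loc[mask].copy()
        block.index = pd.Index(
            [r.split("_", 1)[1] for r in block.index], name="StructName"
        )
        parts.append(RegionalFeatureTable(hemisphere=hemi, data=block))
    return parts[0], parts[1]


def write_matrix(matrix: pd.DataFrame, path: str | Path, atol: float = 1e-8) -> None:
    """Write a labeled square symmetric matrix as TSV.

    Round-tripping through :func:`read_matrix` is lossless to 1e-12.
    """
    if not isinstance(matrix, pd.DataFrame):
        raise MatrixFormatError("matrix must be a labeled DataFrame")
    if matrix.shape[0] != matrix.shape[1]:
        raise MatrixFormatError(f"matrix must be square, got {matrix.shape}")
    if list(matrix.index) != list(matrix.columns):
        raise MatrixFormatError("row and column labels must match")
    values = matrix.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=atol, rtol=0.0):
        raise MatrixFormatError("matrix is not symmetric")
    matrix.to_csv(path, sep="\t", float_format="%.17g", index_label="region")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled TSV matrix written by :func:`write_matrix`."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index.name = None
    if table.shape[0] != table.shape[1] or list(table.index) != list(table.columns):
        raise MatrixFormatError(f"{path}: not a labeled square matrix")
    return table


@dataclass(frozen=True)
class CohortManifest:
    """Locations of each (subject, session) pair of hemisphere stats files."""

    records: pd.DataFrame  # columns: subject_id, session_id, lh_path, rh_path

    REQUIRED = ("subject_id", "session_id", "lh_path", "rh_path")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        key = self.records[["subject_id", "session_id"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate manifest entry for subject "
                f"{dup['subject_id']!r} session {dup['session_id']!r}"
            )

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.records["subject_id"]))

    def require_two_sessions(self) -> None:
        """Raise unless every subject has exactly sessions 1 and 2."""
        for subject, group in self.records.groupby("subject_id", sort=False):
            sessions = sorted(group["session_id"].astype(int))
            if sessions != [1, 2]:
                raise ValueError(
                    f"subject {subject!r} has sessions {sessions}, expected [1, 2]"
                )


def read_manifest(path: str | Path) -> CohortManifest:
    return CohortManifest(records=pd.read_csv(path))


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.records.to_csv(path, index=False)


def load_cohort(
    manifest: CohortManifest, atlas: AtlasDefinition | None = None
) -> list["SubjectFeatureMatrix"]:
    """Read every (subject, session) feature matrix listed in a manifest."""
    out = []
    for rec in manifest.records.itertuples(index=False):
        lh = read_aparc_stats(rec.lh_path, "lh", atlas=atlas)
        rh = read_aparc_stats(rec.rh_path, "rh", atlas=atlas)
        out.append(
            assemble_subject_features(
                lh, rh, atlas=atlas,
                subject_id=str(rec.subject_id), session_id=int(rec.session_id),
            )
        )
    return out


def export_brainnet(
    node_values: Sequence[float],
    net: "BinaryNetwork",
    node_path: str | Path,
    edge_path: str | Path,
    atlas: AtlasDefinition | None = None,
    coords: pd.DataFrame | None = None,
    node_colors: Sequence[float] | None = None,
) -> None:
    """Write BrainNet Viewer ``.node`` and ``.edge`` files.

    The ``.node`` file has six whitespace-delimited columns
    (x, y, z, color, size, label); node size carries ``node_values``
    (e.g. betweenness).  The ``.edge`` file is the binary adjacency matrix.

    ``coords`` defaults to the bundled approximate centroid table and must
    cover every atlas region.
    """
    atlas = atlas or desikan_killiany()
    coords = coords if coords is not None else dk_centroids()
    node_values = np.asarray(node_values, dtype=float)
    if node_values.shape != (atlas.n_regions,):
        raise ValueError(
            f"need {atlas.n_regions} node values, got {node_values.shape}"
        )
    missing = [r for r in atlas.region_names if r not in coords.index]
    if missing:
        raise ValueError(f"coordinates missing for regions {missing}")
    colors = (
        np.ones(atlas.n_regions)
        if node_colors is None
        else np.asarray(node_colors, dtype=float)
    )
    buf = io.StringIO()
    for i, region in enumerate(atlas.region_names):
        x, y, z = coords.loc[region, ["x", "y", "z"]]
        buf.write(f"{x:.1f}\t{y:.1f}\t{z:.1f}\t{colors[i]:g}\t{node_values[i]:g}\t{region}\n")
    Path(node_path).write_text(buf.getvalue())
    np.savetxt(edge_path, net.adjacency, fmt="%d", delimiter="\t")
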