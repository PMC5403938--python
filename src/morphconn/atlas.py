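"""Cortical atlas definition used to anchor node identity and ordering.

Every matrix and network in this package is indexed by a fixed, canonical
region order: all left-hemisphere regions first, then all right-hemisphere
regions, each hemisphere alphabetical by FreeSurfer ``StructName``.  The
bundled atlas is the Desikan-Killiany parcellation (34 gyral regions per
hemisphere, 68 network nodes).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd

#: Canonical morphometric feature columns, in ``aparc.stats`` order.
FEATURE_NAMES: tuple[str, ...] = (
    "NumVert",
    "SurfArea",
    "GrayVol",
    "ThickAvg",
    "ThickStd",
    "MeanCurv",
    "GausCurv",
    "FoldInd",
    "CurvInd",
)

#: Units of each feature as produced by surface reconstruction (native space).
FEATURE_UNITS: dict[str, str] = {
    "NumVert": "count",
    "SurfArea": "mm^2",
    "GrayVol": "mm^3",
    "ThickAvg": "mm",
    "ThickStd": "mm",
    "MeanCurv": "mm^-1",
    "GausCurv": "mm^-2",
    "FoldInd": "dimensionless",
    "CurvInd": "dimensionless",
}

#: Features whose values must be strictly positive in a valid table.
POSITIVE_FEATURES: tuple[str, ...] = ("NumVert", "SurfArea", "GrayVol")


@dataclass(frozen=True)
class AtlasDefinition:
    """An ordered cortical parcellation.

    Parameters
    ----------
    region_names
        Full region labels (``lh_``/``rh_`` prefixed), in canonical order.
    hemispheres
        Per-region hemisphere tag, ``"lh"`` or ``"rh"``.
    """

    region_names: tuple[str, ...]
    hemispheres: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.region_names) != len(self.hemispheres):
            raise ValueError("region_names and hemispheres must align")
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("atlas region names must be unique")
        for name, hemi in zip(self.region_names, self.hemispheres):
            if hemi not in ("lh", "rh"):
                raise ValueError(f"bad hemisphere tag {hemi!r}")
            if not name.startswith(hemi + "_"):
                raise ValueError(f"region {name!r} does not match tag {hemi!r}")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def structnames(self, hemisphere: str) -> list[str]:
        """FreeSurfer ``StructName`` values of one hemisphere, atlas order."""
        return [
            n.split("_", 1)[1]
            for n, h in zip(self.region_names, self.hemispheres)
            if h == hemisphere
        ]

    def index_of(self, region: str) -> int:
        try:
            return self.region_names.index(region)
        except ValueError:
            raise KeyError(f"region {region!r} not in atlas") from None


def _load_data_table(filename: str) -> pd.DataFrame:
    with resources.files("morphconn.data").joinpath(filename).open() as fh:
        return pd.read_csv(fh, sep="\t")


@lru_cache(maxsize=1)
def desikan_killiany() -> AtlasDefinition:
    """The bundled 68-region Desikan-Killiany atlas in canonical order."""
    tab = _load_data_table("dk_atlas.tsv")
    atlas = AtlasDefinition(
        region_names=tuple(tab["region"]), hemispheres=tuple(tab["hemisphere"])
    )
    if atlas.n_regions != 68:
        raise RuntimeError("bundled atlas table is corrupt")
    return atlas


@lru_cache(maxsize=1)
def dk_centroids() -> pd.DataFrame:
    """Approximate MNI-space centroids (mm) of the Desikan-Killiany regions.

    These coordinates are a visualization convenience for surface-viewer
    export; they are hand-rounded approximations, not subject-specific or
    template-exact positions.
    """
    tab = _load_data_table("dk_centroids.tsv").set_index("region")
    return tab[["x", "y", "z"]].astype(float)
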