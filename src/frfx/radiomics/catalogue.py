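"""The frozen 106-feature catalogue and whole-region extraction.

Catalogue composition (19 first-order + 16 shape + 22 GLCM + 16 GLRLM +
16 GLSZM + 12 GLDM + 5 NGTDM = 106) is versioned in ``catalogue.json``; the
canonical feature order is the file's order and never changes within a
catalogue version.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import ndimage

from ..types import ImageVolume, Label, SegMaskSet
from .base import discretize
from .firstorder import first_order_features
from .shape import shape_features
from .texture import texture_features

__all__ = [
    "CATALOGUE_VERSION",
    "catalogue_names",
    "AnalysisMask",
    "flr_analysis_mask",
    "FeatureVector",
    "extract_catalogue",
]

CATALOGUE_VERSION = "1.0"


def catalogue_names() -> list[str]:
    """The 106 canonical feature names, in extraction order."""
    with resources.files("frfx.radiomics").joinpath("catalogue.json").open() as fh:
        data = json.load(fh)
    names: list[str] = []
    for family in data["families"]:
        names.extend(family["features"])
    return names


@dataclass
class AnalysisMask:
    """Boolean analysis region: FLR parenchyma minus vessels and tumour."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    case_id: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("analysis mask must be 3-D")
        if not self.mask.any():
            raise ValueError("no analysable FLR parenchyma")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def flr_analysis_mask(
    seg: SegMaskSet,
    case_id: str = "",
    timepoint: str = "",
    exclusion_margin_voxels: int = 0,
) -> AnalysisMask:
    """FLR parenchyma with vascular and tumour regions removed.

    ``exclusion_margin_voxels`` dilates the vessel/tumour exclusion by that
    many voxels (default 0) to guard against partial-volume contamination.
    """
    flr = seg.observed == Label.FLR
    if not flr.any():
        raise ValueError("no analysable FLR parenchyma: FLR label absent")
    excl = (seg.observed == Label.VESSEL) | (seg.observed == Label.TUMOUR)
    if exclusion_margin_voxels > 0 and excl.any():
        excl = ndimage.binary_dilation(excl, iterations=exclusion_margin_voxels)
    mask = flr & ~excl
    if not mask.any():
        raise ValueError("no analysable FLR parenchyma after exclusions")
    return AnalysisMask(mask, seg.spacing, case_id, timepoint)


@dataclass
class FeatureVector:
    """Ordered 106-feature vector with provenance."""

    names: list[str]
    values: np.ndarray
    case_id: str = ""
    timepoint: str = ""
    region_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != self.values.size:
            raise ValueError("names/values length mismatch")

    def __len__(self) -> int:
        return self.values.size

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def extract_catalogue(
    volume: ImageVolume,
    analysis_mask: AnalysisMask,
    bin_width: float = 25.0,
) -> FeatureVector:
    """Extract the full 106-feature catalogue for one region.

    First-order features use raw intensities (entropy/uniformity on the
    fixed-width histogram anchored at the region minimum); shape features use
    the binary mask and spacing; texture families use the discretised grid.
    """
    mask = analysis_mask.mask
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    values = volume.voxels[mask].astype(np.float64)
    fo = first_order_features(values, bin_width, volume.voxel_volume_mm3)
    sh = shape_features(mask, volume.spacing)
    bins, hist = discretize(values, bin_width)
    levels = np.zeros(mask.shape, dtype=np.int64)
    levels[mask] = bins
    tx = texture_features(levels, mask, int(bins.max()))
    feats = {**fo, **sh, **tx}
    names = catalogue_names()
    missing = set(names) - set(feats)
    if missing:  # pragma: no cover - catalogue/code drift guard
        raise RuntimeError(f"catalogue names not computed: {sorted(missing)}")
    return FeatureVector(
        names=names,
        values=np.array([feats[n] for n in names]),
        case_id=analysis_mask.case_id,
        timepoint=analysis_mask.timepoint,
    )
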