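"""Core containers for CT-like volumes, segmentation masks and phantom cases.

All spatial data live on regular 3-D grids with physical voxel spacing in mm.
Intensities are Hounsfield-unit-like floats. Segmentations use two aligned
integer grids: the *observed* labels a clinical workstation would produce
(liver / future-liver-remnant parenchyma / vessel / tumour) and, for synthetic
phantoms only, a *truth* grid splitting the FLR parenchyma into functional
tissue and oedema/congestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

import numpy as np

__all__ = [
    "Label",
    "Truth",
    "Technique",
    "PhlfGrade",
    "ImageVolume",
    "SegMaskSet",
    "PatientMeta",
    "PhantomCase",
]


class Label(IntEnum):
    """Observed segmentation labels."""

    BACKGROUND = 0
    LIVER = 1          # liver parenchyma outside the future remnant
    FLR = 2            # future-liver-remnant parenchyma
    VESSEL = 3
    TUMOUR = 4


class Truth(IntEnum):
    """Phantom ground-truth labels, defined only on FLR parenchyma."""

    NA = 0
    FUNCTIONAL = 1
    OEDEMA = 2


class Technique:
    ALPPS = "ALPPS"
    PVE = "PVE"
    ALL = (ALPPS, PVE)


class PhlfGrade:
    """ISGLS post-hepatectomy liver-failure grades; >= B is the severe endpoint."""

    NONE = "none"
    A = "A"
    B = "B"
    C = "C"
    ALL = (NONE, A, B, C)

    @staticmethod
    def is_severe(grade: str) -> bool:
        return grade in (PhlfGrade.B, PhlfGrade.C)


@dataclass
class ImageVolume:
    """A 3-D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        HU-like intensities; finite floats.
    spacing : tuple of 3 floats
        Voxel edge length along each axis, mm.
    origin : tuple of 3 floats
        Physical position of voxel (0, 0, 0), mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got {self.voxels.ndim}-D")
        if min(self.voxels.shape) < 8:
            raise ValueError("grid dimensions must be >= 8 per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive floats (mm)")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must all be finite")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0


@dataclass
class SegMaskSet:
    """Aligned observed (and optionally truth) label grids for one volume."""

    observed: np.ndarray
    spacing: tuple[float, float, float]
    truth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=np.int16)
        if self.observed.ndim != 3:
            raise ValueError("observed mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        valid = {int(v) for v in Label}
        present = set(np.unique(self.observed).tolist())
        if not present <= valid:
            raise ValueError(f"invalid observed labels: {sorted(present - valid)}")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=np.int16)
            if self.truth.shape != self.observed.shape:
                raise ValueError("truth grid shape differs from observed")
            tpresent = set(np.unique(self.truth).tolist())
            if not tpresent <= {int(v) for v in Truth}:
                raise ValueError(f"invalid truth labels: {sorted(tpresent)}")
            if np.any((self.truth != Truth.NA) & (self.observed != Label.FLR)):
                raise ValueError("truth labels defined outside FLR parenchyma")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.observed.shape

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def label_mask(self, label: int) -> np.ndarray:
        return self.observed == int(label)


@dataclass
class PatientMeta:
    """Per-case clinical metadata used by volumetry and outcome analysis."""

    case_id: str
    height_cm: float
    weight_kg: float
    technique: str
    days_elapsed: int
    phlf_grade: str = PhlfGrade.NONE

    def __post_init__(self) -> None:
        if not 120 <= self.height_cm <= 220:
            raise ValueError(f"height_cm {self.height_cm} outside [120, 220]")
        if not 30 <= self.weight_kg <= 200:
            raise ValueError(f"weight_kg {self.weight_kg} outside [30, 200]")
        if self.technique not in Technique.ALL:
            raise ValueError(f"unknown technique {self.technique!r}")
        if self.days_elapsed < 1:
            raise ValueError("days_elapsed must be >= 1")
        if self.phlf_grade not in PhlfGrade.ALL:
            raise ValueError(f"unknown PHLF grade {self.phlf_grade!r}")

    @property
    def phlf_severe(self) -> bool:
        return PhlfGrade.is_severe(self.phlf_grade)


@dataclass
class PhantomCase:
    """One synthetic patient: paired pre/post volumes, masks and ground truth.

    ``truth_oedema_fraction`` is the requested share (theta) of post-modulation
    FLR parenchyma that is oedema/congestion; ``truth_frl_cc`` and
    ``truth_frfx_cc`` are the voxel-counted anatomic and functional remnant
    volumes of the post study, so ``truth_frfx_cc ~= (1 - theta) * truth_frl_cc``
    to within one voxel.
    """

    meta: PatientMeta
    pre: tuple[Optional[ImageVolume], SegMaskSet]
    post: tuple[Optional[ImageVolume], SegMaskSet]
    truth_oedema_fraction: float
    truth_frl_cc: float
    truth_frfx_cc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.truth_oedema_fraction <= 1.0:
            raise ValueError("truth_oedema_fraction outside [0, 1]")
        voxcc = self.post[1].voxel_volume_cc
        expect = (1.0 - self.truth_oedema_fraction) * self.truth_frl_cc
        if abs(self.truth_frfx_cc - expect) > self.truth_frl_cc * 1e-6 + voxcc:
            raise ValueError(
                "truth volumes inconsistent: frfx != (1-theta)*frl within a voxel"
            )
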