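"""Liver-remnant volumetry.

Implements the standard volumetric indices used to plan staged hepatectomy:

- ``FRLV% = FRL / (TLV - TV) * 100`` — anatomic remnant share of tumour-free
  liver (FRL: future liver remnant; TLV: total liver volume; TV: tumour
  volume, both measured on the pre-modulation study).
- ``FRFxV% = FRFx / (TLV - TV) * 100`` — same with the *functional* remnant
  (true hypertrophy, excluding oedema/congestion) in the numerator.
- ``iFRL% / iFRFx% = (post - pre) / pre * 100`` — relative growth.
- ``BSA = sqrt(height_cm * weight_kg / 3600)`` (Mosteller), m².
- ``sFLR% = FRL / (-794.41 + 1267.28 * BSA) * 100`` — remnant standardised to
  the BSA-estimated total liver volume.
- ``KGR = (FRLV%_post - FRLV%_pre) / days`` — kinetic growth rate, percentage
  points per day.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from .types import Label, PatientMeta, PhantomCase

__all__ = [
    "VolumetryRecord",
    "mask_volume_cc",
    "frlv_pct",
    "frfxv_pct",
    "growth_pct",
    "bsa_m2",
    "sflr_pct",
    "kgr_pct_per_day",
    "compute_volumetry",
    "volumetry_table",
]

# BSA-standardised total-liver-volume estimate: -794.41 + 1267.28 * BSA (mL).
_STLV_INTERCEPT = -794.41
_STLV_SLOPE = 1267.28
#: BSA below this makes the standardised TLV estimate non-positive.
MIN_BSA_M2 = -_STLV_INTERCEPT / _STLV_SLOPE


@dataclass
class VolumetryRecord:
    """All volumetric indices for one case (volumes cc, percentages 0-100+)."""

    case_id: str
    tlv_cc: float
    tv_cc: float
    frl_pre_cc: float
    frl_post_cc: float
    frfx_pre_cc: float
    frfx_post_cc: float
    frlv_pre_pct: float
    frlv_post_pct: float
    frfxv_pre_pct: float
    frfxv_post_pct: float
    ifrl_pct: float
    ifrfx_pct: float
    bsa_m2: float
    sflr_pre_pct: float
    sflr_post_pct: float
    kgr_pct_per_day: float


def mask_volume_cc(mask_grid: np.ndarray, label: int, spacing_mm: Sequence[float]) -> float:
    """Volume (cc) of all voxels carrying ``label``."""
    spacing = [float(s) for s in spacing_mm]
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    count = int(np.count_nonzero(np.asarray(mask_grid) == label))
    return count * spacing[0] * spacing[1] * spacing[2] / 1000.0


def frlv_pct(frl_cc: float, tlv_cc: float, tv_cc: float) -> float:
    """Anatomic remnant as % of tumour-free total liver volume."""
    denom = tlv_cc - tv_cc
    if denom <= 0:
        raise ValueError(f"TLV - TV must be positive, got {denom:g} cc")
    return frl_cc / denom * 100.0


def frfxv_pct(frfx_cc: float, tlv_cc: float, tv_cc: float) -> float:
    """Functional remnant as % of tumour-free total liver volume."""
    return frlv_pct(frfx_cc, tlv_cc, tv_cc)


def growth_pct(post_cc: float, pre_cc: float) -> float:
    """Relative volume change, %; negative values mean shrinkage."""
    if pre_cc <= 0:
        raise ValueError("pre-modulation volume must be positive")
    return (post_cc - pre_cc) / pre_cc * 100.0


def bsa_m2(height_cm: float, weight_kg: float) -> float:
    """Mosteller body surface area, m²."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return float(np.sqrt(height_cm * weight_kg / 3600.0))


def sflr_pct(frl_cc: float, bsa: float) -> float:
    """Remnant standardised to the BSA-estimated total liver volume, %."""
    denom = _STLV_INTERCEPT + _STLV_SLOPE * bsa
    if denom <= 0:
        raise ValueError(
            f"standardised TLV non-positive: BSA must exceed {MIN_BSA_M2:.5f} m²"
        )
    return frl_cc / denom * 100.0


def kgr_pct_per_day(
    frlv_post: float, frlv_pre: float, days_elapsed: float
) -> float:
    """Kinetic growth rate: FRLV percentage points gained per day."""
    if days_elapsed < 1:
        raise ValueError("days_elapsed must be >= 1")
    return (frlv_post - frlv_pre) / days_elapsed


def compute_volumetry(
    meta: PatientMeta,
    tlv_cc: float,
    tv_cc: float,
    frl_pre_cc: float,
    frl_post_cc: float,
    frfx_pre_cc: float,
    frfx_post_cc: float,
    kgr_basis: str = "frlv",
) -> VolumetryRecord:
    """Assemble the full volumetry record from measured component volumes.

    TLV and TV come from the pre-modulation study; the (TLV - TV) normaliser
    is held fixed across timepoints so pre/post percentages are comparable.
    ``kgr_basis`` selects whether KGR is computed on FRLV ("frlv", default)
    or on sFLR ("sflr") percentage points.
    """
    if min(tlv_cc, tv_cc, frl_pre_cc, frl_post_cc, frfx_pre_cc, frfx_post_cc) < 0:
        raise ValueError("volumes must be non-negative")
    if frfx_pre_cc > frl_pre_cc * (1 + 1e-9) or frfx_post_cc > frl_post_cc * (1 + 1e-9):
        raise ValueError("functional remnant cannot exceed anatomic remnant")
    bsa = bsa_m2(meta.height_cm, meta.weight_kg)
    frlv_pre = frlv_pct(frl_pre_cc, tlv_cc, tv_cc)
    frlv_post = frlv_pct(frl_post_cc, tlv_cc, tv_cc)
    if kgr_basis == "frlv":
        kgr = kgr_pct_per_day(frlv_post, frlv_pre, meta.days_elapsed)
    elif kgr_basis == "sflr":
        kgr = kgr_pct_per_day(
            sflr_pct(frl_post_cc, bsa), sflr_pct(frl_pre_cc, bsa), meta.days_elapsed
        )
    else:
        raise ValueError(f"kgr_basis must be 'frlv' or 'sflr', got {kgr_basis!r}")
    return VolumetryRecord(
        case_id=meta.case_id,
        tlv_cc=tlv_cc,
        tv_cc=tv_cc,
        frl_pre_cc=frl_pre_cc,
        frl_post_cc=frl_post_cc,
        frfx_pre_cc=frfx_pre_cc,
        frfx_post_cc=frfx_post_cc,
        frlv_pre_pct=frlv_pre,
        frlv_post_pct=frlv_post,
        frfxv_pre_pct=frfxv_pct(frfx_pre_cc, tlv_cc, tv_cc),
        frfxv_post_pct=frfxv_pct(frfx_post_cc, tlv_cc, tv_cc),
        ifrl_pct=growth_pct(frl_post_cc, frl_pre_cc),
        ifrfx_pct=growth_pct(frfx_post_cc, frfx_pre_cc),
        bsa_m2=bsa,
        sflr_pre_pct=sflr_pct(frl_pre_cc, bsa),
        sflr_post_pct=sflr_pct(frl_post_cc, bsa),
        kgr_pct_per_day=kgr,
    )


def case_component_volumes(case: PhantomCase) -> dict[str, float]:
    """Measure TLV, TV and anatomic FRL volumes (cc) from a case's masks.

    TLV counts every liver label (parenchyma, vessels, tumour) on the pre
    study; FRL counts FLR *parenchyma* only, matching the truth convention.
    """
    pre_seg = case.pre[1]
    post_seg = case.post[1]
    vox = pre_seg.voxel_volume_cc
    obs = pre_seg.observed
    tlv = float(np.count_nonzero(obs)) * vox  # labels 1..4 are all liver tissue
    tv = float(np.count_nonzero(obs == Label.TUMOUR)) * vox
    frl_pre = float(np.count_nonzero(obs == Label.FLR)) * vox
    frl_post = float(np.count_nonzero(post_seg.observed == Label.FLR)) * vox
    return {"tlv_cc": tlv, "tv_cc": tv, "frl_pre_cc": frl_pre, "frl_post_cc": frl_post}


def volumetry_for_case(
    case: PhantomCase,
    frfx_pre_cc: Optional[float] = None,
    frfx_post_cc: Optional[float] = None,
    kgr_basis: str = "frlv",
) -> VolumetryRecord:
    """Volumetry record for a phantom case.

    Functional volumes default to the ground truth (pre FLR is entirely
    functional; post from the truth mask); pass classifier estimates to
    evaluate the texture pipeline instead.
    """
    comp = case_component_volumes(case)
    if frfx_pre_cc is None:
        frfx_pre_cc = comp["frl_pre_cc"]
    if frfx_post_cc is None:
        frfx_post_cc = case.truth_frfx_cc
    return compute_volumetry(
        case.meta,
        comp["tlv_cc"],
        comp["tv_cc"],
        comp["frl_pre_cc"],
        comp["frl_post_cc"],
        min(frfx_pre_cc, comp["frl_pre_cc"]),
        min(frfx_post_cc, comp["frl_post_cc"]),
        kgr_basis=kgr_basis,
    )


def volumetry_table(records: Sequence[VolumetryRecord]):
    """One row per VolumetryRecord, columns named exactly as the fields."""
    import pandas as pd

    return pd.DataFrame([asdict(r) for r in records])
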