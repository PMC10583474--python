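"""Synthetic hepatic-modulation phantoms.

Generates paired pre/post CT-like volumes for a liver undergoing regenerative
modulation (ALPPS or portal-vein embolisation). The liver is an ellipsoid on a
regular grid; the future liver remnant (FLR) is the portion on one side of a
plane, which moves between the pre and post studies so the remnant grows by a
factor (1 + g). A fraction theta of the post-modulation FLR parenchyma is
oedema/congestion, placed as an outer rim (congestion is peripheral in rapid
regeneration), so anatomic growth overstates functional growth exactly as the
clinical problem poses it. Tissue classes get distinct intensity textures:
correlated Gaussian random fields with class-specific mean, spread and
correlation length. A logistic outcome model ties the probability of severe
post-hepatectomy liver failure (PHLF grade >= B) to the *true* functional
remnant percentage, decreasing in it.

Every generator is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .types import (
    ImageVolume,
    Label,
    PatientMeta,
    PhantomCase,
    PhlfGrade,
    SegMaskSet,
    Technique,
    Truth,
)

__all__ = [
    "TissueTexture",
    "DEFAULT_TEXTURES",
    "ZERO_CONTRAST_TEXTURES",
    "OutcomeCoeffs",
    "CaseParams",
    "CohortParams",
    "GeometryInfeasibleError",
    "make_liver_geometry",
    "synth_texture",
    "assign_phlf",
    "generate_case",
    "generate_cohort",
    "cohort_manifest",
]

# Default desk-scale grid: 64^3 voxels at 2.5 mm isotropic -> voxel = 15.625 mm^3.
DEFAULT_SHAPE = (64, 64, 64)
DEFAULT_SPACING = (2.5, 2.5, 2.5)

# Mild ellipsoid aspect so ~1.7 L livers still fit the 160 mm grid box.
_ASPECT = (1.0, 0.96, 0.92)


class GeometryInfeasibleError(ValueError):
    """Requested phantom geometry cannot be realised on the grid."""


@dataclass(frozen=True)
class TissueTexture:
    """Intensity model of one tissue class: mean HU, spread, correlation length.

    ``corr_len`` is the Gaussian-smoothing scale (voxels) applied to white
    noise before per-class renormalisation to unit variance, so each class's
    sampled voxels have mean ``mu`` and standard deviation ``sigma`` exactly.
    """

    mu: float
    sigma: float
    corr_len: float

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.corr_len < 0:
            raise ValueError("sigma and corr_len must be >= 0")


#: Contrast-CT-plausible defaults. Oedema is hypodense and smoother-grained
#: than functioning parenchyma; vessels are bright (contrast phase).
DEFAULT_TEXTURES: dict[str, TissueTexture] = {
    "background": TissueTexture(-100.0, 15.0, 1.0),
    "liver": TissueTexture(105.0, 12.0, 1.0),
    "functional": TissueTexture(105.0, 12.0, 1.0),
    "oedema": TissueTexture(70.0, 20.0, 2.0),
    "vessel": TissueTexture(180.0, 10.0, 0.5),
    "tumour": TissueTexture(45.0, 15.0, 1.5),
}

#: Null phantom: oedema indistinguishable from functional tissue.
ZERO_CONTRAST_TEXTURES: dict[str, TissueTexture] = {
    **DEFAULT_TEXTURES,
    "oedema": DEFAULT_TEXTURES["functional"],
}


@dataclass(frozen=True)
class OutcomeCoeffs:
    """Logistic link from true functional-remnant percentage to severe PHLF.

    P(PHLF >= B) = expit(a0 - a1 * FRFxV%); a1 >= 0 keeps the clinically
    observed direction (smaller functional remnant -> higher failure risk).
    Severe cases split grade C vs B with ``p_grade_c_given_severe``; non-severe
    split grade A vs none with ``p_grade_a_given_mild``.
    """

    a0: float = 2.0
    a1: float = 0.08
    p_grade_c_given_severe: float = 1.0 / 3.0
    p_grade_a_given_mild: float = 0.22

    def __post_init__(self) -> None:
        if self.a1 < 0:
            raise ValueError(
                "a1 < 0 would make failure risk increase with functional volume"
            )
        for p in (self.p_grade_c_given_severe, self.p_grade_a_given_mild):
            if not 0.0 <= p <= 1.0:
                raise ValueError("grade-split probabilities must lie in [0, 1]")

    def p_severe(self, frfxv_pct: float) -> float:
        from scipy.special import expit

        return expit(self.a0 - self.a1 * np.asarray(frfxv_pct, dtype=float))


@dataclass(frozen=True)
class CaseParams:
    """Deterministic inputs for one phantom case."""

    technique: str = Technique.ALPPS
    tlv_cc: float = 1400.0
    pre_flr_fraction: float = 0.30
    growth: float = 1.2                    # g: post FLR = pre FLR * (1 + g)
    theta: float = 0.45                    # oedema share of post FLR parenchyma
    tumour_cc: float = 40.0
    vessel_density: float = 0.03
    grid_shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING
    textures: dict[str, TissueTexture] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURES)
    )
    outcome: OutcomeCoeffs = field(default_factory=OutcomeCoeffs)
    render_texture: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.growth < 0:
            raise ValueError("growth g must be >= 0")
        if self.technique not in Technique.ALL:
            raise ValueError(f"unknown technique {self.technique!r}")


@dataclass(frozen=True)
class CohortParams:
    """Sampling distributions for a cohort, by technique.

    Defaults emulate the study conditions: 24 cases (11 ALPPS / 13 PVE);
    rapid-but-oedematous ALPPS hypertrophy (growth ~1.2, theta ~0.45 on
    average) versus slower, cleaner PVE hypertrophy (growth ~0.7, theta ~0.2);
    reassessment after 7-22 days (ALPPS) or 36-106 days (PVE).
    """

    n: int = 24
    n_alpps: int = 11
    theta_mean: dict[str, float] = field(
        default_factory=lambda: {Technique.ALPPS: 0.45, Technique.PVE: 0.20}
    )
    theta_concentration: float = 10.0      # Beta(m*k, (1-m)*k)
    growth_mean: dict[str, float] = field(
        default_factory=lambda: {Technique.ALPPS: 1.2, Technique.PVE: 0.7}
    )
    growth_shape: float = 9.0              # Gamma shape; sd = mean / 3
    days_range: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {Technique.ALPPS: (7, 22), Technique.PVE: (36, 106)}
    )
    pre_flr_mean: dict[str, float] = field(
        default_factory=lambda: {Technique.ALPPS: 0.30, Technique.PVE: 0.34}
    )
    pre_flr_sd: float = 0.05
    tlv_mean_cc: float = 1420.0
    tlv_sd_cc: float = 160.0
    tumour_log_median_cc: float = 35.0
    tumour_log_sigma: float = 0.45
    max_post_flr_fraction: float = 0.72    # keeps tumour placement feasible
    grid_shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING
    textures: dict[str, TissueTexture] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURES)
    )
    outcome: OutcomeCoeffs = field(default_factory=OutcomeCoeffs)
    vessel_density: float = 0.03
    render_texture: bool = True


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _grid_coords(shape, spacing):
    """Physical coordinates (mm) of voxel centres, grid-centred."""
    axes = [
        (np.arange(n, dtype=np.float32) - (n - 1) / 2.0) * s
        for n, s in zip(shape, spacing)
    ]
    return axes


def _ellipsoid_semiaxes(tlv_cc: float) -> tuple[float, float, float]:
    vol_mm3 = tlv_cc * 1000.0
    r0 = (vol_mm3 * 3.0 / (4.0 * math.pi * np.prod(_ASPECT))) ** (1.0 / 3.0)
    return tuple(r0 * a for a in _ASPECT)


def _flr_plane_offset(liver_x: np.ndarray, fraction: float) -> float:
    """Plane position (mm along axis 0) putting ~`fraction` of liver below it.

    liver_x are the axis-0 coordinates of liver voxels; FLR is x <= offset.
    Returns the mid-slice threshold whose cumulative count is closest.
    """
    xs, counts = np.unique(liver_x, return_counts=True)
    cum = np.cumsum(counts) / liver_x.size
    idx = int(np.argmin(np.abs(cum - fraction)))
    # threshold between this slice and the next so comparisons are unambiguous
    step = xs[1] - xs[0] if xs.size > 1 else 1.0
    return float(xs[idx] + 0.5 * step)


def _tumour_sphere(
    axes, semi, tumour_cc: float, min_x_mm: float, rng: np.random.Generator
):
    """Sphere of given volume inside the ellipsoid with all x >= min_x_mm."""
    r = (tumour_cc * 1000.0 * 3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    a, b, c = semi
    x_lo = min_x_mm + r
    x_hi = a - r - 2.5
    if x_hi < x_lo:
        raise GeometryInfeasibleError(
            f"geometry infeasible: tumour of {tumour_cc:.0f} cc does not fit in "
            f"the non-FLR side (needs centre x in [{x_lo:.1f}, {x_hi:.1f}] mm)"
        )
    x0 = float(rng.uniform(x_lo, x_hi))
    # small lateral jitter while keeping the sphere inside the ellipsoid
    lat = math.sqrt(max(0.0, 1.0 - (abs(x0) + r) ** 2 / a**2))
    jmax = max(0.0, 0.3 * min(b, c) * lat - 1.0)
    y0 = float(rng.uniform(-jmax, jmax))
    z0 = float(rng.uniform(-jmax, jmax))
    xg, yg, zg = np.meshgrid(*axes, indexing="ij", sparse=True)
    sphere = (xg - x0) ** 2 + (yg - y0) ** 2 + (zg - z0) ** 2 <= r**2
    return sphere


def _vessel_mask(
    liver: np.ndarray,
    axes,
    semi,
    density: float,
    spacing,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random cylinders (line segments with radius) covering ~density of liver."""
    vessels = np.zeros_like(liver, dtype=bool)
    if density <= 0:
        return vessels
    target = int(round(density * liver.sum()))
    a, b, c = semi
    n_covered = 0
    for _ in range(100):
        if n_covered >= target:
            break
        # segment from a hilar-ish start point outward
        p0 = rng.uniform(-0.3, 0.3, size=3) * np.array([a, b, c])
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(40.0, 90.0)
        p1 = p0 + direction * length
        radius = rng.uniform(2.0, 4.5)
        # rasterise only within the segment's bounding box (plus radius)
        lo = np.minimum(p0, p1) - radius
        hi = np.maximum(p0, p1) + radius
        sl = []
        for ax, l, h in zip(axes, lo, hi):
            i0 = int(np.searchsorted(ax, l))
            i1 = int(np.searchsorted(ax, h, side="right"))
            if i0 >= i1:
                sl = None
                break
            sl.append(slice(i0, i1))
        if sl is None:
            continue
        sl = tuple(sl)
        xg, yg, zg = np.meshgrid(
            axes[0][sl[0]], axes[1][sl[1]], axes[2][sl[2]], indexing="ij", sparse=True
        )
        d = p1 - p0
        dd = float(d @ d)
        px, py, pz = xg - p0[0], yg - p0[1], zg - p0[2]
        t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / dd, 0.0, 1.0)
        dist2 = (
            (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2
        )
        box = vessels[sl]
        new = (dist2 <= radius**2) & liver[sl]
        n_covered += int((new & ~box).sum())
        vessels[sl] = box | new
    return vessels


def _make_geometry_multi(
    grid_shape: Sequence[int],
    spacing_mm: Sequence[float],
    target_tlv_cc: float,
    target_flr_fractions: Sequence[float],
    tumour_cc: float,
    vessel_density: float,
    seed: int,
    barrier_fraction: Optional[float] = None,
) -> list[SegMaskSet]:
    """Shared-anatomy geometry for one or more FLR plane positions.

    Computes the liver ellipsoid, tumour and vessels once and cuts the FLR
    plane at each requested fraction, so a pre/post study pair shares its
    anatomy exactly and only the remnant plane moves.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    spacing_mm = tuple(float(s) for s in spacing_mm)
    for frac in target_flr_fractions:
        if not 0.0 < frac < 1.0:
            raise GeometryInfeasibleError(
                "geometry infeasible: FLR fraction must lie strictly in (0, 1) "
                "(an FLR region is required)"
            )
    grid_cc = np.prod(grid_shape) * np.prod(spacing_mm) / 1000.0
    if target_tlv_cc > 0.6 * grid_cc:
        raise GeometryInfeasibleError(
            f"geometry infeasible: target TLV {target_tlv_cc:.0f} cc exceeds "
            f"60% of the grid volume ({grid_cc:.0f} cc)"
        )
    rng = np.random.default_rng(seed)
    axes = _grid_coords(grid_shape, spacing_mm)
    semi = _ellipsoid_semiaxes(target_tlv_cc)
    jitter = rng.uniform(-1.0, 1.0, size=3)
    half_extent = [ax[-1] + 0.5 * s for ax, s in zip(axes, spacing_mm)]
    for s_i, j_i, h_i in zip(semi, jitter, half_extent):
        if s_i + abs(j_i) >= h_i:
            raise GeometryInfeasibleError(
                f"geometry infeasible: liver semi-axis {s_i:.1f} mm does not "
                f"fit the grid half-extent {h_i:.1f} mm"
            )
    xg, yg, zg = np.meshgrid(*axes, indexing="ij", sparse=True)
    liver = (
        ((xg - jitter[0]) / semi[0]) ** 2
        + ((yg - jitter[1]) / semi[1]) ** 2
        + ((zg - jitter[2]) / semi[2]) ** 2
    ) <= 1.0
    x_centred = np.broadcast_to(xg, grid_shape) - jitter[0]
    liver_x = x_centred[liver]

    flrs = []
    for frac in target_flr_fractions:
        offset = _flr_plane_offset(liver_x, frac)
        flr = liver & (x_centred <= offset)
        got = flr.sum() / liver.sum()
        if abs(got - frac) > 0.05 * max(frac, 0.05):
            raise GeometryInfeasibleError(
                f"geometry infeasible: achieved FLR fraction {got:.3f} deviates "
                f"from target {frac:.3f} by more than 5%"
            )
        flrs.append(flr)

    barrier_frac = (
        barrier_fraction if barrier_fraction is not None else max(target_flr_fractions)
    )
    barrier = _flr_plane_offset(liver_x, min(barrier_frac, 0.95))
    tumour = np.zeros(grid_shape, dtype=bool)
    if tumour_cc > 0:
        tumour = _tumour_sphere(axes, semi, tumour_cc, barrier + spacing_mm[0], rng)
        tumour &= liver
    vessels = _vessel_mask(liver, axes, semi, vessel_density, spacing_mm, rng)

    out = []
    for flr in flrs:
        observed = np.zeros(grid_shape, dtype=np.int16)
        observed[liver] = Label.LIVER
        observed[flr] = Label.FLR
        # tumour only on the non-FLR side; vessels carve parenchyma, not tumour
        observed[tumour & (observed == Label.LIVER)] = Label.TUMOUR
        observed[vessels & (observed != Label.TUMOUR) & liver] = Label.VESSEL
        out.append(SegMaskSet(observed=observed, spacing=spacing_mm))
    return out


def make_liver_geometry(
    grid_shape: Sequence[int] = DEFAULT_SHAPE,
    spacing_mm: Sequence[float] = DEFAULT_SPACING,
    target_tlv_cc: float = 1400.0,
    target_flr_fraction: float = 0.30,
    tumour_cc: float = 40.0,
    vessel_density: float = 0.03,
    seed: int = 0,
    _post_flr_fraction: Optional[float] = None,
) -> SegMaskSet:
    """Build the observed label grid for one study.

    The liver is an ellipsoid (volume within 5% of ``target_tlv_cc``); the FLR
    is the portion with axis-0 coordinate below a plane chosen so the FLR
    volume fraction is within 5% of ``target_flr_fraction``; the tumour is a
    sphere in the non-FLR side (beyond ``_post_flr_fraction``'s plane when
    given, so it never ends up inside a later, larger remnant); vessels are
    random cylinders covering ~``vessel_density`` of the liver volume.

    Identical arguments (including the seed) give bit-identical masks.

    Raises
    ------
    GeometryInfeasibleError
        If the liver, remnant or tumour cannot be realised on the grid.
    """
    return _make_geometry_multi(
        grid_shape,
        spacing_mm,
        target_tlv_cc,
        [target_flr_fraction],
        tumour_cc,
        vessel_density,
        seed,
        barrier_fraction=_post_flr_fraction,
    )[0]


def _oedema_rim(flr_region: np.ndarray, parenchyma: np.ndarray, theta: float):
    """Truth grid: outer-rim oedema occupying fraction theta of parenchyma.

    Voxels of the FLR *region* closest to its boundary are converted first
    (congestion is peripheral); exactly round(theta * n_parenchyma) parenchyma
    voxels become oedema, ties broken by flat voxel index for determinism.
    """
    truth = np.zeros(flr_region.shape, dtype=np.int16)
    truth[parenchyma] = Truth.FUNCTIONAL
    n = int(parenchyma.sum())
    k = int(round(theta * n))
    if k == 0:
        return truth
    depth = ndimage.distance_transform_edt(flr_region)
    flat = np.flatnonzero(parenchyma)
    order = np.argsort(depth.ravel()[flat], kind="stable")
    truth.ravel()[flat[order[:k]]] = Truth.OEDEMA
    return truth


# ---------------------------------------------------------------------------
# texture
# ---------------------------------------------------------------------------

def _class_grid(seg: SegMaskSet) -> tuple[np.ndarray, list[str]]:
    """Map observed+truth labels to texture class names.

    Returns an int grid indexing into the returned class-name list.
    """
    names = ["background", "liver", "functional", "oedema", "vessel", "tumour"]
    grid = np.zeros(seg.shape, dtype=np.int8)
    grid[seg.observed == Label.LIVER] = 1
    grid[seg.observed == Label.FLR] = 2
    if seg.truth is not None:
        grid[(seg.observed == Label.FLR) & (seg.truth == Truth.OEDEMA)] = 3
    grid[seg.observed == Label.VESSEL] = 4
    grid[seg.observed == Label.TUMOUR] = 5
    return grid, names


def synth_texture(
    mask_set: SegMaskSet,
    tissue_params: dict[str, TissueTexture],
    seed: int = 0,
) -> ImageVolume:
    """Render a CT-like intensity volume from a label grid.

    Each tissue class receives ``mu + sigma * G`` where G is white Gaussian
    noise smoothed at the class's correlation length and renormalised over the
    class's voxels to zero mean and unit variance, so per-class sample mean
    and standard deviation match (mu, sigma) exactly.
    """
    grid, names = _class_grid(mask_set)
    present = np.unique(grid)
    missing = [names[c] for c in present if names[c] not in tissue_params]
    if missing:
        raise KeyError(
            f"missing tissue_params for present label(s): {', '.join(missing)}"
        )
    rng = np.random.default_rng(seed)
    out = np.zeros(mask_set.shape, dtype=np.float32)
    # one noise field per correlation length, smoothed only within the padded
    # bounding box of the classes that use it; per-class renormalisation keeps
    # class samples at exactly (mu, sigma) regardless of field sharing
    by_lambda: dict[float, list[int]] = {}
    for c in present:
        par = tissue_params[names[c]]
        out[grid == c] = par.mu
        if par.sigma > 0:
            by_lambda.setdefault(float(par.corr_len), []).append(int(c))
    for lam in sorted(by_lambda):
        members = by_lambda[lam]
        union = np.isin(grid, members)
        if not union.any():
            continue
        pad = int(np.ceil(4 * lam)) + 1
        nz = np.nonzero(union)
        sl = tuple(
            slice(max(0, int(a.min()) - pad), min(n, int(a.max()) + 1 + pad))
            for a, n in zip(nz, mask_set.shape)
        )
        noise = rng.standard_normal([s.stop - s.start for s in sl]).astype(np.float32)
        if lam > 0:
            noise = ndimage.gaussian_filter(noise, lam, mode="reflect")
        for c in members:
            par = tissue_params[names[c]]
            sel_box = grid[sl] == c
            if sel_box.sum() < 2:
                continue
            vals = noise[sel_box]
            sd = vals.std()
            if sd > 0:
                box = out[sl]
                box[sel_box] = par.mu + par.sigma * (vals - vals.mean()) / sd
                out[sl] = box
    return ImageVolume(voxels=out, spacing=mask_set.spacing)


# ---------------------------------------------------------------------------
# outcomes and cases
# ---------------------------------------------------------------------------

def assign_phlf(
    true_frfxv_pct: float,
    coeffs: OutcomeCoeffs = OutcomeCoeffs(),
    seed: int | np.random.Generator = 0,
) -> str:
    """Draw an ISGLS PHLF grade from the logistic outcome model.

    P(>= B) decreases strictly in the true functional-remnant percentage.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    p = float(coeffs.p_severe(true_frfxv_pct))
    if rng.uniform() < p:
        return (
            PhlfGrade.C
            if rng.uniform() < coeffs.p_grade_c_given_severe
            else PhlfGrade.B
        )
    return (
        PhlfGrade.A if rng.uniform() < coeffs.p_grade_a_given_mild else PhlfGrade.NONE
    )


def _case_seed(rng: np.random.Generator, lo: int = 0, hi: int = 2**31 - 1) -> int:
    return int(rng.integers(lo, hi))


def generate_case(
    sim_params: CaseParams,
    seed: int = 0,
    case_id: str = "case",
) -> PhantomCase:
    """Generate one paired pre/post phantom case.

    The pre study's FLR is entirely functional; the post study's FLR is
    enlarged to pre * (1 + g) with an oedema rim occupying fraction theta of
    its parenchyma. Patient metadata (height, weight, days to reassessment)
    is sampled; the PHLF grade is drawn from the logistic outcome model
    evaluated at the case's true FRFxV%.
    """
    p = sim_params
    rng = np.random.default_rng(seed)
    post_frac = p.pre_flr_fraction * (1.0 + p.growth)
    if post_frac >= 0.95:
        raise GeometryInfeasibleError(
            f"geometry infeasible: post FLR fraction {post_frac:.2f} of the "
            "liver leaves no non-remnant side"
        )
    geo_seed = _case_seed(rng)
    pre_seg, post_seg = _make_geometry_multi(
        p.grid_shape,
        p.spacing_mm,
        p.tlv_cc,
        [p.pre_flr_fraction, post_frac],  # same anatomy, plane moved
        p.tumour_cc,
        p.vessel_density,
        seed=geo_seed,
        barrier_fraction=post_frac,
    )
    voxcc = pre_seg.voxel_volume_cc

    pre_truth = np.zeros(pre_seg.shape, dtype=np.int16)
    pre_truth[pre_seg.observed == Label.FLR] = Truth.FUNCTIONAL
    pre_seg = SegMaskSet(pre_seg.observed, pre_seg.spacing, truth=pre_truth)

    flr_parenchyma = post_seg.observed == Label.FLR
    post_truth = _oedema_rim(flr_parenchyma, flr_parenchyma, p.theta)
    post_seg = SegMaskSet(post_seg.observed, post_seg.spacing, truth=post_truth)

    truth_frl_cc = float((post_seg.observed == Label.FLR).sum()) * voxcc
    truth_frfx_cc = float((post_seg.truth == Truth.FUNCTIONAL).sum()) * voxcc

    # outcome uses the true functional fraction of (TLV - TV), pre-study basis
    tlv_cc = float(np.isin(pre_seg.observed, [1, 2, 3, 4]).sum()) * voxcc
    tv_cc = float((pre_seg.observed == Label.TUMOUR).sum()) * voxcc
    true_frfxv_pct = truth_frfx_cc / (tlv_cc - tv_cc) * 100.0

    days_lo, days_hi = (7, 22) if p.technique == Technique.ALPPS else (36, 106)
    meta = PatientMeta(
        case_id=case_id,
        height_cm=float(np.clip(rng.normal(170.0, 10.0), 120, 220)),
        weight_kg=float(np.clip(rng.normal(75.0, 12.0), 30, 200)),
        technique=p.technique,
        days_elapsed=int(rng.integers(days_lo, days_hi + 1)),
        phlf_grade=assign_phlf(true_frfxv_pct, p.outcome, rng),
    )

    pre_img = post_img = None
    if p.render_texture:
        pre_img = synth_texture(pre_seg, p.textures, seed=_case_seed(rng))
        post_img = synth_texture(post_seg, p.textures, seed=_case_seed(rng))

    return PhantomCase(
        meta=meta,
        pre=(pre_img, pre_seg),
        post=(post_img, post_seg),
        truth_oedema_fraction=p.theta,
        truth_frl_cc=truth_frl_cc,
        truth_frfx_cc=truth_frfx_cc,
    )


def _sample_case_params(
    cp: CohortParams, technique: str, rng: np.random.Generator
) -> CaseParams:
    th_m = cp.theta_mean[technique]
    theta = float(
        rng.beta(th_m * cp.theta_concentration, (1 - th_m) * cp.theta_concentration)
    )
    g_m = cp.growth_mean[technique]
    growth = float(rng.gamma(cp.growth_shape, g_m / cp.growth_shape))
    pre_flr = float(
        np.clip(rng.normal(cp.pre_flr_mean[technique], cp.pre_flr_sd), 0.15, 0.50)
    )
    growth = min(growth, cp.max_post_flr_fraction / pre_flr - 1.0)
    tlv = float(np.clip(rng.normal(cp.tlv_mean_cc, cp.tlv_sd_cc), 1000.0, 1700.0))
    tumour = float(
        np.clip(
            cp.tumour_log_median_cc * math.exp(rng.normal(0.0, cp.tumour_log_sigma)),
            10.0,
            70.0,
        )
    )
    return CaseParams(
        technique=technique,
        tlv_cc=tlv,
        pre_flr_fraction=pre_flr,
        growth=growth,
        theta=theta,
        tumour_cc=tumour,
        vessel_density=cp.vessel_density,
        grid_shape=cp.grid_shape,
        spacing_mm=cp.spacing_mm,
        textures=cp.textures,
        outcome=cp.outcome,
        render_texture=cp.render_texture,
    )


def generate_cohort(
    params: CohortParams = CohortParams(),
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate a cohort of phantom cases.

    Per-case randomness comes from child streams spawned deterministically
    from the master seed (one per case index), so cohorts are reproducible
    and cases mutually independent.
    """
    if params.n < 2:
        raise ValueError("cohort size n must be >= 2")
    if not 0 <= params.n_alpps <= params.n:
        raise ValueError("technique split must sum to n")
    cases: list[PhantomCase] = []
    for i in range(params.n):
        technique = Technique.ALPPS if i < params.n_alpps else Technique.PVE
        ss = np.random.SeedSequence(seed, spawn_key=(i,))
        rng = np.random.default_rng(ss)
        for attempt in range(50):
            cp = _sample_case_params(params, technique, rng)
            try:
                case = generate_case(cp, seed=_case_seed(rng), case_id=f"case{i:03d}")
                break
            except GeometryInfeasibleError:
                continue
        else:  # pragma: no cover - defensive
            raise GeometryInfeasibleError(
                f"case {i}: no feasible geometry in 50 attempts"
            )
        cases.append(case)
    return cases


def cohort_manifest(cases: Sequence[PhantomCase]):
    """Tabulate per-case metadata and ground truth (one row per case)."""
    import pandas as pd

    rows = []
    for c in cases:
        rows.append(
            {
                "case_id": c.meta.case_id,
                "technique": c.meta.technique,
                "height_cm": round(c.meta.height_cm, 2),
                "weight_kg": round(c.meta.weight_kg, 2),
                "days_elapsed": c.meta.days_elapsed,
                "phlf_grade": c.meta.phlf_grade,
                "theta": round(c.truth_oedema_fraction, 4),
                "truth_frl_cc": round(c.truth_frl_cc, 4),
                "truth_frfx_cc": round(c.truth_frfx_cc, 4),
            }
        )
    return pd.DataFrame(rows)
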