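"""Higher-order texture features: GLCM, GLRLM, GLSZM, GLDM and NGTDM.

All matrices are built on the fixed-bin-width discretised grid at Chebyshev
distance 1. Directional families (co-occurrence, run length) use the 13
unique 3-D direction offsets, compute features per direction and average
them; co-occurrence matrices are symmetrised. Zone, dependence and tone
families use the full 26-neighbourhood.

Degenerate regions (a single grey level) return the families' closed-form
constants — e.g. GLCM contrast 0 and correlation 1, NGTDM coarseness 1e6 —
never NaN.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .base import DIRECTIONS_3D

__all__ = [
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
    "TEXTURE_NAMES",
    "glcm_matrix",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "texture_features",
]

GLCM_NAMES = tuple(
    "glcm_" + n
    for n in (
        "Autocorrelation",
        "ClusterProminence",
        "ClusterShade",
        "ClusterTendency",
        "Contrast",
        "Correlation",
        "DifferenceAverage",
        "DifferenceEntropy",
        "DifferenceVariance",
        "Id",
        "Idm",
        "Idmn",
        "Idn",
        "Imc1",
        "Imc2",
        "InverseVariance",
        "JointAverage",
        "JointEnergy",
        "JointEntropy",
        "MaximumProbability",
        "SumEntropy",
        "SumSquares",
    )
)

GLRLM_NAMES = tuple(
    "glrlm_" + n
    for n in (
        "ShortRunEmphasis",
        "LongRunEmphasis",
        "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized",
        "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized",
        "RunPercentage",
        "GrayLevelVariance",
        "RunVariance",
        "RunEntropy",
        "LowGrayLevelRunEmphasis",
        "HighGrayLevelRunEmphasis",
        "ShortRunLowGrayLevelEmphasis",
        "ShortRunHighGrayLevelEmphasis",
        "LongRunLowGrayLevelEmphasis",
        "LongRunHighGrayLevelEmphasis",
    )
)

GLSZM_NAMES = tuple(
    "glszm_" + n
    for n in (
        "SmallAreaEmphasis",
        "LargeAreaEmphasis",
        "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized",
        "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized",
        "ZonePercentage",
        "GrayLevelVariance",
        "ZoneVariance",
        "ZoneEntropy",
        "LowGrayLevelZoneEmphasis",
        "HighGrayLevelZoneEmphasis",
        "SmallAreaLowGrayLevelEmphasis",
        "SmallAreaHighGrayLevelEmphasis",
        "LargeAreaLowGrayLevelEmphasis",
        "LargeAreaHighGrayLevelEmphasis",
    )
)

GLDM_NAMES = tuple(
    "gldm_" + n
    for n in (
        "SmallDependenceEmphasis",
        "LargeDependenceEmphasis",
        "GrayLevelNonUniformity",
        "DependenceNonUniformity",
        "DependenceNonUniformityNormalized",
        "GrayLevelVariance",
        "DependenceVariance",
        "DependenceEntropy",
        "LowGrayLevelEmphasis",
        "HighGrayLevelEmphasis",
        "SmallDependenceLowGrayLevelEmphasis",
        "LargeDependenceHighGrayLevelEmphasis",
    )
)

NGTDM_NAMES = tuple(
    "ngtdm_" + n for n in ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")
)

TEXTURE_NAMES: tuple[str, ...] = (
    GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES + GLDM_NAMES + NGTDM_NAMES
)

_EPS = np.finfo(np.float64).eps


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _offset_slices(offset: Sequence[int]):
    """Slice pairs (src, dst) so that arr[src] and arr[dst] are voxel pairs
    separated by ``offset``."""
    src, dst = [], []
    for o in offset:
        if o == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif o > 0:
            src.append(slice(None, -o))
            dst.append(slice(o, None))
        else:
            src.append(slice(-o, None))
            dst.append(slice(None, o))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(
    levels: np.ndarray, mask: np.ndarray, offset: Sequence[int], n_levels: int
) -> np.ndarray:
    """Symmetric, normalised grey-level co-occurrence matrix for one offset."""
    src, dst = _offset_slices(offset)
    ok = mask[src] & mask[dst]
    i = levels[src][ok] - 1
    j = levels[dst][ok] - 1
    counts = np.bincount(i * n_levels + j, minlength=n_levels * n_levels)
    P = counts.reshape(n_levels, n_levels).astype(np.float64)
    P = P + P.T
    total = P.sum()
    return P / total if total > 0 else P


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    Ng = P.shape[0]
    i = np.arange(1, Ng + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((px * i).sum())
    sigma2 = float((px * (i - mu) ** 2).sum())
    sigma = np.sqrt(sigma2)

    k_diff = np.arange(Ng, dtype=np.float64)
    p_diff = np.zeros(Ng)
    np.add.at(p_diff, np.abs(I - J).astype(int).ravel(), P.ravel())
    k_sum = np.arange(2, 2 * Ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * Ng - 1)
    np.add.at(p_sum, (I + J).astype(int).ravel() - 2, P.ravel())

    diff_avg = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * p_diff).sum())

    hxy = _entropy_bits(P.ravel())
    hx = _entropy_bits(px)
    pxpy = np.outer(px, px)
    nz = P > 0
    hxy1 = float(-(P[nz] * np.log2(pxpy[nz] + _EPS)).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    autocorr = float((I * J * P).sum())
    if sigma > _EPS:
        correlation = (autocorr - mu * mu) / sigma2
    else:
        correlation = 1.0  # single grey level: perfectly correlated by convention

    off_diag = I != J
    inv_var = float((P[off_diag] / (I[off_diag] - J[off_diag]) ** 2).sum())

    return {
        "glcm_Autocorrelation": autocorr,
        "glcm_ClusterProminence": float(((I + J - 2 * mu) ** 4 * P).sum()),
        "glcm_ClusterShade": float(((I + J - 2 * mu) ** 3 * P).sum()),
        "glcm_ClusterTendency": float(((I + J - 2 * mu) ** 2 * P).sum()),
        "glcm_Contrast": float(((I - J) ** 2 * P).sum()),
        "glcm_Correlation": correlation,
        "glcm_DifferenceAverage": diff_avg,
        "glcm_DifferenceEntropy": _entropy_bits(p_diff),
        "glcm_DifferenceVariance": diff_var,
        "glcm_Id": float((P / (1.0 + np.abs(I - J))).sum()),
        "glcm_Idm": float((P / (1.0 + (I - J) ** 2)).sum()),
        "glcm_Idmn": float((P / (1.0 + (I - J) ** 2 / Ng**2)).sum()),
        "glcm_Idn": float((P / (1.0 + np.abs(I - J) / Ng)).sum()),
        "glcm_Imc1": imc1,
        "glcm_Imc2": imc2,
        "glcm_InverseVariance": inv_var,
        "glcm_JointAverage": mu,
        "glcm_JointEnergy": float((P**2).sum()),
        "glcm_JointEntropy": hxy,
        "glcm_MaximumProbability": float(P.max()),
        "glcm_SumEntropy": _entropy_bits(p_sum),
        "glcm_SumSquares": float(((I - mu) ** 2 * P).sum()),
    }


def glcm_features(
    levels: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    directions: Iterable[Sequence[int]] = DIRECTIONS_3D,
) -> dict[str, float]:
    """GLCM features averaged over direction offsets."""
    acc: dict[str, float] = {}
    ndir = 0
    for d in directions:
        P = glcm_matrix(levels, mask, d, n_levels)
        if P.sum() == 0:
            continue  # no voxel pairs along this direction
        f = _glcm_features_single(P)
        for k, v in f.items():
            acc[k] = acc.get(k, 0.0) + v
        ndir += 1
    if ndir == 0:
        # isolated voxels: no co-occurrence anywhere; degenerate constants
        base = _glcm_features_single(np.ones((1, 1)))
        return base
    return {k: v / ndir for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _runs_along(levels, mask, direction):
    """Run (grey, length) pairs along one direction, runs broken by the mask.

    Voxels on a line satisfy pos = base + t*d, so sorting by (base, t) makes
    line neighbours adjacent; a run continues while the line key matches, t
    advances by one and the grey level repeats.
    """
    idx = np.argwhere(mask)
    if idx.shape[0] == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    g = levels[mask]
    d = np.asarray(direction)
    axis = int(np.flatnonzero(d)[0])
    t = idx[:, axis] * d[axis]  # d[axis] == 1 by construction
    key = idx - t[:, None] * d[None, :]
    order = np.lexsort((t, key[:, 2], key[:, 1], key[:, 0]))
    t_o, k_o, g_o = t[order], key[order], g[order]
    cont = (
        np.all(k_o[1:] == k_o[:-1], axis=1)
        & (t_o[1:] == t_o[:-1] + 1)
        & (g_o[1:] == g_o[:-1])
    )
    starts = np.concatenate(([0], np.flatnonzero(~cont) + 1))
    lengths = np.diff(np.concatenate((starts, [g_o.size])))
    return g_o[starts], lengths


def _rlm_style_features(
    grey: np.ndarray, size: np.ndarray, n_levels: int, n_vox: int, prefix: str, names
) -> dict[str, float]:
    """Shared emphasis/non-uniformity/variance feature set over (grey, size)
    pairs; used by run-length (size = run length) and size-zone (size = zone
    size) families."""
    N = float(size.size)
    i = grey.astype(np.float64)
    s = size.astype(np.float64)
    p = np.full(size.size, 1.0 / N)
    mu_i = float((p * i).sum())
    mu_s = float((p * s).sum())
    gl_counts = np.bincount(grey - 1, minlength=n_levels).astype(np.float64)
    # joint (grey, size) probabilities for the entropy term
    size_max = int(size.max())
    joint = np.bincount(
        (grey - 1) * size_max + (size - 1), minlength=n_levels * size_max
    ).astype(np.float64)
    size_counts = np.bincount(size - 1, minlength=size_max).astype(np.float64)

    vals = [
        float((1.0 / s**2).sum() / N),                  # small/short emphasis
        float((s**2).sum() / N),                        # large/long emphasis
        float((gl_counts**2).sum() / N),                # GLN
        float((gl_counts**2).sum() / N**2),             # GLNN
        float((size_counts**2).sum() / N),              # size non-uniformity
        float((size_counts**2).sum() / N**2),           # normalised
        N / n_vox,                                      # run/zone percentage
        float((p * (i - mu_i) ** 2).sum()),             # grey-level variance
        float((p * (s - mu_s) ** 2).sum()),             # size variance
        _entropy_bits(joint / N),                       # entropy
        float((1.0 / i**2).sum() / N),                  # low grey emphasis
        float((i**2).sum() / N),                        # high grey emphasis
        float((1.0 / (i**2 * s**2)).sum() / N),         # small+low
        float((i**2 / s**2).sum() / N),                 # small+high
        float((s**2 / i**2).sum() / N),                 # large+low
        float((i**2 * s**2).sum() / N),                 # large+high
    ]
    return dict(zip(names, vals))


def glrlm_features(
    levels: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    directions: Iterable[Sequence[int]] = DIRECTIONS_3D,
) -> dict[str, float]:
    """Run-length features averaged over the 13 directions."""
    n_vox = int(mask.sum())
    acc: dict[str, float] = {}
    ndir = 0
    for d in directions:
        grey, length = _runs_along(levels, mask, d)
        f = _rlm_style_features(grey, length, n_levels, n_vox, "glrlm", GLRLM_NAMES)
        for k, v in f.items():
            acc[k] = acc.get(k, 0.0) + v
        ndir += 1
    return {k: v / ndir for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    """Size-zone features; zones are 26-connected same-grey components."""
    n_vox = int(mask.sum())
    greys, sizes = [], []
    for lvl in np.unique(levels[mask]):
        lab, nlab = ndimage.label((levels == lvl) & mask, structure=_STRUCT26)
        if nlab == 0:
            continue
        counts = np.bincount(lab.ravel())[1:]
        greys.append(np.full(nlab, lvl, dtype=np.int64))
        sizes.append(counts.astype(np.int64))
    grey = np.concatenate(greys)
    size = np.concatenate(sizes)
    return _rlm_style_features(grey, size, n_levels, n_vox, "glszm", GLSZM_NAMES)


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_features(
    levels: np.ndarray, mask: np.ndarray, n_levels: int, alpha: float = 0.0
) -> dict[str, float]:
    """Dependence features: per voxel, the count of 26-neighbours within
    ``alpha`` grey levels forms the dependence size j (stored as j+1)."""
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in DIRECTIONS_3D:
        src, dst = _offset_slices(d)
        both = mask[src] & mask[dst]
        close = both & (np.abs(levels[src] - levels[dst]) <= alpha)
        dep[src] += close
        dep[dst] += close
    i = levels[mask].astype(np.int64)
    j = dep[mask] + 1
    N = float(i.size)
    fi = i.astype(np.float64)
    fj = j.astype(np.float64)
    p = np.full(i.size, 1.0 / N)
    mu_j = float(fj.mean())
    gl_counts = np.bincount(i - 1, minlength=n_levels).astype(np.float64)
    jmax = int(j.max())
    dep_counts = np.bincount(j - 1, minlength=jmax).astype(np.float64)
    joint = np.bincount((i - 1) * jmax + (j - 1), minlength=n_levels * jmax).astype(
        np.float64
    )
    return {
        "gldm_SmallDependenceEmphasis": float((1.0 / fj**2).mean()),
        "gldm_LargeDependenceEmphasis": float((fj**2).mean()),
        "gldm_GrayLevelNonUniformity": float((gl_counts**2).sum() / N),
        "gldm_DependenceNonUniformity": float((dep_counts**2).sum() / N),
        "gldm_DependenceNonUniformityNormalized": float((dep_counts**2).sum() / N**2),
        "gldm_GrayLevelVariance": float((p * (fi - fi.mean()) ** 2).sum()),
        "gldm_DependenceVariance": float((p * (fj - mu_j) ** 2).sum()),
        "gldm_DependenceEntropy": _entropy_bits(joint / N),
        "gldm_LowGrayLevelEmphasis": float((1.0 / fi**2).mean()),
        "gldm_HighGrayLevelEmphasis": float((fi**2).mean()),
        "gldm_SmallDependenceLowGrayLevelEmphasis": float((1.0 / (fi**2 * fj**2)).mean()),
        "gldm_LargeDependenceHighGrayLevelEmphasis": float((fi**2 * fj**2).mean()),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    """Neighbourhood grey-tone difference features.

    s_i sums |i - A| over voxels of level i, where A is the mean grey level of
    a voxel's in-mask 26-neighbours; voxels without neighbours are excluded.
    """
    nb_sum = np.zeros(levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    lv = levels.astype(np.float64)
    for d in DIRECTIONS_3D:
        src, dst = _offset_slices(d)
        both = mask[src] & mask[dst]
        nb_sum[src] += np.where(both, lv[dst], 0.0)
        nb_cnt[src] += both
        nb_sum[dst] += np.where(both, lv[src], 0.0)
        nb_cnt[dst] += both
    valid = mask & (nb_cnt > 0)
    nv = int(valid.sum())
    if nv == 0:
        return dict.fromkeys(NGTDM_NAMES, 0.0)
    A = nb_sum[valid] / nb_cnt[valid]
    i_vals = levels[valid].astype(np.int64)
    diff = np.abs(i_vals - A)
    s = np.zeros(n_levels)
    np.add.at(s, i_vals - 1, diff)
    n_i = np.bincount(i_vals - 1, minlength=n_levels).astype(np.float64)
    p_i = n_i / nv
    present = p_i > 0
    ngp = int(present.sum())
    lev = np.arange(1, n_levels + 1, dtype=np.float64)

    denom_coarse = float((p_i * s).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else 1e6

    if ngp > 1:
        ii, jj = np.meshgrid(lev[present], lev[present], indexing="ij")
        pp_i, pp_j = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        contrast = float(
            (pp_i * pp_j * (ii - jj) ** 2).sum()
            / (ngp * (ngp - 1))
            * s.sum()
            / nv
        )
        busy_den = float(np.abs(ii * pp_i - jj * pp_j).sum())
        busyness = denom_coarse / busy_den if busy_den > 0 else 0.0
        ss_i = np.meshgrid(s[present], s[present], indexing="ij")
        complexity = float(
            (
                np.abs(ii - jj)
                * (pp_i * ss_i[0] + pp_j * ss_i[1])
                / (pp_i + pp_j)
            ).sum()
            / nv
        )
        s_tot = float(s.sum())
        strength = (
            float(((pp_i + pp_j) * (ii - jj) ** 2).sum()) / s_tot if s_tot > 0 else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "ngtdm_Coarseness": coarseness,
        "ngtdm_Contrast": contrast,
        "ngtdm_Busyness": busyness,
        "ngtdm_Complexity": complexity,
        "ngtdm_Strength": strength,
    }


# ---------------------------------------------------------------------------

def texture_features(
    levels: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    """All 71 texture features of a discretised region."""
    mask = np.asarray(mask, dtype=bool)
    if int(mask.sum()) < 27:
        raise ValueError("texture features need at least 27 voxels")
    out: dict[str, float] = {}
    out.update(glcm_features(levels, mask, n_levels))
    out.update(glrlm_features(levels, mask, n_levels))
    out.update(glszm_features(levels, mask, n_levels))
    out.update(gldm_features(levels, mask, n_levels))
    out.update(ngtdm_features(levels, mask, n_levels))
    return out
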