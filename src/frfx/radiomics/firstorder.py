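"""First-order (intensity-histogram) features.

Nineteen features computed from the raw intensities of a region plus a
fixed-bin-width discretised histogram (entropy and uniformity). Conventions:
population (1/n) variance, entropy in bits, Pearson kurtosis (Fisher + 3);
skewness and kurtosis are defined as 0 for regions without at least two
distinct values.

A vectorised batch path computes the same features for many regions at once
(rows of a NaN-padded matrix); the scalar path is the batch path on one row,
so the two cannot drift apart.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FIRST_ORDER_NAMES", "first_order_features", "first_order_features_batch"]

FIRST_ORDER_NAMES: tuple[str, ...] = (
    "firstorder_Energy",
    "firstorder_TotalEnergy",
    "firstorder_Entropy",
    "firstorder_Minimum",
    "firstorder_10Percentile",
    "firstorder_90Percentile",
    "firstorder_Maximum",
    "firstorder_Mean",
    "firstorder_Median",
    "firstorder_InterquartileRange",
    "firstorder_Range",
    "firstorder_MeanAbsoluteDeviation",
    "firstorder_RobustMeanAbsoluteDeviation",
    "firstorder_RootMeanSquared",
    "firstorder_StandardDeviation",
    "firstorder_Variance",
    "firstorder_Skewness",
    "firstorder_Kurtosis",
    "firstorder_Uniformity",
)


def _hist_entropy_uniformity(values: np.ndarray, bin_width: float):
    """Per-row (entropy bits, uniformity) over fixed-width bins anchored at
    each row's minimum. ``values`` is (P, m) with NaN padding."""
    anchor = np.nanmin(values, axis=1, keepdims=True)
    bins = np.floor((values - anchor) / bin_width)
    bins = np.where(np.isnan(values), -1, bins).astype(np.int64)
    n_rows = values.shape[0]
    n_bins = int(bins.max()) + 1
    counts = np.zeros((n_rows, n_bins), dtype=np.float64)
    rows = np.repeat(np.arange(n_rows), values.shape[1])
    flat = bins.ravel()
    ok = flat >= 0
    np.add.at(counts, (rows[ok], flat[ok]), 1.0)
    p = counts / counts.sum(axis=1, keepdims=True)
    logp = np.log2(np.where(p > 0, p, 1.0))
    entropy = -(p * logp).sum(axis=1)
    uniformity = (p**2).sum(axis=1)
    return entropy, uniformity


def first_order_features_batch(
    values: np.ndarray, bin_width: float = 25.0, voxel_volume_mm3: float = 1.0
) -> dict[str, np.ndarray]:
    """All 19 first-order features for each row of a NaN-padded matrix.

    Every row must contain at least one finite value.
    """
    V = np.asarray(values, dtype=np.float64)
    if V.ndim != 2:
        raise ValueError("values must be 2-D (regions x voxels)")
    n = np.sum(~np.isnan(V), axis=1)
    if np.any(n == 0):
        raise ValueError("every region must contain at least one voxel")
    mean = np.nanmean(V, axis=1)
    mn = np.nanmin(V, axis=1)
    mx = np.nanmax(V, axis=1)
    # vectorised linear-interpolation percentiles (NaN sort to the end)
    S = np.sort(V, axis=1)
    rows = np.arange(V.shape[0])

    def pct(q: float) -> np.ndarray:
        pos = q / 100.0 * (n - 1)
        lo = np.floor(pos).astype(np.int64)
        hi = np.ceil(pos).astype(np.int64)
        frac = pos - lo
        return S[rows, lo] * (1.0 - frac) + S[rows, hi] * frac

    p10, p25, med, p75, p90 = (pct(q) for q in (10, 25, 50, 75, 90))
    dev = V - mean[:, None]
    m2 = np.nanmean(dev**2, axis=1)
    m3 = np.nanmean(dev**3, axis=1)
    m4 = np.nanmean(dev**4, axis=1)
    nondeg = m2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(nondeg, m3 / np.where(nondeg, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(nondeg, m4 / np.where(nondeg, m2, 1.0) ** 2, 0.0)
    energy = np.nansum(V**2, axis=1)
    mad = np.nanmean(np.abs(dev), axis=1)
    # rMAD over the 10-90 percentile sub-range; tiny regions can have no
    # voxels strictly inside the interpolated percentiles -> rMAD := 0
    in_sub = (V >= p10[:, None]) & (V <= p90[:, None]) & ~np.isnan(V)
    n_sub = in_sub.sum(axis=1)
    sub = np.where(in_sub, V, 0.0)
    sub_mean = sub.sum(axis=1) / np.maximum(n_sub, 1)
    rmad = np.where(
        n_sub > 0,
        (np.abs(sub - sub_mean[:, None]) * in_sub).sum(axis=1) / np.maximum(n_sub, 1),
        0.0,
    )
    entropy, uniformity = _hist_entropy_uniformity(V, bin_width)
    return {
        "firstorder_Energy": energy,
        "firstorder_TotalEnergy": energy * voxel_volume_mm3,
        "firstorder_Entropy": entropy,
        "firstorder_Minimum": mn,
        "firstorder_10Percentile": p10,
        "firstorder_90Percentile": p90,
        "firstorder_Maximum": mx,
        "firstorder_Mean": mean,
        "firstorder_Median": med,
        "firstorder_InterquartileRange": p75 - p25,
        "firstorder_Range": mx - mn,
        "firstorder_MeanAbsoluteDeviation": mad,
        "firstorder_RobustMeanAbsoluteDeviation": rmad,
        "firstorder_RootMeanSquared": np.sqrt(energy / n),
        "firstorder_StandardDeviation": np.sqrt(m2),
        "firstorder_Variance": m2,
        "firstorder_Skewness": skew,
        "firstorder_Kurtosis": kurt,
        "firstorder_Uniformity": uniformity,
    }


def first_order_features(
    values: np.ndarray, bin_width: float = 25.0, voxel_volume_mm3: float = 1.0
) -> dict[str, float]:
    """All 19 first-order features of one region (1-D intensity array)."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("cannot compute features of an empty region")
    batch = first_order_features_batch(v[None, :], bin_width, voxel_volume_mm3)
    return {k: float(val[0]) for k, val in batch.items()}
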