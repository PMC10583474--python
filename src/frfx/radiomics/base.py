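"""Shared radiomics plumbing: grey-level discretisation and standardisation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["discretize", "standardize", "StandardizationParams", "DIRECTIONS_3D"]

#: The 13 unique 3-D direction offsets at Chebyshev distance 1 (one per
#: opposite pair of the 26-neighbourhood), first nonzero component positive.
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
    and next(v for v in (dx, dy, dz) if v != 0) > 0
)
assert len(DIRECTIONS_3D) == 13


def discretize(
    values: np.ndarray, bin_width: float, anchor: Optional[float] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-bin-width grey-level discretisation.

    ``bin(v) = floor((v - anchor) / bin_width) + 1`` with the anchor at the
    region minimum by default, so the lowest grey level is 1. Returns the bin
    index array (same shape as ``values``) and the occupancy histogram over
    levels ``1..max``.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot discretise an empty region")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if anchor is None:
        anchor = float(values.min())
    bins = np.floor((values - anchor) / bin_width).astype(np.int64) + 1
    hist = np.bincount(bins.ravel(), minlength=int(bins.max()) + 1)[1:]
    return bins, hist


@dataclass
class StandardizationParams:
    """Per-column mean/sd fitted on the training rows, plus dropped columns."""

    names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=np.float64) - self.mean) / self.sd


def standardize(
    matrix: np.ndarray,
    names: Sequence[str],
    fit_rows: Optional[np.ndarray] = None,
    sd_floor: float = 1e-12,
) -> tuple[np.ndarray, StandardizationParams]:
    """Column-wise z-scoring with parameters estimated on ``fit_rows`` only.

    Columns whose training-set standard deviation falls below ``sd_floor``
    are dropped (recorded in the returned params). Raises if every column is
    constant.
    """
    X = np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D")
    names = list(names)
    if len(names) != X.shape[1]:
        raise ValueError("one name per column required")
    if fit_rows is None:
        fit_rows = np.ones(X.shape[0], dtype=bool)
    fit = X[fit_rows]
    if fit.shape[0] < 2:
        raise ValueError("need at least 2 fitting rows")
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0, ddof=0)
    keep = sd >= sd_floor
    if not keep.any():
        raise ValueError("all feature columns are constant on the fitting rows")
    dropped = [n for n, k in zip(names, keep) if not k]
    params = StandardizationParams(
        names=[n for n, k in zip(names, keep) if k],
        mean=mean[keep],
        sd=sd[keep],
        dropped=dropped,
    )
    return params.transform(X[:, keep]), params
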