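"""3-D shape features of a binary region.

Sixteen features: mesh-based volume and surface (marching cubes on the padded
binary mask, in physical mm), sphericity/compactness descriptors, maximum
diameters from the convex hull of region voxel centres, and principal-axis
lengths from the eigen-decomposition of the voxel-coordinate covariance
(population form; axis length = 4 * sqrt(eigenvalue), the full axis of the
ellipsoid with matching second moments).
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure

__all__ = ["SHAPE_NAMES", "shape_features"]

SHAPE_NAMES: tuple[str, ...] = (
    "shape_MeshVolume",
    "shape_VoxelVolume",
    "shape_SurfaceArea",
    "shape_SurfaceVolumeRatio",
    "shape_Sphericity",
    "shape_Compactness1",
    "shape_Compactness2",
    "shape_Maximum3DDiameter",
    "shape_Maximum2DDiameterSlice",
    "shape_Maximum2DDiameterColumn",
    "shape_Maximum2DDiameterRow",
    "shape_MajorAxisLength",
    "shape_MinorAxisLength",
    "shape_LeastAxisLength",
    "shape_Elongation",
    "shape_Flatness",
)


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise distance; uses the convex hull when it helps."""
    if points.shape[0] < 2:
        return 0.0
    pts = points
    if points.shape[0] > 50:
        uniq = np.unique(points, axis=0)
        if uniq.shape[0] >= points.shape[1] + 1:
            try:
                pts = uniq[ConvexHull(uniq, qhull_options="QJ").vertices]
            except Exception:  # degenerate (coplanar) sets fall through
                pts = uniq
        else:
            pts = uniq
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def shape_features(mask: np.ndarray, spacing_mm: Sequence[float]) -> dict[str, float]:
    """All 16 shape features of a binary 3-D mask with physical spacing.

    Single-voxel (or otherwise surface-degenerate) regions are flagged with a
    warning and fall back to voxel-cube geometry rather than failing.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    nvox = int(mask.sum())
    if nvox == 0:
        raise ValueError("cannot compute shape features of an empty mask")
    spacing = np.asarray([float(s) for s in spacing_mm])
    voxel_mm3 = float(np.prod(spacing))
    voxel_volume = nvox * voxel_mm3

    if nvox < 2:
        warnings.warn(
            "single-voxel region: mesh/axis shape features are degenerate",
            RuntimeWarning,
            stacklevel=2,
        )

    # Mesh a lightly smoothed indicator so the triangulation tracks the true
    # surface instead of the voxel staircase (which overestimates area by
    # ~10% on a sphere); tiny regions fall back to the raw binary surface.
    padded = np.pad(mask.astype(np.float64), 2)
    if nvox >= 27:
        padded = ndimage.gaussian_filter(padded, sigma=1.0)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    mesh_volume = float(
        abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum())
        / 6.0
    )

    sphericity = (36.0 * math.pi * mesh_volume**2) ** (1.0 / 3.0) / area
    compactness1 = mesh_volume / (math.sqrt(math.pi) * area**1.5)
    compactness2 = 36.0 * math.pi * mesh_volume**2 / area**3

    coords = np.argwhere(mask) * spacing
    max3d = _max_pairwise(coords)
    # in-plane diameters: slice = axes (1,2); column drops axis 1; row drops axis 2
    max2d_slice = _max_pairwise(coords[:, (1, 2)])
    max2d_col = _max_pairwise(coords[:, (0, 2)])
    max2d_row = _max_pairwise(coords[:, (0, 1)])

    if nvox > 1:
        cov = np.cov(coords.T, ddof=0)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * math.sqrt(e) for e in eig)
    elongation = math.sqrt(eig[1] / eig[0]) if eig[0] > 0 else 0.0
    flatness = math.sqrt(eig[2] / eig[0]) if eig[0] > 0 else 0.0

    return {
        "shape_MeshVolume": mesh_volume,
        "shape_VoxelVolume": voxel_volume,
        "shape_SurfaceArea": area,
        "shape_SurfaceVolumeRatio": area / mesh_volume,
        "shape_Sphericity": sphericity,
        "shape_Compactness1": compactness1,
        "shape_Compactness2": compactness2,
        "shape_Maximum3DDiameter": max3d,
        "shape_Maximum2DDiameterSlice": max2d_slice,
        "shape_Maximum2DDiameterColumn": max2d_col,
        "shape_Maximum2DDiameterRow": max2d_row,
        "shape_MajorAxisLength": major,
        "shape_MinorAxisLength": minor,
        "shape_LeastAxisLength": least,
        "shape_Elongation": elongation,
        "shape_Flatness": flatness,
    }
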