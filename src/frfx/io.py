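"""NIfTI and artefact I/O.

Volumes and masks travel as NIfTI-1 files whose affine encodes the voxel
spacing in RAS+ orientation; reads are normalised to the closest canonical
orientation. Round trips preserve voxel values bit-exactly and spacing to
1e-6 mm.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np

from .types import ImageVolume, PhantomCase

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_case",
    "sha256_of",
]


def _affine(spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(path: Union[str, Path], volume: ImageVolume) -> Path:
    """Write an intensity volume as NIfTI-1 (.nii or .nii.gz)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(
        volume.voxels.astype(np.float32), _affine(volume.spacing, volume.origin)
    )
    nib.save(img, path)
    return path


def read_volume(path: Union[str, Path]) -> tuple[ImageVolume, np.ndarray]:
    """Read a NIfTI volume; returns the volume and its RAS+ affine."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:
        raise ValueError(f"malformed NIfTI header in {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D image, got {data.ndim}-D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(voxels=data, spacing=spacing, origin=origin), img.affine


def write_mask(path: Union[str, Path], grid: np.ndarray, spacing) -> Path:
    """Write an integer label grid as NIfTI-1."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(np.asarray(grid, dtype=np.int16), _affine(spacing))
    nib.save(img, path)
    return path


def read_mask(path: Union[str, Path]) -> tuple[np.ndarray, tuple[float, ...]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask file: {path}")
    img = nib.as_closest_canonical(nib.load(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D mask, got {data.ndim}-D in {path}")
    return data.astype(np.int16), tuple(float(z) for z in img.header.get_zooms()[:3])


def write_case(case: PhantomCase, out_dir: Union[str, Path]) -> list[Path]:
    """Write one phantom case: image, observed mask and truth mask per
    timepoint, named ``<case>_<timepoint>_<kind>.nii.gz``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for timepoint, (img, seg) in (("pre", case.pre), ("post", case.post)):
        stem = f"{case.meta.case_id}_{timepoint}"
        if img is not None:
            written.append(write_volume(out_dir / f"{stem}_image.nii.gz", img))
        written.append(
            write_mask(out_dir / f"{stem}_observed-mask.nii.gz", seg.observed, seg.spacing)
        )
        if seg.truth is not None:
            written.append(
                write_mask(out_dir / f"{stem}_truth-mask.nii.gz", seg.truth, seg.spacing)
            )
    return written


def sha256_of(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
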