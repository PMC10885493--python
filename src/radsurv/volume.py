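"""3D scalar volumes and aligned binary tumor masks.

An :class:`ImageVolume` is a calibrated scalar grid (HU for CT) with
anisotropic voxel spacing; a :class:`VoiMask` is a binary volume of interest
defined on the *same* grid.  Physical coordinates follow the usual
convention ``x_mm = origin_mm + index * spacing_mm`` with 0-based indices;
arrays are indexed ``(i, j, k)`` matching the nibabel data layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "VoiMask", "read_volume", "read_mask", "write_volume"]


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular, possibly anisotropic grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar intensities (HU).  Must be finite.
    spacing_mm : tuple of float
        Per-axis voxel size in millimetres, strictly positive.
    origin_mm : tuple of float
        Physical position of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def same_grid(self, other: "ImageVolume | VoiMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


@dataclass
class VoiMask:
    """Binary volume of interest aligned to an :class:`ImageVolume` grid."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask must contain only 0/1, found values {uniq[:10]}")
        self.values = arr.astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def same_grid(self, other: "ImageVolume | VoiMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


def check_aligned(volume: ImageVolume, mask: VoiMask) -> None:
    """Raise if image and mask are not on the identical grid."""
    if volume.shape != mask.shape:
        raise ValueError(f"image/mask shape mismatch: {volume.shape} vs {mask.shape}")
    if not np.allclose(volume.spacing_mm, mask.spacing_mm) or not np.allclose(
        volume.origin_mm, mask.origin_mm
    ):
        raise ValueError("image and mask grids differ in spacing or origin")


def _affine(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def write_volume(obj: ImageVolume | VoiMask, path) -> None:
    """Write a volume or mask to NIfTI; grid geometry goes into the affine."""
    data = obj.values.astype(np.float64) if isinstance(obj, ImageVolume) else obj.values.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine(obj.spacing_mm, obj.origin_mm))
    nib.save(img, str(path))


def _load(path):
    img = nib.load(str(path))
    aff = img.affine
    off = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if not np.allclose(off, 0, atol=1e-6):
        raise ValueError(f"{path}: only axis-aligned (diagonal-affine) volumes are supported")
    data = np.asarray(img.dataobj)
    spacing = tuple(np.abs(np.diag(aff[:3, :3])))
    origin = tuple(aff[:3, 3])
    return data, spacing, origin


def read_volume(path) -> ImageVolume:
    data, spacing, origin = _load(path)
    return ImageVolume(data, spacing, origin)


def read_mask(path) -> VoiMask:
    data, spacing, origin = _load(path)
    return VoiMask(data, spacing, origin)
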