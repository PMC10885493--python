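"""Preprocessing: grid resampling, intensity discretization, image filters.

The standard radiomics workflow resamples CT volumes to a uniform voxel
grid (default 1 x 1 x 3 mm), optionally band-passes the image with a
Gaussian or Laplacian-of-Gaussian (LoG) filter at a millimetre scale, and
discretizes in-mask intensities to a fixed number of gray levels before
texture-matrix computation.  Fixed-bin-count discretization makes all
texture features invariant to affine rescaling of the in-mask intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volume import ImageVolume, VoiMask, check_aligned

__all__ = [
    "TransformTag",
    "DiscretizedVoi",
    "PrepConfig",
    "resample",
    "discretize",
    "gaussian_filter",
    "log_filter",
    "apply_transform",
]

DEFAULT_SPACING = (1.0, 1.0, 3.0)


@dataclass(frozen=True)
class TransformTag:
    """Image-domain transform applied before feature extraction.

    ``kind`` is one of ``"N"`` (non-transformed raw image), ``"G"``
    (Gaussian smoothing) or ``"LOG"`` (Laplacian of Gaussian); ``sigma_mm``
    is the filter scale in millimetres (None for raw).
    """

    kind: str
    sigma_mm: float | None = None

    def __post_init__(self):
        if self.kind not in ("N", "G", "LOG"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "N":
            if self.sigma_mm is not None:
                raise ValueError("raw transform carries no sigma")
        elif self.sigma_mm is None or self.sigma_mm <= 0:
            raise ValueError(f"{self.kind} filter requires sigma_mm > 0")

    @property
    def label(self) -> str:
        return self.kind

    def __str__(self) -> str:
        return self.label


RAW = TransformTag("N")


@dataclass
class DiscretizedVoi:
    """Gray levels 1..n_levels on in-mask voxels (0 outside the mask)."""

    levels: np.ndarray  # int array, same shape as the mask grid
    n_levels: int
    mask: VoiMask
    binning: dict

    def __post_init__(self):
        inside = self.levels[self.mask.values]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("in-mask levels outside [1, n_levels]")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


@dataclass
class PrepConfig:
    """Preprocessing parameters for a feature-extraction run."""

    target_spacing_mm: tuple[float, float, float] = DEFAULT_SPACING
    n_bins: int = 32
    gaussian_sigma_mm: float = 1.0
    log_sigma_mm: float = 2.0

    def transforms(self) -> list[TransformTag]:
        return [
            RAW,
            TransformTag("G", self.gaussian_sigma_mm),
            TransformTag("LOG", self.log_sigma_mm),
        ]


def _to_sitk(values: np.ndarray, spacing, origin) -> sitk.Image:
    # SimpleITK arrays are (z, y, x); our layout is (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).transpose(2, 1, 0)


def resample(
    volume: ImageVolume,
    mask: VoiMask,
    target_spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> tuple[ImageVolume, VoiMask]:
    """Resample an aligned image/mask pair to a uniform voxel grid.

    The image is trilinearly interpolated and the mask resampled with
    nearest-neighbor interpolation so it stays binary.  The physical extent
    of the grid is preserved to within one voxel.

    Raises
    ------
    ValueError
        If image and mask are misaligned, or the mask is empty after
        resampling.
    """
    check_aligned(volume, mask)
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    if volume.spacing_mm == target_spacing:
        return volume, mask

    old_shape = np.array(volume.shape)
    old_spacing = np.array(volume.spacing_mm)
    new_shape = np.maximum(1, np.ceil(old_shape * old_spacing / np.array(target_spacing))).astype(int)

    ref = sitk.Image([int(n) for n in new_shape], sitk.sitkFloat64)
    ref.SetSpacing(target_spacing)
    ref.SetOrigin(volume.origin_mm)

    img = sitk.Resample(_to_sitk(volume.values, volume.spacing_mm, volume.origin_mm), ref,
                        sitk.Transform(), sitk.sitkLinear, 0.0, sitk.sitkFloat64)
    msk = sitk.Resample(_to_sitk(mask.values.astype(np.uint8), mask.spacing_mm, mask.origin_mm),
                        ref, sitk.Transform(), sitk.sitkNearestNeighbor, 0, sitk.sitkUInt8)

    new_mask = _from_sitk(msk).astype(bool)
    if not new_mask.any():
        raise ValueError("mask is empty after resampling")
    return (
        ImageVolume(_from_sitk(img), target_spacing, volume.origin_mm),
        VoiMask(new_mask, target_spacing, volume.origin_mm),
    )


def discretize(volume: ImageVolume, mask: VoiMask, n_bins: int = 32) -> DiscretizedVoi:
    """Fixed-bin-count discretization of in-mask intensities.

    ``level = 1 + floor(n_bins * (x - min) / (range + eps))`` clipped to
    ``n_bins``; a constant region maps everywhere to level 1.
    """
    check_aligned(volume, mask)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not mask.values.any():
        raise ValueError("empty mask")
    x = volume.values[mask.values]
    lo, hi = float(x.min()), float(x.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if hi > lo:
        eps = (hi - lo) * 1e-10
        lv = 1 + np.floor(n_bins * (x - lo) / (hi - lo + eps)).astype(np.int32)
        levels[mask.values] = np.clip(lv, 1, n_bins)
    else:
        levels[mask.values] = 1
    return DiscretizedVoi(
        levels, n_bins, mask,
        binning={"method": "fixed-bin-count", "n_bins": n_bins, "min": lo, "max": hi},
    )


def _sigma_voxels(sigma_mm: float, spacing_mm) -> list[float]:
    return [float(sigma_mm) / s for s in spacing_mm]


def gaussian_filter(volume: ImageVolume, sigma_mm: float) -> ImageVolume:
    """Separable Gaussian smoothing with scale in millimetres.

    Sigma is converted per axis to voxel units using the spacing, so the
    smoothing is isotropic in physical space.  Mirror boundary handling.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    out = ndimage.gaussian_filter(volume.values, _sigma_voxels(sigma_mm, volume.spacing_mm),
                                  mode="mirror")
    return ImageVolume(out, volume.spacing_mm, volume.origin_mm)


def _gauss_kernels(sigma_vox: float) -> tuple[np.ndarray, np.ndarray]:
    """Sampled 1D Gaussian smoothing and second-derivative kernels.

    The derivative kernel is corrected to exact zero sum so the filter
    responds exactly zero to constant (and, being even, to linear) inputs.
    """
    radius = max(2, int(np.ceil(4.0 * sigma_vox)))
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(x**2) / (2.0 * sigma_vox**2))
    g /= g.sum()
    d2 = g * (x**2 - sigma_vox**2) / sigma_vox**4
    d2 -= d2.sum() / d2.size
    return g, d2


def log_filter(volume: ImageVolume, sigma_mm: float) -> ImageVolume:
    """Laplacian of Gaussian, millimetre-scaled.

    Sum over axes of the Gaussian second derivative along that axis; each
    directional second derivative is taken with respect to physical
    coordinates (voxel-unit derivative divided by spacing squared).
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    sig = _sigma_voxels(sigma_mm, volume.spacing_mm)
    kernels = [_gauss_kernels(s) for s in sig]
    out = np.zeros_like(volume.values)
    for ax in range(3):
        term = volume.values
        for other in range(3):
            k = kernels[other][1] if other == ax else kernels[other][0]
            term = ndimage.correlate1d(term, k, axis=other, mode="mirror")
        out += term / volume.spacing_mm[ax] ** 2
    return ImageVolume(out, volume.spacing_mm, volume.origin_mm)


def apply_transform(volume: ImageVolume, tag: TransformTag) -> ImageVolume:
    if tag.kind == "N":
        return volume
    if tag.kind == "G":
        return gaussian_filter(volume, tag.sigma_mm)
    return log_filter(volume, tag.sigma_mm)
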