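"""Radiomics feature extraction: morphologic, first-order, and texture families.

Feature identity is the quadruple ``(phase, transform, family, name)``
rendered canonically as ``"AP|LOG|glcm|joint_entropy"``.  Morphologic
features depend only on the mask and are phase-agnostic; they carry the
phase token ``"VOI"`` and the raw transform ``"N"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import texture
from .preprocess import PrepConfig, apply_transform, discretize
from .volume import ImageVolume, VoiMask, check_aligned

__all__ = [
    "FeatureId",
    "FeatureRegistry",
    "morph_volume",
    "morph_flatness",
    "morph_features",
    "firstorder_features",
    "extract_all",
    "extract_table",
]

FAMILIES = ("morph", "firstorder", "glcm", "glszm", "gldzm", "ngldm")

FIRSTORDER_FEATURES = sorted(
    ["mean", "variance", "skewness", "kurtosis", "maximum", "minimum", "range",
     "percentile10", "percentile25", "median", "percentile75", "percentile90",
     "interquartile_range", "mean_absolute_deviation", "robust_mad",
     "energy", "root_mean_square"]
)

MORPH_FEATURES = sorted(
    ["volume", "voxel_count", "flatness", "elongation",
     "major_axis_length_mm", "least_axis_length_mm"]
)


@dataclass(frozen=True)
class FeatureId:
    """Identity of one radiomics feature."""

    phase: str  # "AP", "PVP", or "VOI" for mask-only morphologic features
    transform: str  # "N", "G", "LOG"
    family: str
    name: str

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "morph" and (self.transform != "N" or self.phase != "VOI"):
            raise ValueError("morphologic features are phase-agnostic raw-image features")

    def __str__(self) -> str:
        return f"{self.phase}|{self.transform}|{self.family}|{self.name}"

    @classmethod
    def parse(cls, s: str) -> "FeatureId":
        parts = s.split("|")
        if len(parts) != 4:
            raise ValueError(f"malformed feature id {s!r}")
        return cls(*parts)


# ---------------------------------------------------------------------------
# Morphologic features (mask-only)
# ---------------------------------------------------------------------------

def morph_volume(mask: VoiMask) -> float:
    """VOI volume in mm^3: voxel count times voxel volume."""
    if not mask.values.any():
        raise ValueError("empty mask")
    return mask.n_voxels * mask.voxel_volume_mm3


def _coord_eigenvalues(mask: VoiMask) -> np.ndarray:
    """Ascending eigenvalues of the physical-coordinate covariance (1/n)."""
    idx = np.argwhere(mask.values).astype(float)
    if idx.shape[0] < 4:
        raise ValueError("mask needs at least 4 voxels for axis statistics")
    coords = idx * np.array(mask.spacing_mm)
    cov = np.cov(coords, rowvar=False, bias=True)
    vals = np.linalg.eigvalsh(cov)
    return np.clip(vals, 0.0, None)


def morph_flatness(mask: VoiMask) -> float:
    """Least-to-major principal-axis ratio, sqrt(lambda_least/lambda_major).

    Bounded in (0, 1]; 1 for an isotropic (spherical) VOI.  Raises for
    degenerate (coplanar or collinear) masks whose least eigenvalue
    vanishes.
    """
    vals = _coord_eigenvalues(mask)
    if vals[0] <= 1e-12 * max(vals[2], 1.0):
        raise ValueError("degenerate (coplanar) mask: flatness undefined")
    return float(np.sqrt(vals[0] / vals[2]))


def morph_features(mask: VoiMask) -> dict[str, float]:
    vals = _coord_eigenvalues(mask)
    out = {
        "volume": morph_volume(mask),
        "voxel_count": float(mask.n_voxels),
        "major_axis_length_mm": float(4.0 * np.sqrt(vals[2])),
        "least_axis_length_mm": float(4.0 * np.sqrt(vals[0])),
    }
    if vals[0] <= 1e-12 * max(vals[2], 1.0):
        raise ValueError("degenerate (coplanar) mask")
    out["flatness"] = float(np.sqrt(vals[0] / vals[2]))
    out["elongation"] = float(np.sqrt(vals[1] / vals[2]))
    return out


# ---------------------------------------------------------------------------
# First-order intensity statistics
# ---------------------------------------------------------------------------

def firstorder_features(volume: ImageVolume, mask: VoiMask) -> dict[str, float]:
    """Statistics of the in-mask intensity distribution.

    ``robust_mad`` is the mean absolute deviation from the mean computed on
    the values lying within the closed [10th, 90th] percentile range.
    """
    check_aligned(volume, mask)
    if not mask.values.any():
        raise ValueError("empty mask")
    x = volume.values[mask.values].astype(float)
    mu = float(x.mean())
    var = float(x.var())
    sd = np.sqrt(var)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    core = x[(x >= p10) & (x <= p90)]
    centered = x - mu
    return {
        "mean": mu,
        "variance": var,
        "skewness": float((centered**3).mean() / sd**3) if sd > 0 else 0.0,
        "kurtosis": float((centered**4).mean() / sd**4 - 3.0) if sd > 0 else 0.0,
        "maximum": float(x.max()),
        "minimum": float(x.min()),
        "range": float(x.max() - x.min()),
        "percentile10": float(p10),
        "percentile25": float(p25),
        "median": float(np.median(x)),
        "percentile75": float(p75),
        "percentile90": float(p90),
        "interquartile_range": float(p75 - p25),
        "mean_absolute_deviation": float(np.abs(centered).mean()),
        "robust_mad": float(np.abs(core - core.mean()).mean()),
        "energy": float((x**2).sum()),
        "root_mean_square": float(np.sqrt((x**2).mean())),
    }


# ---------------------------------------------------------------------------
# Registry and full extraction
# ---------------------------------------------------------------------------

_FAMILY_LISTS = {
    "morph": MORPH_FEATURES,
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": texture.GLCM_FEATURES,
    "glszm": texture.GLSZM_FEATURES,
    "gldzm": texture.GLDZM_FEATURES,
    "ngldm": texture.NGLDM_FEATURES,
}

_TEXTURE_FUNCS = {
    "glcm": texture.glcm_features,
    "glszm": texture.glszm_features,
    "gldzm": texture.gldzm_features,
    "ngldm": texture.ngldm_features,
}


@dataclass
class FeatureRegistry:
    """Which feature ids an extraction run produces.

    ``ids`` is the ordered list of :class:`FeatureId`; order is
    deterministic (phase, then transform, then family, then name as
    registered).
    """

    ids: list[FeatureId] = field(default_factory=list)

    @classmethod
    def default(cls, phases=("AP", "PVP"), transforms=("N", "G", "LOG")) -> "FeatureRegistry":
        """Full feature families per phase and transform, plus morphology."""
        ids = [FeatureId("VOI", "N", "morph", n) for n in MORPH_FEATURES]
        for phase in phases:
            for tr in transforms:
                for fam in ("firstorder", "glcm", "glszm", "gldzm", "ngldm"):
                    ids.extend(FeatureId(phase, tr, fam, n) for n in _FAMILY_LISTS[fam])
        return cls(ids)

    @classmethod
    def from_ids(cls, ids) -> "FeatureRegistry":
        out = []
        for fid in ids:
            fid = FeatureId.parse(fid) if isinstance(fid, str) else fid
            if fid.name not in _FAMILY_LISTS[fid.family]:
                raise ValueError(f"feature {fid.name!r} not implemented in family {fid.family}")
            out.append(fid)
        return cls(out)

    @property
    def id_strings(self) -> list[str]:
        return [str(f) for f in self.ids]

    def __len__(self) -> int:
        return len(self.ids)


def extract_all(
    volume_ap: ImageVolume | None,
    volume_pvp: ImageVolume | None,
    mask: VoiMask,
    registry: FeatureRegistry | None = None,
    prep: PrepConfig | None = None,
) -> dict[str, float]:
    """Extract every registered feature for one subject.

    Inputs are assumed to be on the analysis grid already (see
    :func:`radsurv.preprocess.resample`).  Per phase and transform the image
    is filtered, discretized with the configured fixed bin count, and each
    registered family is evaluated.  Raises with the offending feature id on
    any family error.
    """
    prep = prep or PrepConfig()
    phases = {}
    if volume_ap is not None:
        phases["AP"] = volume_ap
    if volume_pvp is not None:
        phases["PVP"] = volume_pvp
    if not phases:
        raise ValueError("at least one phase volume is required")
    if registry is None:
        registry = FeatureRegistry.default(phases=tuple(phases))

    transforms = {t.label: t for t in prep.transforms()}
    # group requested ids by (phase, transform, family)
    wanted: dict[tuple[str, str, str], list[str]] = {}
    for fid in registry.ids:
        wanted.setdefault((fid.phase, fid.transform, fid.family), []).append(fid.name)

    values: dict[str, float] = {}
    cache: dict[tuple[str, str, str], dict[str, float]] = {}
    for (phase, tr, fam), names in wanted.items():
        key = (phase, tr, fam)
        if key not in cache:
            try:
                if fam == "morph":
                    cache[key] = morph_features(mask)
                else:
                    if phase not in phases:
                        raise ValueError(f"phase {phase} not provided")
                    img = apply_transform(phases[phase], transforms[tr])
                    if fam == "firstorder":
                        cache[key] = firstorder_features(img, mask)
                    else:
                        disc = discretize(img, mask, prep.n_bins)
                        cache[key] = _TEXTURE_FUNCS[fam](disc)
            except Exception as err:
                raise type(err)(f"{phase}|{tr}|{fam}: {err}") from err
        fam_vals = cache[key]
        for name in names:
            values[str(FeatureId(phase, tr, fam, name))] = fam_vals[name]

    bad = [k for k, v in values.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values: {bad[:5]}")
    return values


def extract_table(
    subjects: dict[str, tuple[ImageVolume | None, ImageVolume | None, VoiMask]],
    registry: FeatureRegistry | None = None,
    prep: PrepConfig | None = None,
) -> pd.DataFrame:
    """Extract a subjects x features table (rows indexed by subject id)."""
    rows = {
        sid: extract_all(ap, pvp, mask, registry=registry, prep=prep)
        for sid, (ap, pvp, mask) in subjects.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df
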