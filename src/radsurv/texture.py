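"""Gray-level texture matrices and their scalar features.

Implements the four 3D texture families used for tumor-heterogeneity
radiomics: the co-occurrence matrix (GLCM), the size-zone matrix (GLSZM),
the distance-zone matrix (GLDZM) and the neighboring gray-level dependence
matrix (NGLDM), following the IBSI reference definitions.

Conventions (fixed across the package):

* 3D neighborhoods use Chebyshev distance 1 (26 neighbors); the GLCM is
  accumulated over the 13 unique directions, symmetrized, normalized per
  direction and merged by averaging the normalized matrices.
* Zones (GLSZM/GLDZM) are 26-connected sets of equal-level voxels;
  anisotropic spacing is ignored for connectivity (voxel topology).
* GLDZM zone distance is the minimum in-mask Chebyshev distance from any
  zone voxel to the mask border; border voxels have distance 1.
* NGLDM dependence of a voxel is the number of its in-mask 26-neighbors
  with exactly the same gray level (coarseness threshold alpha = 0); the
  matrix column index is ``dependence + 1`` so inverse moments are defined.
* All entropies use log base 2.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .preprocess import DiscretizedVoi

__all__ = [
    "glcm_matrix",
    "glszm_matrix",
    "gldzm_matrix",
    "ngldm_matrix",
    "glcm_features",
    "glszm_features",
    "gldzm_features",
    "ngldm_features",
    "GLCM_FEATURES",
    "GLSZM_FEATURES",
    "GLDZM_FEATURES",
    "NGLDM_FEATURES",
]

# 13 unique direction offsets: lexicographically positive half of the
# 26-neighborhood.
DIRECTIONS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _crop(d: DiscretizedVoi) -> tuple[np.ndarray, np.ndarray]:
    """Levels and mask cropped to the mask bounding box (padded by 1)."""
    m = d.mask.values
    if not m.any():
        raise ValueError("empty mask")
    idx = np.argwhere(m)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    levels = np.pad(d.levels[sl], 1)
    mask = np.pad(m[sl], 1)
    return levels, mask


def _shift_pairs(arr: np.ndarray, off):
    """Slices of arr and arr shifted by off, aligned elementwise."""
    sl_a, sl_b = [], []
    for o, n in zip(off, arr.shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def glcm_matrix(d: DiscretizedVoi) -> np.ndarray:
    """Direction-averaged symmetric co-occurrence probability matrix.

    Returns the (Ng, Ng) matrix; entry (i-1, j-1) is the probability of the
    in-mask ordered level pair (i, j) at Chebyshev distance 1, averaged over
    the normalized per-direction matrices.
    """
    levels, mask = _crop(d)
    ng = d.n_levels
    acc = np.zeros((ng, ng))
    n_dir = 0
    for off in DIRECTIONS_13:
        la, lb = _shift_pairs(levels, off)
        ma, mb = _shift_pairs(mask, off)
        ok = ma & mb
        if not ok.any():
            continue
        i = la[ok] - 1
        j = lb[ok] - 1
        counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(float)
        counts = counts + counts.T  # symmetric pairs
        acc += counts / counts.sum()
        n_dir += 1
    if n_dir == 0:
        raise ValueError("VOI has no valid in-mask voxel pair")
    return acc / n_dir


def _zone_entries(d: DiscretizedVoi, dist: np.ndarray | None = None):
    """Per 26-connected equal-level zone: (level, size[, min distance])."""
    levels, mask = _crop(d)
    entries = []
    for g in range(1, d.n_levels + 1):
        binary = (levels == g) & mask
        if not binary.any():
            continue
        lab, n = ndimage.label(binary, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel(), minlength=n + 1)[1:]
        if dist is None:
            entries.extend((g, int(s)) for s in sizes)
        else:
            dmin = ndimage.minimum(dist, lab, index=np.arange(1, n + 1))
            entries.extend((g, int(zd)) for zd in np.atleast_1d(dmin))
    return entries


def glszm_matrix(d: DiscretizedVoi) -> np.ndarray:
    """Size-zone count matrix, shape (Ng, S_max); column s-1 = zone size s."""
    entries = _zone_entries(d)
    smax = max(s for _, s in entries)
    mat = np.zeros((d.n_levels, smax))
    for g, s in entries:
        mat[g - 1, s - 1] += 1
    return mat


def gldzm_matrix(d: DiscretizedVoi) -> np.ndarray:
    """Distance-zone count matrix, shape (Ng, D_max); column d-1 = distance d.

    Distance of a voxel is its Chebyshev distance to the nearest voxel
    outside the mask (mask-border voxels have distance 1); a zone's distance
    is the minimum over its voxels.
    """
    levels, mask = _crop(d)
    dist = ndimage.distance_transform_cdt(mask, metric="chessboard")
    entries = _zone_entries(d, dist=dist)
    dmax = max(zd for _, zd in entries)
    mat = np.zeros((d.n_levels, dmax))
    for g, zd in entries:
        mat[g - 1, zd - 1] += 1
    return mat


def ngldm_matrix(d: DiscretizedVoi) -> np.ndarray:
    """Dependence matrix, shape (Ng, 27); column k = dependence count k.

    Dependence count of an in-mask voxel is the number of its in-mask
    26-neighbors sharing its gray level exactly (alpha = 0).
    """
    levels, mask = _crop(d)
    dep = np.zeros(levels.shape, dtype=np.int32)
    for off in DIRECTIONS_13:
        la, lb = _shift_pairs(levels, off)
        ma, mb = _shift_pairs(mask, off)
        same = (la == lb) & ma & mb
        a, b = _shift_pairs(dep, off)
        a += same
        b += same
    mat = np.zeros((d.n_levels, 27))
    g = levels[mask] - 1
    k = dep[mask]
    np.add.at(mat, (g, k), 1.0)
    return mat


# ---------------------------------------------------------------------------
# Scalar features
# ---------------------------------------------------------------------------

def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(d: DiscretizedVoi) -> dict[str, float]:
    p = glcm_matrix(d)
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mu = float((ii * p).sum())  # symmetric: row and column means coincide
    var = float(((ii - mu) ** 2 * p).sum())

    diff = np.abs(ii - jj)
    p_diff = np.array([p[diff == k].sum() for k in range(ng)])
    ssum = ii + jj
    p_sum = np.array([p[ssum == k].sum() for k in range(2, 2 * ng + 1)])
    kd = np.arange(ng)
    mu_diff = float((kd * p_diff).sum())

    feats = {
        "joint_maximum": float(p.max()),
        "joint_energy": float((p**2).sum()),
        "joint_entropy": _entropy(p),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "dissimilarity": float((diff * p).sum()),
        "inverse_difference": float((p / (1.0 + diff)).sum()),
        "inverse_difference_moment": float((p / (1.0 + diff**2)).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "difference_entropy": _entropy(p_diff),
        "difference_variance": float(((kd - mu_diff) ** 2 * p_diff).sum()),
        "sum_average": float((ssum * p).sum()),
        "sum_entropy": _entropy(p_sum),
        "correlation": float(((ii - mu) * (jj - mu) * p).sum() / var) if var > 0 else 0.0,
    }
    return feats


def _zone_family_features(
    mat: np.ndarray, n_mask_voxels: int, emph: str, axis: str
) -> dict[str, float]:
    """Shared GLSZM/GLDZM feature definitions.

    ``mat`` holds zone counts indexed (gray level - 1, s - 1) where s is the
    zone size (GLSZM: ``emph="zone"``, ``axis="zone_size"``) or the zone
    distance (GLDZM: ``emph="distance"``, ``axis="zone_distance"``).
    """
    nz = mat.sum()
    p = mat / nz
    ng, smax = mat.shape
    g = np.arange(1, ng + 1)[:, None].astype(float)
    s = np.arange(1, smax + 1)[None, :].astype(float)
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_g = float((np.arange(1, ng + 1) * pg).sum())
    mu_s = float((np.arange(1, smax + 1) * ps).sum())
    return {
        f"small_{emph}_emphasis": float((p / s**2).sum()),
        f"large_{emph}_emphasis": float((p * s**2).sum()),
        "low_gray_level_emphasis": float((p / g**2).sum()),
        "high_gray_level_emphasis": float((p * g**2).sum()),
        f"small_{emph}_low_gray_level_emphasis": float((p / (s**2 * g**2)).sum()),
        f"small_{emph}_high_gray_level_emphasis": float((p * g**2 / s**2).sum()),
        f"large_{emph}_low_gray_level_emphasis": float((p * s**2 / g**2).sum()),
        f"large_{emph}_high_gray_level_emphasis": float((p * s**2 * g**2).sum()),
        "gray_level_nonuniformity": float((mat.sum(axis=1) ** 2).sum() / nz),
        f"{axis}_nonuniformity": float((mat.sum(axis=0) ** 2).sum() / nz),
        "zone_percentage": float(nz / n_mask_voxels),
        "gray_level_variance": float((p * (g - mu_g) ** 2).sum()),
        f"{axis}_variance": float((p * (s - mu_s) ** 2).sum()),
        "zone_entropy": _entropy(p.ravel()),
    }


def glszm_features(d: DiscretizedVoi) -> dict[str, float]:
    return _zone_family_features(glszm_matrix(d), d.mask.n_voxels, "zone", "zone_size")


def gldzm_features(d: DiscretizedVoi) -> dict[str, float]:
    return _zone_family_features(gldzm_matrix(d), d.mask.n_voxels, "distance", "zone_distance")


def ngldm_features(d: DiscretizedVoi) -> dict[str, float]:
    mat = ngldm_matrix(d)
    nz = mat.sum()
    p = mat / nz
    ng = mat.shape[0]
    g = np.arange(1, ng + 1)[:, None].astype(float)
    j = np.arange(1, 28)[None, :].astype(float)  # dependence count + 1
    pg = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_g = float((np.arange(1, ng + 1) * pg).sum())
    mu_j = float((np.arange(1, 28) * pj).sum())
    return {
        "low_dependence_emphasis": float((p / j**2).sum()),
        "high_dependence_emphasis": float((p * j**2).sum()),
        "low_gray_level_count_emphasis": float((p / g**2).sum()),
        "high_gray_level_count_emphasis": float((p * g**2).sum()),
        "low_dependence_low_gray_level_emphasis": float((p / (j**2 * g**2)).sum()),
        "low_dependence_high_gray_level_emphasis": float((p * g**2 / j**2).sum()),
        "high_dependence_low_gray_level_emphasis": float((p * j**2 / g**2).sum()),
        "high_dependence_high_gray_level_emphasis": float((p * j**2 * g**2).sum()),
        "gray_level_nonuniformity": float((mat.sum(axis=1) ** 2).sum() / nz),
        "dependence_count_nonuniformity": float((mat.sum(axis=0) ** 2).sum() / nz),
        "gray_level_variance": float((p * (g - mu_g) ** 2).sum()),
        "dependence_count_variance": float((p * (j - mu_j) ** 2).sum()),
        "dependence_count_entropy": _entropy(p.ravel()),
    }


GLCM_FEATURES = sorted(
    ["joint_maximum", "joint_energy", "joint_entropy", "contrast", "dissimilarity",
     "inverse_difference", "inverse_difference_moment", "cluster_tendency",
     "cluster_shade", "cluster_prominence", "difference_entropy",
     "difference_variance", "sum_average", "sum_entropy", "correlation"]
)
GLSZM_FEATURES = sorted(
    ["small_zone_emphasis", "large_zone_emphasis", "low_gray_level_emphasis",
     "high_gray_level_emphasis", "small_zone_low_gray_level_emphasis",
     "small_zone_high_gray_level_emphasis", "large_zone_low_gray_level_emphasis",
     "large_zone_high_gray_level_emphasis", "gray_level_nonuniformity",
     "zone_size_nonuniformity", "zone_percentage", "gray_level_variance",
     "zone_size_variance", "zone_entropy"]
)
GLDZM_FEATURES = sorted(
    ["small_distance_emphasis", "large_distance_emphasis",
     "low_gray_level_emphasis", "high_gray_level_emphasis",
     "small_distance_low_gray_level_emphasis",
     "small_distance_high_gray_level_emphasis",
     "large_distance_low_gray_level_emphasis",
     "large_distance_high_gray_level_emphasis", "gray_level_nonuniformity",
     "zone_distance_nonuniformity", "zone_percentage", "gray_level_variance",
     "zone_distance_variance", "zone_entropy"]
)
NGLDM_FEATURES = sorted(
    ["low_dependence_emphasis", "high_dependence_emphasis",
     "low_gray_level_count_emphasis", "high_gray_level_count_emphasis",
     "low_dependence_low_gray_level_emphasis", "low_dependence_high_gray_level_emphasis",
     "high_dependence_low_gray_level_emphasis", "high_dependence_high_gray_level_emphasis",
     "gray_level_nonuniformity", "dependence_count_nonuniformity",
     "gray_level_variance", "dependence_count_variance", "dependence_count_entropy"]
)
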