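"""Independent brute-force oracles used to verify the package's math.

Everything here is deliberately written as plain loops / direct formula
evaluation, independent of the vectorized implementations under test.
"""

from __future__ import annotations

import math

import numpy as np

HALF_DIRECTIONS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
ALL_NEIGHBORS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _in(shape, v):
    return all(0 <= v[a] < shape[a] for a in range(3))


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    """Average of per-direction normalized symmetric co-occurrence matrices."""
    shape = mask.shape
    acc = np.zeros((ng, ng))
    used = 0
    for d in HALF_DIRECTIONS:
        counts = np.zeros((ng, ng))
        for v in np.argwhere(mask):
            w = tuple(v + d)
            if _in(shape, w) and mask[w]:
                i, j = levels[tuple(v)] - 1, levels[w] - 1
                counts[i, j] += 1
                counts[j, i] += 1
        if counts.sum() > 0:
            acc += counts / counts.sum()
            used += 1
    return acc / used


def glcm_features(p: np.ndarray) -> dict:
    ng = p.shape[0]
    mu = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    var = sum((i + 1 - mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    pd_ = [sum(p[i, j] for i in range(ng) for j in range(ng) if abs(i - j) == k) for k in range(ng)]
    ps_ = [sum(p[i, j] for i in range(ng) for j in range(ng) if i + j + 2 == k) for k in range(2, 2 * ng + 1)]
    mu_d = sum(k * pd_[k] for k in range(ng))

    def ent(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    out = {
        "joint_maximum": p.max(),
        "joint_energy": sum(p[i, j] ** 2 for i in range(ng) for j in range(ng)),
        "joint_entropy": ent(p.ravel()),
        "contrast": sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)),
        "dissimilarity": sum(abs(i - j) * p[i, j] for i in range(ng) for j in range(ng)),
        "inverse_difference": sum(p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)),
        "inverse_difference_moment": sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)),
        "cluster_tendency": sum((i + j + 2 - 2 * mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng)),
        "cluster_shade": sum((i + j + 2 - 2 * mu) ** 3 * p[i, j] for i in range(ng) for j in range(ng)),
        "cluster_prominence": sum((i + j + 2 - 2 * mu) ** 4 * p[i, j] for i in range(ng) for j in range(ng)),
        "difference_entropy": ent(pd_),
        "difference_variance": sum((k - mu_d) ** 2 * pd_[k] for k in range(ng)),
        "sum_average": sum((i + j + 2) * p[i, j] for i in range(ng) for j in range(ng)),
        "sum_entropy": ent(ps_),
        "correlation": (
            sum((i + 1 - mu) * (j + 1 - mu) * p[i, j] for i in range(ng) for j in range(ng)) / var
            if var > 0 else 0.0
        ),
    }
    return out


def flood_zones(levels: np.ndarray, mask: np.ndarray):
    """26-connected equal-level zones via BFS; yields lists of voxel tuples."""
    seen = np.zeros(mask.shape, dtype=bool)
    zones = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        g = levels[start]
        queue = [start]
        seen[start] = True
        members = []
        while queue:
            v = queue.pop()
            members.append(v)
            for d in ALL_NEIGHBORS:
                w = tuple(np.add(v, d))
                if _in(mask.shape, w) and mask[w] and not seen[w] and levels[w] == g:
                    seen[w] = True
                    queue.append(w)
        zones.append((int(g), members))
    return zones


def border_distance(mask: np.ndarray, v) -> int:
    """Chebyshev distance from an in-mask voxel to the nearest non-mask
    position (grid exterior counts as non-mask)."""
    best = None
    shape = mask.shape
    # search over a bounding box big enough to include the exterior
    for x in range(-1, shape[0] + 1):
        for y in range(-1, shape[1] + 1):
            for z in range(-1, shape[2] + 1):
                w = (x, y, z)
                inside = _in(shape, w)
                if inside and mask[w]:
                    continue
                d = max(abs(v[0] - x), abs(v[1] - y), abs(v[2] - z))
                if best is None or d < best:
                    best = d
    return best


def glszm_matrix(levels, mask, ng):
    zones = flood_zones(levels, mask)
    smax = max(len(m) for _, m in zones)
    mat = np.zeros((ng, smax))
    for g, members in zones:
        mat[g - 1, len(members) - 1] += 1
    return mat


def gldzm_matrix(levels, mask, ng):
    zones = flood_zones(levels, mask)
    entries = []
    for g, members in zones:
        d = min(border_distance(mask, v) for v in members)
        entries.append((g, d))
    dmax = max(d for _, d in entries)
    mat = np.zeros((ng, dmax))
    for g, d in entries:
        mat[g - 1, d - 1] += 1
    return mat


def ngldm_matrix(levels, mask, ng):
    mat = np.zeros((ng, 27))
    for v in map(tuple, np.argwhere(mask)):
        k = 0
        for d in ALL_NEIGHBORS:
            w = tuple(np.add(v, d))
            if _in(mask.shape, w) and mask[w] and levels[w] == levels[v]:
                k += 1
        mat[levels[v] - 1, k] += 1
    return mat


def zone_features(mat: np.ndarray, n_voxels: int, emph: str, axis: str) -> dict:
    nz = mat.sum()
    ng, smax = mat.shape
    out = {}
    p = mat / nz
    mu_g = sum((g + 1) * p[g, s] for g in range(ng) for s in range(smax))
    mu_s = sum((s + 1) * p[g, s] for g in range(ng) for s in range(smax))

    def agg(f):
        return sum(f(g + 1, s + 1) * p[g, s] for g in range(ng) for s in range(smax))

    out[f"small_{emph}_emphasis"] = agg(lambda g, s: 1 / s**2)
    out[f"large_{emph}_emphasis"] = agg(lambda g, s: s**2)
    out["low_gray_level_emphasis"] = agg(lambda g, s: 1 / g**2)
    out["high_gray_level_emphasis"] = agg(lambda g, s: g**2)
    out[f"small_{emph}_low_gray_level_emphasis"] = agg(lambda g, s: 1 / (g**2 * s**2))
    out[f"small_{emph}_high_gray_level_emphasis"] = agg(lambda g, s: g**2 / s**2)
    out[f"large_{emph}_low_gray_level_emphasis"] = agg(lambda g, s: s**2 / g**2)
    out[f"large_{emph}_high_gray_level_emphasis"] = agg(lambda g, s: s**2 * g**2)
    out["gray_level_nonuniformity"] = sum(mat[g, :].sum() ** 2 for g in range(ng)) / nz
    out[f"{axis}_nonuniformity"] = sum(mat[:, s].sum() ** 2 for s in range(smax)) / nz
    out["zone_percentage"] = nz / n_voxels
    out["gray_level_variance"] = agg(lambda g, s: (g - mu_g) ** 2)
    out[f"{axis}_variance"] = agg(lambda g, s: (s - mu_s) ** 2)
    out["zone_entropy"] = -sum(
        p[g, s] * math.log2(p[g, s]) for g in range(ng) for s in range(smax) if p[g, s] > 0
    )
    return out


def ngldm_features(mat: np.ndarray) -> dict:
    nz = mat.sum()
    ng = mat.shape[0]
    p = mat / nz
    mu_g = sum((g + 1) * p[g, k] for g in range(ng) for k in range(27))
    mu_j = sum((k + 1) * p[g, k] for g in range(ng) for k in range(27))

    def agg(f):
        return sum(f(g + 1, k + 1) * p[g, k] for g in range(ng) for k in range(27))

    return {
        "low_dependence_emphasis": agg(lambda g, j: 1 / j**2),
        "high_dependence_emphasis": agg(lambda g, j: j**2),
        "low_gray_level_count_emphasis": agg(lambda g, j: 1 / g**2),
        "high_gray_level_count_emphasis": agg(lambda g, j: g**2),
        "low_dependence_low_gray_level_emphasis": agg(lambda g, j: 1 / (g**2 * j**2)),
        "low_dependence_high_gray_level_emphasis": agg(lambda g, j: g**2 / j**2),
        "high_dependence_low_gray_level_emphasis": agg(lambda g, j: j**2 / g**2),
        "high_dependence_high_gray_level_emphasis": agg(lambda g, j: j**2 * g**2),
        "gray_level_nonuniformity": sum(mat[g, :].sum() ** 2 for g in range(ng)) / nz,
        "dependence_count_nonuniformity": sum(mat[:, k].sum() ** 2 for k in range(27)) / nz,
        "gray_level_variance": agg(lambda g, j: (g - mu_g) ** 2),
        "dependence_count_variance": agg(lambda g, j: (j - mu_j) ** 2),
        "dependence_count_entropy": -sum(
            p[g, k] * math.log2(p[g, k]) for g in range(ng) for k in range(27) if p[g, k] > 0
        ),
    }


# ---------------------------------------------------------------------------
# Survival oracles
# ---------------------------------------------------------------------------

def harrell_cindex(lp, time, event) -> float:
    """Exhaustive usable-pair enumeration per Harrell's conventions."""
    num = den = 0.0
    n = len(lp)
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj, ei, ej = time[i], time[j], event[i], event[j]
            if ti == tj:
                if ei + ej != 1:
                    continue  # both events or both censored at same time: unusable
                a, b = (i, j) if ei == 1 else (j, i)  # a is the event
                usable = True
            elif ti < tj:
                if ei != 1:
                    continue
                a, b = i, j
                usable = True
            else:
                if ej != 1:
                    continue
                a, b = j, i
                usable = True
            if usable:
                den += 1
                if lp[a] > lp[b]:
                    num += 1
                elif lp[a] == lp[b]:
                    num += 0.5
    return num / den


def rank_sum_auc(score, case) -> float:
    """Mann-Whitney AUC for a binary outcome."""
    pos = [s for s, c in zip(score, case) if c]
    neg = [s for s, c in zip(score, case) if not c]
    num = 0.0
    for a in pos:
        for b in neg:
            num += 1.0 if a > b else (0.5 if a == b else 0.0)
    return num / (len(pos) * len(neg))


def nri_idi_uncensored(p_old, p_new, case) -> tuple[float, float]:
    """Direct evaluation of the category-free NRI and IDI definitions."""
    case = np.asarray(case, bool)
    up = np.asarray(p_new) > np.asarray(p_old)
    down = np.asarray(p_new) < np.asarray(p_old)
    nri = (
        up[case].mean() - down[case].mean() + down[~case].mean() - up[~case].mean()
    )
    diff = np.asarray(p_new) - np.asarray(p_old)
    idi = diff[case].mean() - diff[~case].mean()
    return float(nri), float(idi)


def newton_cox(X, time, event, tol=1e-10, max_iter=100) -> np.ndarray:
    """Unpenalized Cox partial-likelihood MLE (Breslow ties), Newton-Raphson."""
    X = np.asarray(X, float)
    n, p = X.shape
    beta = np.zeros(p)
    order = np.argsort(time)
    for _ in range(max_iter):
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        for i in range(n):
            if event[i] != 1:
                continue
            at_risk = [j for j in range(n) if time[j] >= time[i]]
            w = np.exp(X[at_risk] @ beta)
            sw = w.sum()
            xbar = (w[:, None] * X[at_risk]).sum(axis=0) / sw
            grad += X[i] - xbar
            xc = X[at_risk] - xbar
            hess -= (w[:, None, None] * (xc[:, :, None] * xc[:, None, :])).sum(axis=0) / sw
        step = np.linalg.solve(hess, grad)
        beta = beta - step
        if np.abs(step).max() < tol:
            break
    return beta


def weibull_ph_event_prob(beta, z_density, shape, scale, horizon, grid=4001) -> float:
    """P(T <= horizon) under a Weibull-PH model mixing over a latent z.

    ``z_density`` is a (z, pdf) tuple on a fine grid; integration by the
    trapezoid rule.
    """
    z, pdf = z_density
    h0 = (horizon / scale) ** shape
    p_z = 1.0 - np.exp(-h0 * np.exp(beta * z))
    return float(np.trapezoid(p_z * pdf, z))
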