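"""Texture matrices (GLCM, GLRLM, GLSZM, NGTDM, NGLDM) and their features.

Conventions:

* input is a discretized region embedded in its bounding box: an integer
  array of grey levels 1..L with an in-region mask;
* GLCM: distance 1, the 13 unique 3D directions, each matrix symmetrized,
  normalized, then averaged over directions with at least one pair;
* GLRLM: maximal runs along the same 13 directions, count matrices averaged
  over directions;
* GLSZM: 26-connected zones of equal grey level;
* NGTDM / NGLDM: 26-neighbourhood, only in-region neighbours counted.

Feature scalars follow the standard (IBSI-style) formulas; degenerate
denominators are guarded (see ``COARSENESS_CAP``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .catalogue import TextureGeometrySpec
from .firstorder import EmptyRegionError

EPS = np.finfo(np.float64).eps
#: value returned for NGTDM coarseness when its denominator vanishes
#: (e.g. a perfectly constant region)
COARSENESS_CAP = 1e6

# 13 unique distance-1 3D directions (26-neighbourhood up to sign):
# offsets whose first nonzero component is positive.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0) and ((a, b, c) > (0, 0, 0))
)

OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
)


@dataclass
class TextureMatrices:
    glcm: np.ndarray        # (L, L) symmetric, normalized, direction-averaged
    glrlm: np.ndarray       # (L, max_run) counts averaged over directions
    glszm: np.ndarray       # (L, max_zone) zone counts
    ngtdm_n: np.ndarray     # (L,) valid-voxel counts per level
    ngtdm_p: np.ndarray     # (L,) probabilities
    ngtdm_s: np.ndarray     # (L,) neighbourhood-difference sums
    ngldm: np.ndarray       # (L, max_dependence) dependence counts (col j = j+1 dependent voxels incl. self)
    n_voxels: int
    n_levels: int


def _shift_slices(shape: tuple[int, ...], offset: tuple[int, ...]):
    """Index slices (a, b) such that arr[a] and arr[b] are offset by ``offset``."""
    sl_a, sl_b = [], []
    for dim, off in zip(shape, offset):
        if off >= 0:
            sl_a.append(slice(0, dim - off))
            sl_b.append(slice(off, dim))
        else:
            sl_a.append(slice(-off, dim))
            sl_b.append(slice(0, dim + off))
    return tuple(sl_a), tuple(sl_b)


def _glcm(
    levels: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    distance: int,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> np.ndarray:
    acc = np.zeros((n_levels, n_levels))
    n_dirs = 0
    for d in directions:
        off = tuple(distance * o for o in d)
        sl_a, sl_b = _shift_slices(levels.shape, off)
        valid = mask[sl_a] & mask[sl_b]
        if not valid.any():
            continue
        la = levels[sl_a][valid] - 1
        lb = levels[sl_b][valid] - 1
        mat = np.bincount(la * n_levels + lb, minlength=n_levels * n_levels).reshape(
            n_levels, n_levels
        ).astype(np.float64)
        mat = mat + mat.T
        acc += mat / mat.sum()
        n_dirs += 1
    if n_dirs == 0:
        # isolated voxels: all mass on the diagonal of observed levels
        lev = levels[mask]
        mat = np.zeros((n_levels, n_levels))
        for g in np.unique(lev):
            mat[g - 1, g - 1] = np.count_nonzero(lev == g)
        return mat / mat.sum()
    return acc / n_dirs


def _glrlm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    max_run = max(levels.shape)
    acc = np.zeros((n_levels, max_run))
    mask_i = mask.astype(np.int32)
    for d in DIRECTIONS_13:
        sl_a, sl_b = _shift_slices(levels.shape, d)
        # cont[p]: the run through p continues at p + d
        cont = np.zeros(levels.shape, dtype=bool)
        cont[sl_a] = mask[sl_a] & mask[sl_b] & (levels[sl_a] == levels[sl_b])
        start = mask.copy()
        start[sl_b] &= ~cont[sl_a]
        # remaining run length r[p] = 1 + r[p + d] while the run continues;
        # the fixed point is reached after max-run-length sweeps
        r = mask_i.copy()
        while True:
            nxt = np.zeros_like(r)
            nxt[sl_a] = r[sl_b]
            new_r = np.where(cont, 1 + nxt, mask_i)
            if np.array_equal(new_r, r):
                break
            r = new_r
        np.add.at(acc, (levels[start] - 1, r[start] - 1), 1.0)
    return acc / len(DIRECTIONS_13)


def _glszm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    # zones = connected components (26-connectivity) of the same-level
    # neighbour graph, found in a single union pass over the 13 directions
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    flat = np.nonzero(mask)
    n_vox = len(flat[0])
    idx = np.full(levels.shape, -1, dtype=np.int64)
    idx[flat] = np.arange(n_vox)
    rows, cols = [], []
    for d in DIRECTIONS_13:
        sl_a, sl_b = _shift_slices(levels.shape, d)
        eq = mask[sl_a] & mask[sl_b] & (levels[sl_a] == levels[sl_b])
        rows.append(idx[sl_a][eq])
        cols.append(idx[sl_b][eq])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    graph = coo_matrix((np.ones(len(r), dtype=np.int8), (r, c)), shape=(n_vox, n_vox))
    n_zones, zone_of = connected_components(graph, directed=False)
    sizes = np.bincount(zone_of, minlength=n_zones)
    zone_level = np.zeros(n_zones, dtype=np.int64)
    zone_level[zone_of] = levels[flat]  # consistent within a zone by construction
    acc = np.zeros((n_levels, int(sizes.max())))
    np.add.at(acc, (zone_level - 1, sizes - 1), 1.0)
    return acc


def _ngtdm(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    maskf = mask.astype(np.float64)
    neighbour_sum = ndimage.correlate(levels * maskf, kernel, mode="constant")
    neighbour_cnt = ndimage.correlate(maskf, kernel, mode="constant")
    valid = mask & (neighbour_cnt > 0)
    n = np.zeros(n_levels)
    s = np.zeros(n_levels)
    if valid.any():
        lv = levels[valid]
        avg = neighbour_sum[valid] / neighbour_cnt[valid]
        diff = np.abs(lv - avg)
        n = np.bincount(lv - 1, minlength=n_levels).astype(np.float64)
        s = np.bincount(lv - 1, weights=diff, minlength=n_levels)
    total = n.sum()
    p = n / total if total > 0 else n
    return n, p, s


def _ngldm(levels: np.ndarray, mask: np.ndarray, n_levels: int, alpha: int) -> np.ndarray:
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_26:
        sl_a, sl_b = _shift_slices(levels.shape, off)
        close = (
            mask[sl_a]
            & mask[sl_b]
            & (np.abs(levels[sl_a] - levels[sl_b]) <= alpha)
        )
        dep[sl_a] += close
    lev = levels[mask] - 1
    k = dep[mask]  # number of dependent neighbours, 0..26
    mat = np.zeros((n_levels, 27))
    np.add.at(mat, (lev, k), 1.0)
    last = int(np.max(np.nonzero(mat.sum(axis=0))[0])) + 1
    return mat[:, :last]


def texture_matrices(
    levels: np.ndarray,
    mask: np.ndarray,
    geometry: TextureGeometrySpec | None = None,
    n_levels: int | None = None,
) -> TextureMatrices:
    """Compute all five texture matrices of a discretized region.

    ``levels`` is the bounding-box grid of grey levels (1..L inside the
    region; values outside the mask are ignored), ``mask`` the in-region
    indicator of the same shape.
    """
    geometry = geometry or TextureGeometrySpec()
    levels = np.asarray(levels, dtype=np.int64)
    mask = np.asarray(mask, dtype=bool)
    if levels.shape != mask.shape:
        raise ValueError("levels and mask shapes differ")
    if not mask.any():
        raise EmptyRegionError("cannot compute texture matrices of an empty region")
    if levels[mask].min() < 1:
        raise ValueError("grey levels must be >= 1 inside the region")
    L = int(n_levels if n_levels is not None else levels[mask].max())
    n_vox = int(mask.sum())
    glcm = _glcm(levels, mask, L, geometry.glcm_distance)
    glrlm = _glrlm(levels, mask, L)
    glszm = _glszm(levels, mask, L)
    ngtdm_n, ngtdm_p, ngtdm_s = _ngtdm(levels, mask, L)
    ngldm = _ngldm(levels, mask, L, geometry.ngldm_alpha)
    return TextureMatrices(
        glcm=glcm, glrlm=glrlm, glszm=glszm,
        ngtdm_n=ngtdm_n, ngtdm_p=ngtdm_p, ngtdm_s=ngtdm_s,
        ngldm=ngldm, n_voxels=n_vox, n_levels=L,
    )


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """The 22 default GLCM scalars from a normalized symmetric matrix."""
    L = P.shape[0]
    i = np.arange(1, L + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))
    # diagonal and cross-diagonal distributions
    p_sum = np.zeros(2 * L + 1)       # index k = i + j, 2..2L
    p_diff = np.zeros(L)              # index k = |i - j|, 0..L-1
    np.add.at(p_sum, (ii + jj).ravel(), P.ravel())
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())
    k_sum = np.arange(2 * L + 1)
    k_diff = np.arange(L)

    contrast = float((((ii - jj) ** 2) * P).sum())
    dissimilarity = float((np.abs(ii - jj) * P).sum())
    if sd_x * sd_y > 0:
        correlation = float(((ii * jj * P).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 1.0
    off_diag = ii != jj
    inverse_variance = float((P[off_diag] / (ii - jj)[off_diag] ** 2).sum())
    HXY = _entropy2(P.ravel())
    pxy = np.outer(px, py)
    nz = (P > 0) & (pxy > 0)
    HXY1 = float(-(P[nz] * np.log2(pxy[nz])).sum())
    HXY2 = _entropy2(pxy.ravel())
    HX = _entropy2(px)
    HY = _entropy2(py)
    denom = max(HX, HY)
    imc1 = float((HXY - HXY1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - HXY)))))
    da = float((k_diff * p_diff).sum())
    return {
        "joint_maximum": float(P.max()),
        "joint_average": mu_x,
        "joint_variance": float((((ii - mu_x) ** 2) * P).sum()),
        "joint_entropy": HXY,
        "joint_energy": float((P ** 2).sum()),
        "contrast": contrast,
        "dissimilarity": dissimilarity,
        "inverse_difference": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "inverse_difference_moment": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "inverse_variance": inverse_variance,
        "correlation": correlation,
        "autocorrelation": float((ii * jj * P).sum()),
        "cluster_tendency": float((((ii + jj - mu_x - mu_y) ** 2) * P).sum()),
        "cluster_shade": float((((ii + jj - mu_x - mu_y) ** 3) * P).sum()),
        "cluster_prominence": float((((ii + jj - mu_x - mu_y) ** 4) * P).sum()),
        "sum_average": float((k_sum * p_sum).sum()),
        "sum_entropy": _entropy2(p_sum),
        "difference_average": da,
        "difference_variance": float((((k_diff - da) ** 2) * p_diff).sum()),
        "difference_entropy": _entropy2(p_diff),
        "imc1": imc1,
        "imc2": imc2,
    }


def _run_zone_features(M: np.ndarray, n_voxels: int, prefix: str) -> dict[str, float]:
    """Shared run-length / size-zone formulas: M[g-1, j-1] counts of grey level
    g with run length / zone size j."""
    Ns = M.sum()
    L, J = M.shape
    g = np.arange(1, L + 1)
    j = np.arange(1, J + 1)
    gg, jj = np.meshgrid(g, j, indexing="ij")
    rj = M.sum(axis=0)
    gi = M.sum(axis=1)
    return {
        f"{prefix}_small": float((rj / j ** 2).sum() / Ns),
        f"{prefix}_large": float((rj * j ** 2).sum() / Ns),
        "grey_level_nonuniformity": float((gi ** 2).sum() / Ns),
        f"{prefix}_nonuniformity": float((rj ** 2).sum() / Ns),
        f"{prefix}_percentage": float(Ns / n_voxels),
        "low_grey_level": float((gi / g ** 2).sum() / Ns),
        "high_grey_level": float((gi * g ** 2).sum() / Ns),
        "small_low": float((M / (gg ** 2 * jj ** 2)).sum() / Ns),
        "small_high": float((M * gg ** 2 / jj ** 2).sum() / Ns),
        "large_low": float((M * jj ** 2 / gg ** 2).sum() / Ns),
        "large_high": float((M * gg ** 2 * jj ** 2).sum() / Ns),
    }


def glrlm_features(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 11 default run-length scalars."""
    f = _run_zone_features(R, n_voxels, "run")
    return {
        "short_run_emphasis": f["run_small"],
        "long_run_emphasis": f["run_large"],
        "grey_level_nonuniformity": f["grey_level_nonuniformity"],
        "run_length_nonuniformity": f["run_nonuniformity"],
        "run_percentage": f["run_percentage"],
        "low_grey_level_run_emphasis": f["low_grey_level"],
        "high_grey_level_run_emphasis": f["high_grey_level"],
        "short_run_low_grey_level_emphasis": f["small_low"],
        "short_run_high_grey_level_emphasis": f["small_high"],
        "long_run_low_grey_level_emphasis": f["large_low"],
        "long_run_high_grey_level_emphasis": f["large_high"],
    }


def glszm_features(S: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 11 default size-zone scalars."""
    f = _run_zone_features(S, n_voxels, "zone")
    return {
        "small_zone_emphasis": f["zone_small"],
        "large_zone_emphasis": f["zone_large"],
        "grey_level_nonuniformity": f["grey_level_nonuniformity"],
        "zone_size_nonuniformity": f["zone_nonuniformity"],
        "zone_percentage": f["zone_percentage"],
        "low_grey_level_zone_emphasis": f["low_grey_level"],
        "high_grey_level_zone_emphasis": f["high_grey_level"],
        "small_zone_low_grey_level_emphasis": f["small_low"],
        "small_zone_high_grey_level_emphasis": f["small_high"],
        "large_zone_low_grey_level_emphasis": f["large_low"],
        "large_zone_high_grey_level_emphasis": f["large_high"],
    }


def ngtdm_features(n: np.ndarray, p: np.ndarray, s: np.ndarray) -> dict[str, float]:
    """The 5 neighbourhood grey tone difference scalars (Amadasun/IBSI forms).

    Coarseness is 1 / sum(p_i s_i): the inverse of the probability-weighted
    neighbourhood-difference sum; it is capped at ``COARSENESS_CAP`` when the
    denominator vanishes (constant regions).
    """
    L = len(p)
    i = np.arange(1, L + 1)
    present = p > 0
    N = n.sum()
    ngp = int(present.sum())
    denom = float((p * s).sum())
    coarseness = min(COARSENESS_CAP, 1.0 / denom) if denom > 0 else COARSENESS_CAP
    if ngp <= 1 or N == 0:
        return {
            "coarseness": coarseness, "contrast": 0.0, "busyness": 0.0,
            "complexity": 0.0, "strength": 0.0,
        }
    ip = i[present]
    pp = p[present]
    sp = s[present]
    di = ip[:, None] - ip[None, :]
    contrast = float(
        (pp[:, None] * pp[None, :] * di ** 2).sum() / (ngp * (ngp - 1)) * (sp.sum() / N)
    )
    busy_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
    busyness = float((pp * sp).sum() / busy_den) if busy_den > 0 else 0.0
    pair_w = (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]) / (
        pp[:, None] + pp[None, :]
    )
    complexity = float((np.abs(di) * pair_w).sum() / N)
    s_sum = float(sp.sum())
    strength = (
        float(((pp[:, None] + pp[None, :]) * di ** 2).sum() / s_sum) if s_sum > 0 else 0.0
    )
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


def ngldm_features(M: np.ndarray) -> dict[str, float]:
    """The 5 default dependence-matrix scalars.

    Column j of ``M`` corresponds to a dependence size of j+1 (the voxel plus
    j neighbours within alpha of its level).
    """
    Ns = M.sum()
    L, K = M.shape
    j = np.arange(1, K + 1)  # dependence size = neighbours + 1
    mj = M.sum(axis=0)
    pj = mj / Ns
    mu = float((j * pj).sum())
    pk = (M / Ns).ravel()
    return {
        "low_dependence_emphasis": float((mj / j ** 2).sum() / Ns),
        "high_dependence_emphasis": float((mj * j ** 2).sum() / Ns),
        "dependence_nonuniformity": float((mj ** 2).sum() / Ns),
        "dependence_variance": float((((j - mu) ** 2) * pj).sum()),
        "dependence_entropy": _entropy2(pk),
    }


def texture_features(mats: TextureMatrices) -> dict[str, dict[str, float]]:
    """All texture scalars keyed by family."""
    return {
        "glcm": glcm_features(mats.glcm),
        "glrlm": glrlm_features(mats.glrlm, mats.n_voxels),
        "glszm": glszm_features(mats.glszm, mats.n_voxels),
        "ngtdm": ngtdm_features(mats.ngtdm_n, mats.ngtdm_p, mats.ngtdm_s),
        "ngldm": ngldm_features(mats.ngldm),
    }
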