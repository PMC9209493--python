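"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with plain Python loops and explicit
formulas, independent of the package's vectorized implementations.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

OFFSETS_26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]
DIRECTIONS_13 = [d for d in OFFSETS_26 if d > (0, 0, 0)]


def _in(shape, p):
    return all(0 <= p[i] < shape[i] for i in range(3))


def brute_glcm(levels, mask, n_levels, directions=None):
    """Pair enumeration: symmetric, normalized per direction, then averaged."""
    directions = directions or DIRECTIONS_13
    shape = levels.shape
    mats = []
    for d in directions:
        counts = [[0.0] * n_levels for _ in range(n_levels)]
        total = 0
        for p in product(*map(range, shape)):
            if not mask[p]:
                continue
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if _in(shape, q) and mask[q]:
                a, b = levels[p] - 1, levels[q] - 1
                counts[a][b] += 1
                counts[b][a] += 1
                total += 2
        if total:
            mats.append([[c / total for c in row] for row in counts])
    if not mats:
        # isolated voxels: diagonal mass
        counts = [[0.0] * n_levels for _ in range(n_levels)]
        tot = 0
        for p in product(*map(range, shape)):
            if mask[p]:
                counts[levels[p] - 1][levels[p] - 1] += 1
                tot += 1
        return np.asarray([[c / tot for c in row] for row in counts])
    out = np.zeros((n_levels, n_levels))
    for m in mats:
        out += np.asarray(m)
    return out / len(mats)


def brute_glrlm(levels, mask, n_levels, max_run):
    """Maximal-run walking per direction, counts averaged over directions."""
    shape = levels.shape
    acc = np.zeros((n_levels, max_run))
    for d in DIRECTIONS_13:
        for p in product(*map(range, shape)):
            if not mask[p]:
                continue
            prev = (p[0] - d[0], p[1] - d[1], p[2] - d[2])
            if _in(shape, prev) and mask[prev] and levels[prev] == levels[p]:
                continue  # not a run start
            length = 1
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            while _in(shape, q) and mask[q] and levels[q] == levels[p]:
                length += 1
                q = (q[0] + d[0], q[1] + d[1], q[2] + d[2])
            acc[levels[p] - 1, length - 1] += 1
    return acc / len(DIRECTIONS_13)


def brute_glszm(levels, mask, n_levels, n_voxels):
    """Flood-fill (26-connected) zone enumeration."""
    shape = levels.shape
    acc = np.zeros((n_levels, n_voxels))
    seen = set()
    for p in product(*map(range, shape)):
        if not mask[p] or p in seen:
            continue
        g = levels[p]
        stack = [p]
        zone = set()
        while stack:
            cur = stack.pop()
            if cur in zone or not _in(shape, cur) or not mask[cur] or levels[cur] != g:
                continue
            zone.add(cur)
            for d in OFFSETS_26:
                stack.append((cur[0] + d[0], cur[1] + d[1], cur[2] + d[2]))
        seen |= zone
        acc[g - 1, len(zone) - 1] += 1
    last = 1
    for j in range(n_voxels):
        if acc[:, j].sum() > 0:
            last = j + 1
    return acc[:, :last]


def brute_ngtdm(levels, mask, n_levels):
    shape = levels.shape
    n = np.zeros(n_levels)
    s = np.zeros(n_levels)
    for p in product(*map(range, shape)):
        if not mask[p]:
            continue
        nb = []
        for d in OFFSETS_26:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if _in(shape, q) and mask[q]:
                nb.append(levels[q])
        if nb:
            g = levels[p]
            n[g - 1] += 1
            s[g - 1] += abs(g - sum(nb) / len(nb))
    total = n.sum()
    p_arr = n / total if total else n
    return n, p_arr, s


def brute_ngldm(levels, mask, n_levels, alpha=0):
    shape = levels.shape
    mat = np.zeros((n_levels, 27))
    for p in product(*map(range, shape)):
        if not mask[p]:
            continue
        k = 0
        for d in OFFSETS_26:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if _in(shape, q) and mask[q] and abs(levels[q] - levels[p]) <= alpha:
                k += 1
        mat[levels[p] - 1, k] += 1
    last = 1
    for j in range(27):
        if mat[:, j].sum() > 0:
            last = j + 1
    return mat[:, :last]


# --- feature formula oracles (explicit loops, math.log2) -------------------


def _xlog2(v):
    return v * math.log2(v) if v > 0 else 0.0


def oracle_glcm_features(P):
    L = P.shape[0]
    px = [sum(P[i][j] for j in range(L)) for i in range(L)]
    py = [sum(P[i][j] for i in range(L)) for j in range(L)]
    mu_x = sum((i + 1) * px[i] for i in range(L))
    mu_y = sum((j + 1) * py[j] for j in range(L))
    sd_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(L)))
    sd_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(L)))
    p_sum = [0.0] * (2 * L + 1)
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_sum[i + j + 2] += P[i][j]
            p_diff[abs(i - j)] += P[i][j]
    out = {}
    out["joint_maximum"] = max(max(row) for row in P)
    out["joint_average"] = mu_x
    out["joint_variance"] = sum(
        (i + 1 - mu_x) ** 2 * P[i][j] for i in range(L) for j in range(L)
    )
    out["joint_entropy"] = -sum(_xlog2(P[i][j]) for i in range(L) for j in range(L))
    out["joint_energy"] = sum(P[i][j] ** 2 for i in range(L) for j in range(L))
    out["contrast"] = sum((i - j) ** 2 * P[i][j] for i in range(L) for j in range(L))
    out["dissimilarity"] = sum(abs(i - j) * P[i][j] for i in range(L) for j in range(L))
    out["inverse_difference"] = sum(
        P[i][j] / (1 + abs(i - j)) for i in range(L) for j in range(L)
    )
    out["inverse_difference_moment"] = sum(
        P[i][j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L)
    )
    out["inverse_variance"] = sum(
        P[i][j] / (i - j) ** 2 for i in range(L) for j in range(L) if i != j
    )
    if sd_x * sd_y > 0:
        out["correlation"] = (
            sum((i + 1) * (j + 1) * P[i][j] for i in range(L) for j in range(L))
            - mu_x * mu_y
        ) / (sd_x * sd_y)
    else:
        out["correlation"] = 1.0
    out["autocorrelation"] = sum(
        (i + 1) * (j + 1) * P[i][j] for i in range(L) for j in range(L)
    )
    for power, name in ((2, "cluster_tendency"), (3, "cluster_shade"), (4, "cluster_prominence")):
        out[name] = sum(
            (i + 1 + j + 1 - mu_x - mu_y) ** power * P[i][j]
            for i in range(L)
            for j in range(L)
        )
    out["sum_average"] = sum(k * p_sum[k] for k in range(2 * L + 1))
    out["sum_entropy"] = -sum(_xlog2(v) for v in p_sum)
    da = sum(k * p_diff[k] for k in range(L))
    out["difference_average"] = da
    out["difference_variance"] = sum((k - da) ** 2 * p_diff[k] for k in range(L))
    out["difference_entropy"] = -sum(_xlog2(v) for v in p_diff)
    HX = -sum(_xlog2(v) for v in px)
    HY = -sum(_xlog2(v) for v in py)
    HXY = out["joint_entropy"]
    HXY1 = -sum(
        P[i][j] * math.log2(px[i] * py[j])
        for i in range(L)
        for j in range(L)
        if P[i][j] > 0 and px[i] * py[j] > 0
    )
    HXY2 = -sum(_xlog2(px[i] * py[j]) for i in range(L) for j in range(L))
    out["imc1"] = (HXY - HXY1) / max(HX, HY) if max(HX, HY) > 0 else 0.0
    out["imc2"] = math.sqrt(max(0.0, 1 - math.exp(-2 * (HXY2 - HXY))))
    return out


def _oracle_run_zone(M, n_voxels):
    L = len(M)
    J = len(M[0])
    Ns = sum(sum(row) for row in M)
    rj = [sum(M[i][j] for i in range(L)) for j in range(J)]
    gi = [sum(M[i][j] for j in range(J)) for i in range(L)]
    return {
        "small": sum(rj[j] / (j + 1) ** 2 for j in range(J)) / Ns,
        "large": sum(rj[j] * (j + 1) ** 2 for j in range(J)) / Ns,
        "gln": sum(v**2 for v in gi) / Ns,
        "nun": sum(v**2 for v in rj) / Ns,
        "pct": Ns / n_voxels,
        "lgl": sum(gi[i] / (i + 1) ** 2 for i in range(L)) / Ns,
        "hgl": sum(gi[i] * (i + 1) ** 2 for i in range(L)) / Ns,
        "sl": sum(
            M[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(L) for j in range(J)
        ) / Ns,
        "sh": sum(
            M[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(L) for j in range(J)
        ) / Ns,
        "ll": sum(
            M[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(L) for j in range(J)
        ) / Ns,
        "lh": sum(
            M[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(L) for j in range(J)
        ) / Ns,
    }


def oracle_glrlm_features(R, n_voxels):
    f = _oracle_run_zone(R, n_voxels)
    return {
        "short_run_emphasis": f["small"],
        "long_run_emphasis": f["large"],
        "grey_level_nonuniformity": f["gln"],
        "run_length_nonuniformity": f["nun"],
        "run_percentage": f["pct"],
        "low_grey_level_run_emphasis": f["lgl"],
        "high_grey_level_run_emphasis": f["hgl"],
        "short_run_low_grey_level_emphasis": f["sl"],
        "short_run_high_grey_level_emphasis": f["sh"],
        "long_run_low_grey_level_emphasis": f["ll"],
        "long_run_high_grey_level_emphasis": f["lh"],
    }


def oracle_glszm_features(S, n_voxels):
    f = _oracle_run_zone(S, n_voxels)
    return {
        "small_zone_emphasis": f["small"],
        "large_zone_emphasis": f["large"],
        "grey_level_nonuniformity": f["gln"],
        "zone_size_nonuniformity": f["nun"],
        "zone_percentage": f["pct"],
        "low_grey_level_zone_emphasis": f["lgl"],
        "high_grey_level_zone_emphasis": f["hgl"],
        "small_zone_low_grey_level_emphasis": f["sl"],
        "small_zone_high_grey_level_emphasis": f["sh"],
        "large_zone_low_grey_level_emphasis": f["ll"],
        "large_zone_high_grey_level_emphasis": f["lh"],
    }


def oracle_ngtdm_features(n, p, s, cap=1e6):
    L = len(p)
    N = sum(n)
    present = [i for i in range(L) if p[i] > 0]
    ngp = len(present)
    denom = sum(p[i] * s[i] for i in range(L))
    coarseness = min(cap, 1.0 / denom) if denom > 0 else cap
    if ngp <= 1 or N == 0:
        return {
            "coarseness": coarseness, "contrast": 0.0, "busyness": 0.0,
            "complexity": 0.0, "strength": 0.0,
        }
    contrast = (
        sum(
            p[i] * p[j] * (i - j) ** 2 for i in present for j in present
        )
        / (ngp * (ngp - 1))
    ) * (sum(s[i] for i in present) / N)
    busy_den = sum(
        abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
    )
    busyness = (
        sum(p[i] * s[i] for i in present) / busy_den if busy_den > 0 else 0.0
    )
    complexity = (
        sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in present
            for j in present
        )
        / N
    )
    s_sum = sum(s[i] for i in present)
    strength = (
        sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / s_sum
        if s_sum > 0
        else 0.0
    )
    return {
        "coarseness": coarseness, "contrast": contrast, "busyness": busyness,
        "complexity": complexity, "strength": strength,
    }


def oracle_ngldm_features(M):
    L = len(M)
    K = len(M[0])
    Ns = sum(sum(row) for row in M)
    mj = [sum(M[i][j] for i in range(L)) for j in range(K)]
    pj = [v / Ns for v in mj]
    mu = sum((j + 1) * pj[j] for j in range(K))
    ent = -sum(_xlog2(M[i][j] / Ns) for i in range(L) for j in range(K))
    return {
        "low_dependence_emphasis": sum(mj[j] / (j + 1) ** 2 for j in range(K)) / Ns,
        "high_dependence_emphasis": sum(mj[j] * (j + 1) ** 2 for j in range(K)) / Ns,
        "dependence_nonuniformity": sum(v**2 for v in mj) / Ns,
        "dependence_variance": sum((j + 1 - mu) ** 2 * pj[j] for j in range(K)),
        "dependence_entropy": ent,
    }


def oracle_bh_kept(pvals, level):
    """Largest k with p_(k) <= k * level / m; keep everything at or below."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * level / m:
            k_star = rank
    kept = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= k_star:
            kept[idx] = True
    return kept


def oracle_auc(scores, labels):
    """Pairwise comparison AUC with tie midranks."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))
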