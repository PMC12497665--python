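"""Independent brute-force oracles used across the test suite.

Everything here is written as plain Python loops, deliberately avoiding the
vectorized code paths of the package, so that agreement between the two is
meaningful evidence of correctness.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

NEIGHBORS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


# ------------------------------------------------------------- morphology

def brute_erode_slicewise(vox: np.ndarray, radius: int) -> np.ndarray:
    """Edge-slice removal + per-slice disk erosion by scanning every voxel's disk."""
    nx, ny, nz = vox.shape
    occupied = [vox[:, :, z].any() for z in range(nz)]
    out = np.zeros_like(vox)
    for z in range(nz):
        if not occupied[z]:
            continue
        if z - 1 < 0 or z + 1 >= nz or not occupied[z - 1] or not occupied[z + 1]:
            continue
        for i in range(nx):
            for j in range(ny):
                if not vox[i, j, z]:
                    continue
                keep = True
                for di in range(-radius, radius + 1):
                    for dj in range(-radius, radius + 1):
                        if di * di + dj * dj > radius * radius:
                            continue
                        ii, jj = i + di, j + dj
                        if not (0 <= ii < nx and 0 <= jj < ny and vox[ii, jj, z]):
                            keep = False
                if keep:
                    out[i, j, z] = True
    return out


# ----------------------------------------------------------------- metrics

def brute_roc_auc(labels, scores) -> float:
    """Exhaustive pairwise Mann-Whitney comparison, ties counted half."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_average_precision(labels, scores) -> float:
    """Step-wise sum of precision x recall increment over descending scores."""
    order = sorted(range(len(labels)), key=lambda i: -scores[i])
    n_pos = sum(labels)
    tp = fp = 0
    ap = 0.0
    prev_recall = 0.0
    # group tied scores: metrics step once per distinct threshold
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            tp += labels[order[j]]
            fp += 1 - labels[order[j]]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += precision * (recall - prev_recall)
        prev_recall = recall
        i = j
    return ap


# ----------------------------------------------------------------- firstorder

def brute_percentile(values, q) -> float:
    """Linear interpolation between closest ranks."""
    xs = sorted(values)
    rank = (len(xs) - 1) * q / 100.0
    lo = int(math.floor(rank))
    hi = int(math.ceil(rank))
    frac = rank - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def brute_first_order(values, bin_width):
    """Two-pass / sort-based reference for the first-order statistics."""
    xs = [float(v) for v in values]
    n = len(xs)
    mean = sum(xs) / n
    var = sum((x - mean) ** 2 for x in xs) / n
    sd = math.sqrt(var)
    p10 = brute_percentile(xs, 10)
    p90 = brute_percentile(xs, 90)
    robust = [x for x in xs if p10 <= x <= p90]
    rmean = sum(robust) / len(robust)
    counts = {}
    offset = math.floor(min(xs) / bin_width)
    for x in xs:
        lev = math.floor(x / bin_width) - offset + 1
        counts[lev] = counts.get(lev, 0) + 1
    probs = [c / n for c in counts.values()]
    out = {
        "Mean": mean,
        "Variance": var,
        "StandardDeviation": sd,
        "Minimum": min(xs),
        "Maximum": max(xs),
        "Range": max(xs) - min(xs),
        "10Percentile": p10,
        "90Percentile": p90,
        "Median": brute_percentile(xs, 50),
        "InterquartileRange": brute_percentile(xs, 75) - brute_percentile(xs, 25),
        "Energy": sum(x * x for x in xs),
        "RootMeanSquared": math.sqrt(sum(x * x for x in xs) / n),
        "MeanAbsoluteDeviation": sum(abs(x - mean) for x in xs) / n,
        "RobustMeanAbsoluteDeviation": sum(abs(x - rmean) for x in robust) / len(robust),
        "Entropy": -sum(p * math.log2(p) for p in probs),
        "Uniformity": sum(p * p for p in probs),
    }
    if var > 0:
        out["Skewness"] = (sum((x - mean) ** 3 for x in xs) / n) / var ** 1.5
        out["Kurtosis"] = (sum((x - mean) ** 4 for x in xs) / n) / var ** 2
    else:
        out["Skewness"] = 0.0
        out["Kurtosis"] = 0.0
    return out


# ------------------------------------------------------------------ texture

def brute_glcm(levels: np.ndarray, n_levels: int, d) -> np.ndarray:
    """Exhaustive symmetric pair count at offset d."""
    P = np.zeros((n_levels, n_levels))
    nx, ny, nz = levels.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                a = levels[i, j, k]
                if a == 0:
                    continue
                ii, jj, kk = i + d[0], j + d[1], k + d[2]
                if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz:
                    b = levels[ii, jj, kk]
                    if b > 0:
                        P[a - 1, b - 1] += 1
                        P[b - 1, a - 1] += 1
    return P


def brute_glrlm(levels: np.ndarray, n_levels: int, d):
    """Enumerate maximal runs along direction d by walking each line."""
    nx, ny, nz = levels.shape
    runs = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                a = levels[i, j, k]
                if a == 0:
                    continue
                pi, pj, pk = i - d[0], j - d[1], k - d[2]
                if (0 <= pi < nx and 0 <= pj < ny and 0 <= pk < nz
                        and levels[pi, pj, pk] == a):
                    continue  # not a run start
                length = 1
                ci, cj, ck = i + d[0], j + d[1], k + d[2]
                while (0 <= ci < nx and 0 <= cj < ny and 0 <= ck < nz
                       and levels[ci, cj, ck] == a):
                    length += 1
                    ci, cj, ck = ci + d[0], cj + d[1], ck + d[2]
                runs.append((a, length))
    max_len = max((l for _, l in runs), default=1)
    P = np.zeros((n_levels, max_len))
    for g, l in runs:
        P[g - 1, l - 1] += 1
    return P


def brute_glszm_zones(levels: np.ndarray):
    """Flood-fill 26-connected equal-level zones; returns [(level, size)]."""
    visited = np.zeros(levels.shape, dtype=bool)
    zones = []
    nx, ny, nz = levels.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if levels[i, j, k] == 0 or visited[i, j, k]:
                    continue
                g = levels[i, j, k]
                stack = [(i, j, k)]
                visited[i, j, k] = True
                size = 0
                while stack:
                    ci, cj, ck = stack.pop()
                    size += 1
                    for di, dj, dk in NEIGHBORS_26:
                        ni, nj, nk = ci + di, cj + dj, ck + dk
                        if (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz
                                and not visited[ni, nj, nk]
                                and levels[ni, nj, nk] == g):
                            visited[ni, nj, nk] = True
                            stack.append((ni, nj, nk))
                zones.append((int(g), size))
    return zones


def brute_ngtdm(levels: np.ndarray, n_levels: int):
    """(n_i, s_i, Nvp) by looping every voxel's 26-neighbourhood."""
    nx, ny, nz = levels.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    nvp = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                g = levels[i, j, k]
                if g == 0:
                    continue
                neigh = []
                for di, dj, dk in NEIGHBORS_26:
                    ni, nj, nk = i + di, j + dj, k + dk
                    if (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz
                            and levels[ni, nj, nk] > 0):
                        neigh.append(levels[ni, nj, nk])
                if not neigh:
                    continue
                nvp += 1
                n_i[g - 1] += 1
                s_i[g - 1] += abs(g - sum(neigh) / len(neigh))
    return n_i, s_i, nvp


def brute_gldm(levels: np.ndarray, n_levels: int, alpha: int = 0):
    """Dependence matrix: size = 1 + matching 26-neighbours, per voxel."""
    nx, ny, nz = levels.shape
    entries = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                g = levels[i, j, k]
                if g == 0:
                    continue
                dep = 1
                for di, dj, dk in NEIGHBORS_26:
                    ni, nj, nk = i + di, j + dj, k + dk
                    if (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz
                            and levels[ni, nj, nk] > 0
                            and abs(int(levels[ni, nj, nk]) - int(g)) <= alpha):
                        dep += 1
                entries.append((int(g), dep))
    max_dep = max(d for _, d in entries)
    P = np.zeros((n_levels, max_dep))
    for g, d in entries:
        P[g - 1, d - 1] += 1
    return P


# ------------------------------------------------- texture feature formulas
# Scalar-loop evaluations of each family's feature list, computed from the
# brute-force matrices above.

def oracle_glcm_features(P: np.ndarray) -> dict:
    Ng = P.shape[0]
    s = P.sum()
    p = [[P[i][j] / s for j in range(Ng)] for i in range(Ng)]
    px = [sum(row) for row in p]
    py = [sum(p[i][j] for i in range(Ng)) for j in range(Ng)]
    ux = sum((i + 1) * px[i] for i in range(Ng))
    uy = sum((j + 1) * py[j] for j in range(Ng))
    sx = math.sqrt(sum((i + 1 - ux) ** 2 * px[i] for i in range(Ng)))
    sy = math.sqrt(sum((j + 1 - uy) ** 2 * py[j] for j in range(Ng)))
    p_sum = {}
    p_diff = {}
    for i in range(Ng):
        for j in range(Ng):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + p[i][j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + p[i][j]
    hxy = -sum(v * math.log2(v) for row in p for v in row if v > 0)
    hx = -sum(v * math.log2(v) for v in px if v > 0)
    hy = -sum(v * math.log2(v) for v in py if v > 0)
    hxy1 = -sum(p[i][j] * math.log2(px[i] * py[j])
                for i in range(Ng) for j in range(Ng)
                if p[i][j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j])
                for i in range(Ng) for j in range(Ng) if px[i] * py[j] > 0)
    da = sum(k * v for k, v in p_diff.items())
    out = {
        "Autocorrelation": sum((i + 1) * (j + 1) * p[i][j]
                               for i in range(Ng) for j in range(Ng)),
        "JointAverage": ux,
        "ClusterProminence": sum((i + j + 2 - ux - uy) ** 4 * p[i][j]
                                 for i in range(Ng) for j in range(Ng)),
        "ClusterShade": sum((i + j + 2 - ux - uy) ** 3 * p[i][j]
                            for i in range(Ng) for j in range(Ng)),
        "ClusterTendency": sum((i + j + 2 - ux - uy) ** 2 * p[i][j]
                               for i in range(Ng) for j in range(Ng)),
        "Contrast": sum((i - j) ** 2 * p[i][j] for i in range(Ng) for j in range(Ng)),
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * math.log2(v) for v in p_diff.values() if v > 0),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in p_diff.items()),
        "JointEnergy": sum(v * v for row in p for v in row),
        "JointEntropy": hxy,
        "Idm": sum(p[i][j] / (1 + (i - j) ** 2) for i in range(Ng) for j in range(Ng)),
        "Idmn": sum(p[i][j] / (1 + ((i - j) / Ng) ** 2)
                    for i in range(Ng) for j in range(Ng)),
        "Id": sum(p[i][j] / (1 + abs(i - j)) for i in range(Ng) for j in range(Ng)),
        "Idn": sum(p[i][j] / (1 + abs(i - j) / Ng)
                   for i in range(Ng) for j in range(Ng)),
        "InverseVariance": sum(p[i][j] / (i - j) ** 2
                               for i in range(Ng) for j in range(Ng) if i != j),
        "MaximumProbability": max(v for row in p for v in row),
        "SumAverage": sum(k * v for k, v in p_sum.items()),
        "SumEntropy": -sum(v * math.log2(v) for v in p_sum.values() if v > 0),
        "SumSquares": sum((i + 1 - ux) ** 2 * p[i][j]
                          for i in range(Ng) for j in range(Ng)),
    }
    out["Correlation"] = (
        (out["Autocorrelation"] - ux * uy) / (sx * sy) if sx > 0 and sy > 0 else 1.0
    )
    div = max(hx, hy)
    out["Imc1"] = (hxy - hxy1) / div if div > 0 else 0.0
    out["Imc2"] = math.sqrt(1 - math.exp(-2 * max(hxy2 - hxy, 0.0)))
    keep = [i for i in range(Ng) if px[i] > 0]
    if len(keep) > 1:
        Q = [[sum(p[i][k] * p[j][k] / (px[i] * py[k]) for k in keep)
              for j in keep] for i in keep]
        eig = sorted(np.real(np.linalg.eigvals(np.array(Q))), reverse=True)
        out["MCC"] = math.sqrt(max(eig[1], 0.0))
    else:
        out["MCC"] = 1.0
    return out


def oracle_run_or_dependence_features(P: np.ndarray, n_voxels: int, kind: str) -> dict:
    """GLRLM / GLSZM / GLDM share the same weighted-sum structure."""
    Ng, Nj = P.shape
    N = P.sum()
    mu_i = sum((i + 1) * P[i][j] / N for i in range(Ng) for j in range(Nj))
    mu_j = sum((j + 1) * P[i][j] / N for i in range(Ng) for j in range(Nj))
    sums = {
        "small": sum(P[i][j] / (j + 1) ** 2 for i in range(Ng) for j in range(Nj)) / N,
        "large": sum(P[i][j] * (j + 1) ** 2 for i in range(Ng) for j in range(Nj)) / N,
        "gln": sum(sum(P[i]) ** 2 for i in range(Ng)) / N,
        "jn": sum(sum(P[i][j] for i in range(Ng)) ** 2 for j in range(Nj)) / N,
        "glv": sum((i + 1 - mu_i) ** 2 * P[i][j] / N for i in range(Ng) for j in range(Nj)),
        "jv": sum((j + 1 - mu_j) ** 2 * P[i][j] / N for i in range(Ng) for j in range(Nj)),
        "ent": -sum(P[i][j] / N * math.log2(P[i][j] / N)
                    for i in range(Ng) for j in range(Nj) if P[i][j] > 0),
        "low": sum(P[i][j] / (i + 1) ** 2 for i in range(Ng) for j in range(Nj)) / N,
        "high": sum(P[i][j] * (i + 1) ** 2 for i in range(Ng) for j in range(Nj)) / N,
        "sl": sum(P[i][j] / ((i + 1) ** 2 * (j + 1) ** 2)
                  for i in range(Ng) for j in range(Nj)) / N,
        "sh": sum(P[i][j] * (i + 1) ** 2 / (j + 1) ** 2
                  for i in range(Ng) for j in range(Nj)) / N,
        "ll": sum(P[i][j] * (j + 1) ** 2 / (i + 1) ** 2
                  for i in range(Ng) for j in range(Nj)) / N,
        "lh": sum(P[i][j] * (i + 1) ** 2 * (j + 1) ** 2
                  for i in range(Ng) for j in range(Nj)) / N,
        "pct": N / n_voxels,
        "jnn": sum(sum(P[i][j] for i in range(Ng)) ** 2 for j in range(Nj)) / N ** 2,
        "glnn": sum(sum(P[i]) ** 2 for i in range(Ng)) / N ** 2,
    }
    if kind == "glrlm":
        return {
            "ShortRunEmphasis": sums["small"], "LongRunEmphasis": sums["large"],
            "GrayLevelNonUniformity": sums["gln"],
            "GrayLevelNonUniformityNormalized": sums["glnn"],
            "RunLengthNonUniformity": sums["jn"],
            "RunLengthNonUniformityNormalized": sums["jnn"],
            "RunPercentage": sums["pct"], "GrayLevelVariance": sums["glv"],
            "RunVariance": sums["jv"], "RunEntropy": sums["ent"],
            "LowGrayLevelRunEmphasis": sums["low"],
            "HighGrayLevelRunEmphasis": sums["high"],
            "ShortRunLowGrayLevelEmphasis": sums["sl"],
            "ShortRunHighGrayLevelEmphasis": sums["sh"],
            "LongRunLowGrayLevelEmphasis": sums["ll"],
            "LongRunHighGrayLevelEmphasis": sums["lh"],
        }
    if kind == "glszm":
        return {
            "SmallAreaEmphasis": sums["small"], "LargeAreaEmphasis": sums["large"],
            "GrayLevelNonUniformity": sums["gln"],
            "GrayLevelNonUniformityNormalized": sums["glnn"],
            "SizeZoneNonUniformity": sums["jn"],
            "SizeZoneNonUniformityNormalized": sums["jnn"],
            "ZonePercentage": sums["pct"], "GrayLevelVariance": sums["glv"],
            "ZoneVariance": sums["jv"], "ZoneEntropy": sums["ent"],
            "LowGrayLevelZoneEmphasis": sums["low"],
            "HighGrayLevelZoneEmphasis": sums["high"],
            "SmallAreaLowGrayLevelEmphasis": sums["sl"],
            "SmallAreaHighGrayLevelEmphasis": sums["sh"],
            "LargeAreaLowGrayLevelEmphasis": sums["ll"],
            "LargeAreaHighGrayLevelEmphasis": sums["lh"],
        }
    if kind == "gldm":
        return {
            "SmallDependenceEmphasis": sums["small"],
            "LargeDependenceEmphasis": sums["large"],
            "GrayLevelNonUniformity": sums["gln"],
            "DependenceNonUniformity": sums["jn"],
            "DependenceNonUniformityNormalized": sums["jnn"],
            "GrayLevelVariance": sums["glv"], "DependenceVariance": sums["jv"],
            "DependenceEntropy": sums["ent"],
            "LowGrayLevelEmphasis": sums["low"],
            "HighGrayLevelEmphasis": sums["high"],
            "SmallDependenceLowGrayLevelEmphasis": sums["sl"],
            "SmallDependenceHighGrayLevelEmphasis": sums["sh"],
            "LargeDependenceLowGrayLevelEmphasis": sums["ll"],
            "LargeDependenceHighGrayLevelEmphasis": sums["lh"],
        }
    raise ValueError(kind)


def oracle_ngtdm_features(n_i, s_i, nvp) -> dict:
    Ng = len(n_i)
    p = [n / nvp for n in n_i]
    present = [i for i in range(Ng) if p[i] > 0]
    ngp = len(present)
    denom = sum(p[i] * s_i[i] for i in range(Ng))
    coarseness = 1.0 / denom if denom > 0 else 1e6
    if ngp > 1:
        contrast = sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
        contrast *= sum(s_i) / (ngp * (ngp - 1) * nvp)
        busy_den = sum(abs((i + 1) * p[i] - (j + 1) * p[j])
                       for i in present for j in present)
        busyness = denom / busy_den if busy_den > 0 else 0.0
        complexity = sum(abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
                         for i in present for j in present) / nvp
        s_sum = sum(s_i)
        strength = (sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present)
                    / s_sum if s_sum > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {"Coarseness": coarseness, "Contrast": contrast, "Busyness": busyness,
            "Complexity": complexity, "Strength": strength}
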