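"""Gray-level texture matrices and their feature sets.

Five families over a discretized region (integer levels 1..Ng, 0 outside
the mask), all in 3D with 26-connectivity:

* GLCM  — co-occurrence at distance 1 over the 13 unique angles, symmetric;
          24 features, computed per angle and averaged.
* GLRLM — run lengths along the 13 angles; 16 features, per angle, averaged.
* GLSZM — 26-connected equal-level zones; 16 features, single matrix.
* NGTDM — neighbourhood gray-tone difference; 5 features.
* GLDM  — gray-level dependence with dependence threshold alpha = 0;
          14 features.  The dependence size of a voxel is 1 (itself) plus
          the number of in-mask Chebyshev-distance-1 neighbours with the
          same level, so sizes start at 1.

Matrices are computed only over region voxels; a pair/run/zone never
crosses the mask boundary.  Degenerate regions (single gray level) return
each feature's documented limiting value rather than failing.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

_EPS = np.finfo(float).tiny

# 13 unique direction offsets (one of each +/- pair of the 26-neighbourhood).
ANGLES_13: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)
ALL_26 = tuple(d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0))


def _pair_slices(shape, d):
    """Slices (a, b) such that arr[a] and arr[b] are voxel pairs offset by d."""
    a, b = [], []
    for n, dd in zip(shape, d):
        a.append(slice(max(0, -dd), n - max(0, dd)))
        b.append(slice(max(0, dd), n - max(0, -dd)))
    return tuple(a), tuple(b)


# ---------------------------------------------------------------- GLCM

def glcm_matrix(levels: np.ndarray, n_levels: int, angle) -> np.ndarray | None:
    """Symmetric co-occurrence count matrix for one angle; None if no pairs."""
    a_sl, b_sl = _pair_slices(levels.shape, angle)
    a, b = levels[a_sl], levels[b_sl]
    ok = (a > 0) & (b > 0)
    if not ok.any():
        return None
    flat = (a[ok] - 1) * n_levels + (b[ok] - 1)
    m = np.bincount(flat, minlength=n_levels * n_levels).reshape(n_levels, n_levels)
    return (m + m.T).astype(float)


def glcm_features_single(P: np.ndarray) -> dict[str, float]:
    """The 24 co-occurrence features of one normalized symmetric matrix."""
    Ng = P.shape[0]
    p = P / P.sum()
    i = np.arange(1, Ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((i * px).sum())
    uy = float((i * py).sum())
    sx = float(np.sqrt(((i - ux) ** 2 * px).sum()))
    sy = float(np.sqrt(((i - uy) ** 2 * py).sum()))

    ksum = np.arange(2, 2 * Ng + 1, dtype=float)
    p_sum = np.bincount((ii + jj).astype(int).ravel(), weights=p.ravel(), minlength=2 * Ng + 1)[2:]
    kdiff = np.arange(0, Ng, dtype=float)
    p_diff = np.bincount(np.abs(ii - jj).astype(int).ravel(), weights=p.ravel(), minlength=Ng)

    nz = p > 0
    log_p = np.zeros_like(p)
    log_p[nz] = np.log2(p[nz])
    hxy = float(-(p[nz] * log_p[nz]).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
    pxpy = px[:, None] * py[None, :]
    ok = nz & (pxpy > 0)
    hxy1 = float(-(p[ok] * np.log2(pxpy[ok])).sum())
    okk = pxpy > 0
    hxy2 = float(-(pxpy[okk] * np.log2(pxpy[okk])).sum())

    div = max(hx, hy)
    imc1 = (hxy - hxy1) / div if div > 0 else 0.0
    imc2 = float(np.sqrt(1 - np.exp(-2.0 * max(hxy2 - hxy, 0.0))))

    da = float((kdiff * p_diff).sum())
    diff_ent = float(-(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum())
    sum_ent = float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum())

    if sx > 0 and sy > 0:
        correlation = float(((ii * jj * p).sum() - ux * uy) / (sx * sy))
    else:
        correlation = 1.0  # degenerate single-level limit

    # Maximal correlation coefficient from the transition matrix Q.
    keep = px > 0
    if keep.sum() > 1:
        psub = p[np.ix_(keep, keep)]
        pxs = px[keep]
        pys = py[keep]
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
        Q = (psub / pxs[:, None]) @ (psub / pys[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        mcc = float(np.sqrt(max(eig[1], 0.0))) if len(eig) > 1 else 1.0
    else:
        mcc = 1.0

    off = ii != jj
    inv_var = float((p[off] / (ii - jj)[off] ** 2).sum()) if off.any() else 0.0

    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": ux,
        "ClusterProminence": float(((ii + jj - ux - uy) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - ux - uy) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - ux - uy) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": diff_ent,
        "DifferenceVariance": float(((kdiff - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "MCC": mcc,
        "Idmn": float((p / (1.0 + ((ii - jj) / Ng) ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / Ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((ksum * p_sum).sum()),
        "SumEntropy": sum_ent,
        "SumSquares": float(((ii - ux) ** 2 * p).sum()),
    }


def glcm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    per_angle = []
    for d in ANGLES_13:
        m = glcm_matrix(levels, n_levels, d)
        if m is not None:
            per_angle.append(glcm_features_single(m))
    if not per_angle:
        # no co-occurring pairs at all (isolated voxels): limiting values
        per_angle = [glcm_features_single(np.ones((1, 1)))]
    return {k: float(np.mean([f[k] for f in per_angle])) for k in per_angle[0]}


# ---------------------------------------------------------------- GLRLM

def glrlm_matrix(levels: np.ndarray, n_levels: int, angle) -> np.ndarray:
    """Run-length count matrix (Ng x max_run) for one angle."""
    shape = levels.shape
    a_sl, b_sl = _pair_slices(shape, angle)
    link = np.zeros(shape, dtype=bool)  # link[v]: v -> v+d continues the run
    link[a_sl] = (levels[a_sl] > 0) & (levels[a_sl] == levels[b_sl])
    pred = np.zeros(shape, dtype=bool)  # pred[v]: v-d -> v link exists
    pred[b_sl] = link[a_sl]
    starts = (levels > 0) & ~pred

    pos = np.argwhere(starts)
    if len(pos) == 0:
        return np.zeros((n_levels, 1))
    lengths = np.ones(len(pos), dtype=int)
    cur = pos.copy()
    alive = np.arange(len(pos))
    d = np.asarray(angle)
    while alive.size:
        cont = link[tuple(cur[alive].T)]
        alive = alive[cont]
        cur[alive] += d
        lengths[alive] += 1
    g = levels[tuple(pos.T)] - 1
    P = np.zeros((n_levels, int(lengths.max())))
    np.add.at(P, (g, lengths - 1), 1.0)
    return P


def glrlm_features_single(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    Nr = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    j = np.arange(1, P.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = P / Nr
    pg = P.sum(axis=1)  # per gray level
    pr = P.sum(axis=0)  # per run length
    mu_i = float((p * ii).sum())
    mu_j = float((p * jj).sum())
    nz = p > 0
    return {
        "ShortRunEmphasis": float((P / jj ** 2).sum() / Nr),
        "LongRunEmphasis": float((P * jj ** 2).sum() / Nr),
        "GrayLevelNonUniformity": float((pg ** 2).sum() / Nr),
        "GrayLevelNonUniformityNormalized": float((pg ** 2).sum() / Nr ** 2),
        "RunLengthNonUniformity": float((pr ** 2).sum() / Nr),
        "RunLengthNonUniformityNormalized": float((pr ** 2).sum() / Nr ** 2),
        "RunPercentage": float(Nr / n_voxels),
        "GrayLevelVariance": float((p * (ii - mu_i) ** 2).sum()),
        "RunVariance": float((p * (jj - mu_j) ** 2).sum()),
        "RunEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LowGrayLevelRunEmphasis": float((P / ii ** 2).sum() / Nr),
        "HighGrayLevelRunEmphasis": float((P * ii ** 2).sum() / Nr),
        "ShortRunLowGrayLevelEmphasis": float((P / (ii ** 2 * jj ** 2)).sum() / Nr),
        "ShortRunHighGrayLevelEmphasis": float((P * ii ** 2 / jj ** 2).sum() / Nr),
        "LongRunLowGrayLevelEmphasis": float((P * jj ** 2 / ii ** 2).sum() / Nr),
        "LongRunHighGrayLevelEmphasis": float((P * ii ** 2 * jj ** 2).sum() / Nr),
    }


def glrlm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    n_voxels = int((levels > 0).sum())
    per_angle = []
    for d in ANGLES_13:
        P = glrlm_matrix(levels, n_levels, d)
        if P.sum() > 0:
            per_angle.append(glrlm_features_single(P, n_voxels))
    return {k: float(np.mean([f[k] for f in per_angle])) for k in per_angle[0]}


# ---------------------------------------------------------------- GLSZM

def glszm_zones(levels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(gray level, zone size) for every 26-connected equal-level zone."""
    structure = np.ones((3, 3, 3), dtype=bool)
    gs, sizes = [], []
    for g in np.unique(levels[levels > 0]):
        lab, n = ndimage.label(levels == g, structure=structure)
        if n:
            cnt = np.bincount(lab.ravel())[1:]
            gs.extend([int(g)] * n)
            sizes.extend(cnt.tolist())
    return np.asarray(gs, dtype=float), np.asarray(sizes, dtype=float)


def glszm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    i, s = glszm_zones(levels)
    n_voxels = int((levels > 0).sum())
    Nz = float(len(i))
    p = np.full(len(i), 1.0 / Nz)
    # aggregate per gray level / per size for the non-uniformity sums
    gl_counts = np.bincount(i.astype(int), minlength=n_levels + 1)[1:].astype(float)
    size_counts = np.bincount(s.astype(int))[1:].astype(float)
    mu_i = float((p * i).sum())
    mu_s = float((p * s).sum())
    _, joint_counts = np.unique(np.stack([i, s], axis=1), axis=0, return_counts=True)
    ent_p = joint_counts / Nz
    return {
        "SmallAreaEmphasis": float((1.0 / s ** 2).sum() / Nz),
        "LargeAreaEmphasis": float((s ** 2).sum() / Nz),
        "GrayLevelNonUniformity": float((gl_counts ** 2).sum() / Nz),
        "GrayLevelNonUniformityNormalized": float((gl_counts ** 2).sum() / Nz ** 2),
        "SizeZoneNonUniformity": float((size_counts ** 2).sum() / Nz),
        "SizeZoneNonUniformityNormalized": float((size_counts ** 2).sum() / Nz ** 2),
        "ZonePercentage": float(Nz / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "ZoneVariance": float((p * (s - mu_s) ** 2).sum()),
        "ZoneEntropy": float(-(ent_p * np.log2(ent_p)).sum()),
        "LowGrayLevelZoneEmphasis": float((1.0 / i ** 2).sum() / Nz),
        "HighGrayLevelZoneEmphasis": float((i ** 2).sum() / Nz),
        "SmallAreaLowGrayLevelEmphasis": float((1.0 / (i ** 2 * s ** 2)).sum() / Nz),
        "SmallAreaHighGrayLevelEmphasis": float((i ** 2 / s ** 2).sum() / Nz),
        "LargeAreaLowGrayLevelEmphasis": float((s ** 2 / i ** 2).sum() / Nz),
        "LargeAreaHighGrayLevelEmphasis": float((i ** 2 * s ** 2).sum() / Nz),
    }


# ---------------------------------------------------------------- NGTDM

def ngtdm_table(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray, int]:
    """(n_i, s_i, Nvp): counts and summed gray-tone differences per level.

    A voxel contributes if it has at least one in-mask 26-neighbour; its
    difference is |level - mean neighbour level|.
    """
    mask = levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    cnt = ndimage.convolve(mask.astype(float), kernel, mode="constant")
    tot = ndimage.convolve(np.where(mask, levels, 0).astype(float), kernel, mode="constant")
    valid = mask & (cnt > 0)
    g = levels[valid]
    diff = np.abs(g - tot[valid] / cnt[valid])
    n_i = np.bincount(g - 1, minlength=n_levels).astype(float)
    s_i = np.bincount(g - 1, weights=diff, minlength=n_levels)
    return n_i, s_i, int(valid.sum())


def ngtdm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    n_i, s_i, nvp = ngtdm_table(levels, n_levels)
    if nvp == 0:
        return {"Coarseness": 1e6, "Contrast": 0.0, "Busyness": 0.0,
                "Complexity": 0.0, "Strength": 0.0}
    p = n_i / nvp
    i = np.arange(1, n_levels + 1, dtype=float)
    nz = p > 0
    ngp = int(nz.sum())

    denom_coarse = float((p * s_i).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else 1e6

    if ngp > 1:
        pi_, pj_ = np.meshgrid(p[nz], p[nz], indexing="ij")
        ii_, jj_ = np.meshgrid(i[nz], i[nz], indexing="ij")
        contrast = float((pi_ * pj_ * (ii_ - jj_) ** 2).sum()) / (ngp * (ngp - 1))
        contrast *= float(s_i.sum()) / nvp
        busy_den = float(np.abs(ii_ * pi_ - jj_ * pj_).sum())
        busyness = float((p * s_i).sum()) / busy_den if busy_den > 0 else 0.0
        si_, sj_ = np.meshgrid(s_i[nz], s_i[nz], indexing="ij")
        complexity = float(
            (np.abs(ii_ - jj_) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)).sum()
        ) / nvp
        s_sum = float(s_i.sum())
        strength = float(((pi_ + pj_) * (ii_ - jj_) ** 2).sum()) / s_sum if s_sum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------- GLDM

def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix (Ng x max dependence size)."""
    mask = levels > 0
    dep = np.zeros(levels.shape, dtype=int)
    for d in ALL_26:
        a_sl, b_sl = _pair_slices(levels.shape, d)
        match = (np.abs(levels[a_sl] - levels[b_sl]) <= alpha) & (levels[b_sl] > 0)
        dep[a_sl] += match & (levels[a_sl] > 0)
    size = dep[mask] + 1  # centre voxel always depends on itself
    g = levels[mask] - 1
    P = np.zeros((n_levels, int(size.max())))
    np.add.at(P, (g, size - 1), 1.0)
    return P


def gldm_features(levels: np.ndarray, n_levels: int, alpha: int = 0) -> dict[str, float]:
    P = gldm_matrix(levels, n_levels, alpha)
    Nz = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    j = np.arange(1, P.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = P / Nz
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    mu_i = float((p * ii).sum())
    mu_j = float((p * jj).sum())
    nz = p > 0
    return {
        "SmallDependenceEmphasis": float((P / jj ** 2).sum() / Nz),
        "LargeDependenceEmphasis": float((P * jj ** 2).sum() / Nz),
        "GrayLevelNonUniformity": float((pg ** 2).sum() / Nz),
        "DependenceNonUniformity": float((pd ** 2).sum() / Nz),
        "DependenceNonUniformityNormalized": float((pd ** 2).sum() / Nz ** 2),
        "GrayLevelVariance": float((p * (ii - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (jj - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LowGrayLevelEmphasis": float((P / ii ** 2).sum() / Nz),
        "HighGrayLevelEmphasis": float((P * ii ** 2).sum() / Nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (ii ** 2 * jj ** 2)).sum() / Nz),
        "SmallDependenceHighGrayLevelEmphasis": float((P * ii ** 2 / jj ** 2).sum() / Nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * jj ** 2 / ii ** 2).sum() / Nz),
        "LargeDependenceHighGrayLevelEmphasis": float((P * ii ** 2 * jj ** 2).sum() / Nz),
    }


# ---------------------------------------------------------------- driver

def texture_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """All 75 texture features, keyed "<family>_<Feature>".

    ``levels``: 3D integer array, 1..n_levels inside the region, 0 outside.
    """
    if n_levels < 1 or (levels > 0).sum() < 2:
        raise ValueError("texture features require >= 2 region voxels")
    out: dict[str, float] = {}
    for fam, func in (
        ("glcm", glcm_features),
        ("glrlm", glrlm_features),
        ("glszm", glszm_features),
        ("ngtdm", ngtdm_features),
        ("gldm", gldm_features),
    ):
        for name, val in func(levels, n_levels).items():
            out[f"{fam}_{name}"] = val
    return out
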