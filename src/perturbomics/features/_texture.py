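"""Texture features (75) from gray-level matrices.

Implements the standardized matrix definitions: co-occurrence (GLCM, 24),
run length (GLRLM, 16), size zone (GLSZM, 16), neighbourhood tone
difference (NGTDM, 5) and dependence (GLDM, 14). Intensities are
discretized with a fixed bin width; GLCM and GLRLM are computed per
3D direction (13 unique angles at Chebyshev distance 1) and the feature
values averaged over directions; zones and neighbourhoods use
26-connectivity.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import correlate, label

_EPS = np.finfo(np.float64).tiny

GLCM_NAMES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
]
GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]
GLSZM_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]
NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]
GLDM_NAMES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]

# 13 unique 3D directions (half of the 26-neighbourhood)
ANGLES = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]
assert len(ANGLES) == 13


def discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width gray levels, 1-based: floor(x/w) - floor(min/w) + 1."""
    x = np.asarray(values, dtype=np.float64)
    return (np.floor(x / bin_width) - np.floor(x.min() / bin_width) + 1).astype(np.int64)


def _center_slices(shape, d) -> tuple[slice, ...]:
    """Slices selecting voxels whose d-neighbour stays inside the grid."""
    out = []
    for dim, off in zip(shape, d):
        if off == 0:
            out.append(slice(None))
        elif off > 0:
            out.append(slice(0, dim - off))
        else:
            out.append(slice(-off, dim))
    return tuple(out)


def _shift_views(a: np.ndarray, d: tuple[int, int, int]):
    """Aligned views (center, shifted-by-d) of equal shape."""
    sl_c = _center_slices(a.shape, d)
    sl_s = _center_slices(a.shape, tuple(-x for x in d))
    return a[sl_c], a[sl_s]


# ---------------------------------------------------------------- GLCM

def _glcm_single(levels: np.ndarray, mask: np.ndarray, ng: int, d) -> np.ndarray:
    lc, ls = _shift_views(levels, d)
    mc, ms = _shift_views(mask, d)
    ok = mc & ms
    i = lc[ok] - 1
    j = ls[ok] - 1
    P = np.zeros((ng, ng))
    np.add.at(P, (i, j), 1.0)
    P = P + P.T  # symmetric co-occurrence
    return P


def _glcm_features_from_matrix(P: np.ndarray) -> dict[str, float]:
    s = P.sum()
    ng = P.shape[0]
    v = np.arange(1, ng + 1, dtype=np.float64)
    if s == 0:
        return {k: 0.0 for k in GLCM_NAMES}
    p = P / s
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float(np.sum(v * px))
    uy = float(np.sum(v * py))
    sx = float(np.sqrt(np.sum((v - ux) ** 2 * px)))
    sy = float(np.sqrt(np.sum((v - uy) ** 2 * py)))
    ii, jj = np.meshgrid(v, v, indexing="ij")
    d_abs = np.abs(ii - jj)
    ksum = (ii + jj).astype(np.int64)
    kdiff = d_abs.astype(np.int64)
    p_sum = np.zeros(2 * ng + 1)
    np.add.at(p_sum, ksum.ravel(), p.ravel())
    p_diff = np.zeros(ng)
    np.add.at(p_diff, kdiff.ravel(), p.ravel())
    k_sum = np.arange(2 * ng + 1, dtype=np.float64)
    k_diff = np.arange(ng, dtype=np.float64)

    out: dict[str, float] = {}
    out["Autocorrelation"] = float(np.sum(ii * jj * p))
    out["JointAverage"] = ux
    cl = ii + jj - ux - uy
    out["ClusterProminence"] = float(np.sum(cl**4 * p))
    out["ClusterShade"] = float(np.sum(cl**3 * p))
    out["ClusterTendency"] = float(np.sum(cl**2 * p))
    out["Contrast"] = float(np.sum((ii - jj) ** 2 * p))
    out["Correlation"] = (
        (out["Autocorrelation"] - ux * uy) / (sx * sy) if sx > 0 and sy > 0 else 1.0
    )
    da = float(np.sum(k_diff * p_diff))
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = float(-np.sum(p_diff * np.log2(p_diff + _EPS)))
    out["DifferenceVariance"] = float(np.sum((k_diff - da) ** 2 * p_diff))
    out["JointEnergy"] = float(np.sum(p**2))
    hxy = float(-np.sum(p * np.log2(p + _EPS)))
    out["JointEntropy"] = hxy
    pxpy = np.outer(px, py)
    hxy1 = float(-np.sum(p * np.log2(pxpy + _EPS)))
    hxy2 = float(-np.sum(pxpy * np.log2(pxpy + _EPS)))
    hx = float(-np.sum(px * np.log2(px + _EPS)))
    hy = float(-np.sum(py * np.log2(py + _EPS)))
    div = max(hx, hy)
    out["Imc1"] = (hxy - hxy1) / div if div > 0 else 0.0
    out["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0
    out["Idm"] = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    out["Idmn"] = float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2)))
    out["Id"] = float(np.sum(p / (1.0 + d_abs)))
    out["Idn"] = float(np.sum(p / (1.0 + d_abs / ng)))
    off = d_abs > 0
    out["InverseVariance"] = float(np.sum(p[off] / d_abs[off] ** 2))
    out["MaximumProbability"] = float(p.max())
    out["SumAverage"] = float(np.sum(k_sum * p_sum))
    out["SumEntropy"] = float(-np.sum(p_sum * np.log2(p_sum + _EPS)))
    out["SumSquares"] = float(np.sum((ii - ux) ** 2 * p))

    keep = px > 0
    if keep.sum() < 2:
        out["MCC"] = 1.0
    else:
        psub = p[np.ix_(keep, keep)]
        pxs = px[keep]
        pys = py[keep]
        q = (psub / (pxs[:, None] * pys[None, :] + _EPS)) @ psub.T
        eig = np.linalg.eigvals(q)
        eig = np.sort(np.real(eig))[::-1]
        out["MCC"] = float(np.sqrt(max(0.0, eig[1]))) if eig.size > 1 else 1.0
    return out


def glcm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    ng = int(levels[mask].max())
    acc: dict[str, float] = {k: 0.0 for k in GLCM_NAMES}
    for d in ANGLES:
        f = _glcm_features_from_matrix(_glcm_single(levels, mask, ng, d))
        for k in GLCM_NAMES:
            acc[k] += f[k]
    return {k: acc[k] / len(ANGLES) for k in GLCM_NAMES}


# ---------------------------------------------------------------- GLRLM

def _glrlm_single(levels: np.ndarray, mask: np.ndarray, ng: int, d) -> np.ndarray:
    """Run-length matrix along one direction (counts, Ng x max_run)."""
    shape = levels.shape
    back = tuple(-x for x in d)
    # run starts: voxels whose predecessor along d is absent or differs
    prev_same = np.zeros(shape, dtype=bool)
    lc, ls = _shift_views(levels, back)  # ls = predecessor voxels
    mc, ms = _shift_views(mask, back)
    prev_same[_center_slices(shape, back)] = (lc == ls) & mc & ms
    starts = np.argwhere(mask & ~prev_same)
    runs: dict[tuple[int, int], int] = {}
    max_len = 1
    dz, dy, dx = d
    nz, ny, nx = shape
    for z, y, x in starts:
        g = levels[z, y, x]
        length = 1
        zz, yy, xx = z + dz, y + dy, x + dx
        while 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx and mask[zz, yy, xx] and levels[zz, yy, xx] == g:
            length += 1
            zz += dz
            yy += dy
            xx += dx
        key = (int(g), length)
        runs[key] = runs.get(key, 0) + 1
        max_len = max(max_len, length)
    P = np.zeros((ng, max_len))
    for (g, length), c in runs.items():
        P[g - 1, length - 1] = c
    return P


def _rl_family(P: np.ndarray, n_voxels: int, prefix: dict[str, str]) -> dict[str, float]:
    """Shared feature family for run-length-style matrices.

    `prefix` maps the 16 canonical slots to output names.
    """
    nr = P.sum()
    ng, nl = P.shape
    iv = np.arange(1, ng + 1, dtype=np.float64)
    jv = np.arange(1, nl + 1, dtype=np.float64)
    ii, jj = np.meshgrid(iv, jv, indexing="ij")
    pg = P.sum(axis=1)  # per gray level
    pr = P.sum(axis=0)  # per length
    p = P / nr
    mu_i = float(np.sum(ii * p))
    mu_j = float(np.sum(jj * p))
    out = {
        prefix["sre"]: float(np.sum(P / jj**2) / nr),
        prefix["lre"]: float(np.sum(P * jj**2) / nr),
        prefix["gln"]: float(np.sum(pg**2) / nr),
        prefix["glnn"]: float(np.sum(pg**2) / nr**2),
        prefix["rln"]: float(np.sum(pr**2) / nr),
        prefix["rlnn"]: float(np.sum(pr**2) / nr**2),
        prefix["rp"]: float(nr / n_voxels),
        prefix["glv"]: float(np.sum(p * (ii - mu_i) ** 2)),
        prefix["rv"]: float(np.sum(p * (jj - mu_j) ** 2)),
        prefix["re"]: float(-np.sum(p * np.log2(p + _EPS))),
        prefix["lgl"]: float(np.sum(P / ii**2) / nr),
        prefix["hgl"]: float(np.sum(P * ii**2) / nr),
        prefix["srlgl"]: float(np.sum(P / (ii**2 * jj**2)) / nr),
        prefix["srhgl"]: float(np.sum(P * ii**2 / jj**2) / nr),
        prefix["lrlgl"]: float(np.sum(P * jj**2 / ii**2) / nr),
        prefix["lrhgl"]: float(np.sum(P * ii**2 * jj**2) / nr),
    }
    return out


_GLRLM_SLOTS = dict(
    sre="ShortRunEmphasis", lre="LongRunEmphasis", gln="GrayLevelNonUniformity",
    glnn="GrayLevelNonUniformityNormalized", rln="RunLengthNonUniformity",
    rlnn="RunLengthNonUniformityNormalized", rp="RunPercentage",
    glv="GrayLevelVariance", rv="RunVariance", re="RunEntropy",
    lgl="LowGrayLevelRunEmphasis", hgl="HighGrayLevelRunEmphasis",
    srlgl="ShortRunLowGrayLevelEmphasis", srhgl="ShortRunHighGrayLevelEmphasis",
    lrlgl="LongRunLowGrayLevelEmphasis", lrhgl="LongRunHighGrayLevelEmphasis",
)


def glrlm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    ng = int(levels[mask].max())
    n_vox = int(mask.sum())
    acc = {k: 0.0 for k in GLRLM_NAMES}
    for d in ANGLES:
        P = _glrlm_single(levels, mask, ng, d)
        f = _rl_family(P, n_vox, _GLRLM_SLOTS)
        for k in GLRLM_NAMES:
            acc[k] += f[k]
    return {k: acc[k] / len(ANGLES) for k in GLRLM_NAMES}


# ---------------------------------------------------------------- GLSZM

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    ng = int(levels[mask].max())
    n_vox = int(mask.sum())
    zones: dict[tuple[int, int], int] = {}
    max_size = 1
    arr = np.where(mask, levels, 0)
    for g in np.unique(arr[mask]):
        lab, n_lab = label(arr == g, structure=_STRUCT26)
        if n_lab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones[(int(g), int(s))] = zones.get((int(g), int(s)), 0) + 1
            max_size = max(max_size, int(s))
    P = np.zeros((ng, max_size))
    for (g, s), c in zones.items():
        P[g - 1, s - 1] = c
    slots = dict(
        sre="SmallAreaEmphasis", lre="LargeAreaEmphasis",
        gln="GrayLevelNonUniformity", glnn="GrayLevelNonUniformityNormalized",
        rln="SizeZoneNonUniformity", rlnn="SizeZoneNonUniformityNormalized",
        rp="ZonePercentage", glv="GrayLevelVariance", rv="ZoneVariance",
        re="ZoneEntropy", lgl="LowGrayLevelZoneEmphasis",
        hgl="HighGrayLevelZoneEmphasis", srlgl="SmallAreaLowGrayLevelEmphasis",
        srhgl="SmallAreaHighGrayLevelEmphasis",
        lrlgl="LargeAreaLowGrayLevelEmphasis", lrhgl="LargeAreaHighGrayLevelEmphasis",
    )
    return _rl_family(P, n_vox, slots)


# ---------------------------------------------------------------- NGTDM

_KERNEL26 = np.ones((3, 3, 3))
_KERNEL26[1, 1, 1] = 0


def ngtdm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    ng = int(levels[mask].max())
    arr = np.where(mask, levels, 0).astype(np.float64)
    msk = mask.astype(np.float64)
    nb_sum = correlate(arr, _KERNEL26, mode="constant", cval=0.0)
    nb_cnt = correlate(msk, _KERNEL26, mode="constant", cval=0.0)
    valid = mask & (nb_cnt > 0)
    nvp = int(valid.sum())
    g = levels[valid]
    a = nb_sum[valid] / nb_cnt[valid]
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    np.add.at(n_i, g - 1, 1.0)
    np.add.at(s_i, g - 1, np.abs(g - a))
    p_i = n_i / nvp
    iv = np.arange(1, ng + 1, dtype=np.float64)
    present = p_i > 0
    ngp = int(present.sum())
    out: dict[str, float] = {}
    denom = float(np.sum(p_i * s_i))
    out["Coarseness"] = 1.0 / denom if denom > 0 else 1e6
    if ngp > 1:
        pi = p_i[present]
        vi = iv[present]
        si = s_i[present]
        diff2 = (vi[:, None] - vi[None, :]) ** 2
        out["Contrast"] = (
            float(np.sum(pi[:, None] * pi[None, :] * diff2)) / (ngp * (ngp - 1))
        ) * (float(s_i.sum()) / nvp)
        ipi = vi * pi
        busy_den = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
        out["Busyness"] = denom / busy_den if busy_den > 0 else 0.0
        pden = pi[:, None] + pi[None, :]
        pnum = pi[:, None] * si[:, None] + pi[None, :] * si[None, :]
        out["Complexity"] = float(np.sum(np.abs(vi[:, None] - vi[None, :]) * pnum / pden)) / nvp
        ssum = float(s_i.sum())
        out["Strength"] = float(np.sum(pden * diff2)) / ssum if ssum > 0 else 0.0
    else:
        out["Contrast"] = 0.0
        out["Busyness"] = 0.0
        out["Complexity"] = 0.0
        out["Strength"] = 0.0
    return out


# ---------------------------------------------------------------- GLDM

def gldm_features(levels: np.ndarray, mask: np.ndarray, alpha: int = 0) -> dict[str, float]:
    ng = int(levels[mask].max())
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in ANGLES:
        for dd in (d, tuple(-x for x in d)):
            lc, ls = _shift_views(levels, dd)
            mc, ms = _shift_views(mask, dd)
            ok = mc & ms & (np.abs(lc - ls) <= alpha)
            contrib = np.zeros(levels.shape, dtype=np.int64)
            contrib[_center_slices(levels.shape, dd)] = ok
            dep += contrib
    sizes = dep[mask] + 1  # dependence size includes the center voxel
    g = levels[mask]
    nd = int(sizes.max())
    P = np.zeros((ng, nd))
    np.add.at(P, (g - 1, sizes - 1), 1.0)
    n_vox = int(mask.sum())
    slots = dict(
        sre="SmallDependenceEmphasis", lre="LargeDependenceEmphasis",
        gln="GrayLevelNonUniformity", glnn="_drop_glnn",
        rln="DependenceNonUniformity", rlnn="DependenceNonUniformityNormalized",
        rp="_drop_rp", glv="GrayLevelVariance", rv="DependenceVariance",
        re="DependenceEntropy", lgl="LowGrayLevelEmphasis",
        hgl="HighGrayLevelEmphasis", srlgl="SmallDependenceLowGrayLevelEmphasis",
        srhgl="SmallDependenceHighGrayLevelEmphasis",
        lrlgl="LargeDependenceLowGrayLevelEmphasis",
        lrhgl="LargeDependenceHighGrayLevelEmphasis",
    )
    fam = _rl_family(P, n_vox, slots)
    return {k: fam[k] for k in GLDM_NAMES}
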