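"""Gray-level texture matrices and their features.

Implements the five 3D texture families on a fixed-bin-width discretized
image: co-occurrence (GLCM, 24), run length (GLRLM, 16), size zone
(GLSZM, 16), neighbouring gray-tone difference (NGTDM, 5) and gray-level
dependence (GLDM, 14). Conventions follow the IBSI-aligned defaults of the
widely used radiomics extractors: 26-connectivity (13 unique directions at
distance 1), symmetric GLCM, per-direction feature values averaged over
directions, matrices indexed by the gray levels actually present in the ROI.

Degenerate (single-gray-level) ROIs return the features' natural limits
(e.g. GLCM correlation 1, NGTDM coarseness capped at 1e6) rather than NaN.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "discretize",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "NGTDM_FEATURES",
    "GLDM_FEATURES",
]

_EPS = np.spacing(1)
_COARSENESS_CAP = 1e6

# 13 unique direction vectors of the 26-neighbourhood (first nonzero positive)
_ANGLES = [
    (0, 0, 1),
    (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1),
    (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
]


def discretize(values: np.ndarray, mask: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width discretization to integer levels starting at 1.

    Levels are anchored at floor(min/width) so that equal intensities map to
    equal levels regardless of the mask. Out-of-mask voxels get level 0.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    vals = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    inmask = vals[mask]
    lo = np.floor(inmask.min() / bin_width)
    g = np.zeros(vals.shape, dtype=np.int64)
    g[mask] = (np.floor(inmask / bin_width) - lo).astype(np.int64) + 1
    return g


def _crop(g: np.ndarray, mask: np.ndarray):
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return g[sl], mask[sl]


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


# ---------------------------------------------------------------------------
# GLCM

GLCM_FEATURES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
]


def _pair_matrix(g, mask, offset, n_levels):
    """Symmetric co-occurrence counts for one direction."""
    sl_a, sl_b = [], []
    for d in offset:
        if d == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif d > 0:
            sl_a.append(slice(None, -d))
            sl_b.append(slice(d, None))
        else:
            sl_a.append(slice(-d, None))
            sl_b.append(slice(None, d))
    a = g[tuple(sl_a)].ravel()
    b = g[tuple(sl_b)].ravel()
    valid = (a > 0) & (b > 0)
    a, b = a[valid] - 1, b[valid] - 1
    mat = np.zeros((n_levels, n_levels), dtype=np.float64)
    np.add.at(mat, (a, b), 1.0)
    return mat + mat.T


def _glcm_one(P, iv, n_levels_full) -> dict[str, float]:
    P = P / P.sum()
    px = P.sum(axis=1)
    ivf = iv.astype(float)
    ux = float(np.sum(px * ivf))
    sigx = float(np.sqrt(np.sum(px * (ivf - ux) ** 2)))

    I = ivf[:, None]
    J = ivf[None, :]
    diff = np.abs(I - J)
    ssum = I + J

    diff_int = diff.astype(int)
    pxmy = np.bincount(diff_int.ravel(), weights=P.ravel())
    kd = np.arange(pxmy.size, dtype=float)
    pxpy = np.bincount(ssum.astype(int).ravel(), weights=P.ravel())
    ks = np.arange(pxpy.size, dtype=float)

    da = float(np.sum(kd * pxmy))
    joint_entropy = _entropy2(P.ravel())
    hx = _entropy2(px)
    # symmetric matrix: marginals coincide
    hxy1 = -float(np.sum(P * np.log2(px[:, None] * px[None, :] + _EPS)))
    hxy2 = _entropy2(np.outer(px, px).ravel())

    if sigx > 0:
        corr = float((np.sum(P * I * J) - ux * ux) / (sigx * sigx))
    else:
        corr = 1.0
    imc1 = (joint_entropy - hxy1) / hx if hx > 0 else 0.0
    imc2_arg = 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy))
    imc2 = float(np.sqrt(max(imc2_arg, 0.0)))

    ng = float(n_levels_full)
    offdiag = diff > 0
    inv_var = float(np.sum(P[offdiag] / (diff[offdiag] ** 2))) if offdiag.any() else 0.0

    if P.shape[0] > 1:
        px_safe = np.where(px > 0, px, 1.0)
        A = P / px_safe[:, None]
        B = P / px_safe[None, :]  # symmetric: py == px
        Q = A @ B.T
        eig = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(eig[-2], 0.0))) if eig.size > 1 else 1.0
    else:
        mcc = 1.0

    return {
        "Autocorrelation": float(np.sum(P * I * J)),
        "JointAverage": ux,
        "ClusterProminence": float(np.sum(P * (ssum - 2 * ux) ** 4)),
        "ClusterShade": float(np.sum(P * (ssum - 2 * ux) ** 3)),
        "ClusterTendency": float(np.sum(P * (ssum - 2 * ux) ** 2)),
        "Contrast": float(np.sum(P * diff**2)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy2(pxmy),
        "DifferenceVariance": float(np.sum(pxmy * (kd - da) ** 2)),
        "JointEnergy": float(np.sum(P**2)),
        "JointEntropy": joint_entropy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float(np.sum(P / (1.0 + diff**2))),
        "Idmn": float(np.sum(P / (1.0 + (diff / ng) ** 2))),
        "Id": float(np.sum(P / (1.0 + diff))),
        "Idn": float(np.sum(P / (1.0 + diff / ng))),
        "InverseVariance": inv_var,
        "MaximumProbability": float(P.max()),
        "SumAverage": float(np.sum(ks * pxpy)),
        "SumEntropy": _entropy2(pxpy),
        "SumSquares": float(np.sum(P * (I - ux) ** 2)),
        "MCC": mcc,
    }


def glcm_features(g: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    g, mask = _crop(g, mask)
    n_levels = int(g.max())
    present = np.unique(g[mask])
    per_angle = []
    for offset in _ANGLES:
        mat = _pair_matrix(g, mask, offset, n_levels)
        sub = mat[np.ix_(present - 1, present - 1)]
        if sub.sum() == 0:
            continue
        per_angle.append(_glcm_one(sub, present, n_levels))
    if not per_angle:  # single-voxel ROI: no pairs in any direction
        return {k: 0.0 for k in GLCM_FEATURES} | {"Correlation": 1.0, "MCC": 1.0}
    return {k: float(np.mean([f[k] for f in per_angle])) for k in GLCM_FEATURES}


# ---------------------------------------------------------------------------
# GLRLM

GLRLM_FEATURES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]


def _run_matrix(coords, grays, offset, n_levels, max_len):
    """Run-length counts for one direction via line-sorted traversal."""
    d = np.asarray(offset)
    primary = int(np.argmax(d != 0))  # first nonzero component is +1
    t = coords[:, primary]
    key = coords - t[:, None] * d
    order = np.lexsort((t, key[:, 2], key[:, 1], key[:, 0]))
    ks = key[order]
    ts = t[order]
    gs = grays[order]
    same_line = np.all(ks[1:] == ks[:-1], axis=1) & (ts[1:] == ts[:-1] + 1)
    cont = same_line & (gs[1:] == gs[:-1])
    start = np.concatenate(([True], ~cont))
    run_id = np.cumsum(start) - 1
    lengths = np.bincount(run_id)
    run_gray = gs[start]
    mat = np.zeros((n_levels, max_len), dtype=np.float64)
    np.add.at(mat, (run_gray - 1, lengths - 1), 1.0)
    return mat


def _length_family(P, iv, jv, n_voxels, kind) -> dict[str, float]:
    """Shared features of the run-length / size-zone families.

    ``kind`` selects naming: runs (GLRLM) or zones (GLSZM). ``jv`` is the
    length/size vector, ``iv`` the gray values of the matrix rows.
    """
    Ns = P.sum()
    p = P / Ns
    ivf = iv.astype(float)[:, None]
    jvf = jv.astype(float)[None, :]
    pg = P.sum(axis=1)
    pl = P.sum(axis=0)
    mu_i = float(np.sum(p * ivf))
    mu_j = float(np.sum(p * jvf))

    vals = {
        "short": float(np.sum(P / jvf**2) / Ns),
        "long": float(np.sum(P * jvf**2) / Ns),
        "gln": float(np.sum(pg**2) / Ns),
        "glnn": float(np.sum(pg**2) / Ns**2),
        "lnu": float(np.sum(pl**2) / Ns),
        "lnun": float(np.sum(pl**2) / Ns**2),
        "pct": float(Ns / n_voxels),
        "glv": float(np.sum(p * (ivf - mu_i) ** 2)),
        "lv": float(np.sum(p * (jvf - mu_j) ** 2)),
        "entropy": _entropy2(p.ravel()),
        "lgl": float(np.sum(P / ivf**2) / Ns),
        "hgl": float(np.sum(P * ivf**2) / Ns),
        "slgl": float(np.sum(P / (ivf**2 * jvf**2)) / Ns),
        "shgl": float(np.sum(P * ivf**2 / jvf**2) / Ns),
        "llgl": float(np.sum(P * jvf**2 / ivf**2) / Ns),
        "lhgl": float(np.sum(P * ivf**2 * jvf**2) / Ns),
    }
    if kind == "run":
        names = GLRLM_FEATURES
    else:
        names = GLSZM_FEATURES
    keys = ["short", "long", "gln", "glnn", "lnu", "lnun", "pct", "glv", "lv",
            "entropy", "lgl", "hgl", "slgl", "shgl", "llgl", "lhgl"]
    return dict(zip(names, (vals[k] for k in keys)))


def glrlm_features(g: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    g, mask = _crop(g, mask)
    coords = np.argwhere(mask)
    grays = g[mask]
    n_levels = int(g.max())
    max_len = int(max(g.shape))
    n_vox = int(mask.sum())
    present = np.unique(grays)
    per_angle = []
    for offset in _ANGLES:
        mat = _run_matrix(coords, grays, offset, n_levels, max_len)
        sub = mat[present - 1]
        jv = np.arange(1, max_len + 1)
        per_angle.append(_length_family(sub, present, jv, n_vox, "run"))
    return {k: float(np.mean([f[k] for f in per_angle])) for k in GLRLM_FEATURES}


# ---------------------------------------------------------------------------
# GLSZM

GLSZM_FEATURES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]

_CONN26 = np.ones((3, 3, 3), dtype=int)


def glszm_features(g: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    g, mask = _crop(g, mask)
    n_vox = int(mask.sum())
    present = np.unique(g[mask])
    zone_gray: list[np.ndarray] = []
    zone_size: list[np.ndarray] = []
    for level in present:
        lab, nlab = ndimage.label(g == level, structure=_CONN26)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zone_size.append(sizes)
        zone_gray.append(np.full(nlab, level))
    sizes = np.concatenate(zone_size)
    grays = np.concatenate(zone_gray)
    max_size = int(sizes.max())
    mat = np.zeros((present.size, max_size), dtype=np.float64)
    gray_idx = np.searchsorted(present, grays)
    np.add.at(mat, (gray_idx, sizes - 1), 1.0)
    jv = np.arange(1, max_size + 1)
    return _length_family(mat, present, jv, n_vox, "zone")


# ---------------------------------------------------------------------------
# NGTDM

NGTDM_FEATURES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]


def _neighbour_average(g: np.ndarray, mask: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    m = mask.astype(float)
    nsum = ndimage.convolve(g * m, kernel, mode="constant")
    ncnt = ndimage.convolve(m, kernel, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(ncnt > 0, nsum / np.maximum(ncnt, 1e-30), 0.0)
    return avg


def ngtdm_features(g: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    g, mask = _crop(g, mask)
    avg = _neighbour_average(g.astype(float), mask)
    grays = g[mask]
    diffs = np.abs(grays - avg[mask])
    present = np.unique(grays)
    idx = np.searchsorted(present, grays)
    n_i = np.bincount(idx, minlength=present.size).astype(float)
    s_i = np.bincount(idx, weights=diffs, minlength=present.size)
    nv = float(grays.size)
    p_i = n_i / nv
    iv = present.astype(float)
    ngp = present.size

    denom_coars = float(np.sum(p_i * s_i))
    coarseness = 1.0 / denom_coars if denom_coars > 0 else _COARSENESS_CAP

    if ngp > 1:
        pi = p_i[:, None]
        pj = p_i[None, :]
        di = iv[:, None] - iv[None, :]
        contrast = (
            float(np.sum(pi * pj * di**2)) / (ngp * (ngp - 1))
        ) * (float(s_i.sum()) / nv)
        ipi = iv * p_i
        busy_den = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
        busyness = denom_coars / busy_den if busy_den > 0 else 0.0
        psum = pi + pj
        with np.errstate(invalid="ignore", divide="ignore"):
            cmpx = np.abs(di) * (pi * s_i[:, None] + pj * s_i[None, :]) / psum
        complexity = float(np.nansum(cmpx)) / nv
        s_tot = float(s_i.sum())
        strength = float(np.sum(psum * di**2)) / s_tot if s_tot > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# GLDM

GLDM_FEATURES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]

_ALL_OFFSETS = [o for o in np.ndindex(3, 3, 3) if o != (1, 1, 1)]


def _dependence_counts(g: np.ndarray, mask: np.ndarray, alpha: float) -> np.ndarray:
    """1 + number of 26-neighbours within +-alpha of the centre gray level."""
    dep = np.ones(g.shape, dtype=np.int64)
    gp = np.pad(g.astype(float), 1, constant_values=np.nan)
    for off in _ALL_OFFSETS:
        sl = tuple(slice(o, o + n) for o, n in zip(off, g.shape))
        neigh = gp[sl]
        with np.errstate(invalid="ignore"):
            ok = np.abs(neigh - g) <= alpha
        ok &= neigh > 0  # neighbour inside mask (level 0 / NaN excluded)
        dep += ok.astype(np.int64)
    dep[~mask] = 0
    return dep


def gldm_features(g: np.ndarray, mask: np.ndarray, alpha: float = 0.0) -> dict[str, float]:
    g, mask = _crop(g, mask)
    gm = np.where(mask, g, 0)
    dep = _dependence_counts(gm, mask, alpha)
    grays = gm[mask]
    deps = dep[mask]
    present = np.unique(grays)
    max_dep = int(deps.max())
    mat = np.zeros((present.size, max_dep), dtype=np.float64)
    np.add.at(mat, (np.searchsorted(present, grays), deps - 1), 1.0)

    Nz = mat.sum()
    p = mat / Nz
    ivf = present.astype(float)[:, None]
    jvf = np.arange(1, max_dep + 1, dtype=float)[None, :]
    pg = mat.sum(axis=1)
    pd = mat.sum(axis=0)
    mu_i = float(np.sum(p * ivf))
    mu_j = float(np.sum(p * jvf))

    return {
        "SmallDependenceEmphasis": float(np.sum(mat / jvf**2) / Nz),
        "LargeDependenceEmphasis": float(np.sum(mat * jvf**2) / Nz),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / Nz),
        "DependenceNonUniformity": float(np.sum(pd**2) / Nz),
        "DependenceNonUniformityNormalized": float(np.sum(pd**2) / Nz**2),
        "GrayLevelVariance": float(np.sum(p * (ivf - mu_i) ** 2)),
        "DependenceVariance": float(np.sum(p * (jvf - mu_j) ** 2)),
        "DependenceEntropy": _entropy2(p.ravel()),
        "LowGrayLevelEmphasis": float(np.sum(mat / ivf**2) / Nz),
        "HighGrayLevelEmphasis": float(np.sum(mat * ivf**2) / Nz),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(mat / (ivf**2 * jvf**2)) / Nz),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(mat * ivf**2 / jvf**2) / Nz),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(mat * jvf**2 / ivf**2) / Nz),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(mat * ivf**2 * jvf**2) / Nz),
    }
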