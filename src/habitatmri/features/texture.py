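"""Gray-level texture matrices and their IBSI feature sets.

All five families operate on a fixed-bin-width quantised grid (levels
1..Ng inside the mask, 0 outside).  GLCM and GLRLM are computed per
direction over the 13 unique 3-D offsets and aggregated by averaging the
feature values; GLSZM zones, GLDM dependencies and NGTDM neighbourhoods
use 26-connectivity.  Degenerate regions follow the 0*log(0) = 0
convention; GLCM correlation is undefined (NaN) on a single-level region.

Matrix builders are exposed separately from the feature functions so that
independent brute-force oracles can check the matrices themselves.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import DIRECTIONS_13

__all__ = [
    "glcm_matrix", "glcm_features",
    "glrlm_matrix", "glrlm_features",
    "glszm_matrix", "glszm_features",
    "gldm_matrix", "gldm_features",
    "ngtdm_table", "ngtdm_features",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _pair_views(q: np.ndarray, offset) -> tuple[np.ndarray, np.ndarray]:
    """Views of voxel pairs separated by ``offset`` (both inside the grid)."""
    sl_a, sl_b = [], []
    for o, n in zip(offset, q.shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return q[tuple(sl_a)], q[tuple(sl_b)]


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


# ----------------------------------------------------------------- GLCM


def glcm_matrix(quantized: np.ndarray, n_levels: int, offset) -> np.ndarray:
    """Symmetric co-occurrence counts for one offset."""
    a, b = _pair_views(quantized, offset)
    sel = (a > 0) & (b > 0)
    idx = (a[sel] - 1) * n_levels + (b[sel] - 1)
    c = np.bincount(idx, minlength=n_levels * n_levels).reshape(n_levels, n_levels)
    return (c + c.T).astype(float)


def _glcm_features_one(P: np.ndarray) -> dict[str, float]:
    Ng = P.shape[0]
    total = P.sum()
    if total == 0:
        return dict.fromkeys(_GLCM_NAMES, float("nan"))
    p = P / total
    i = np.arange(1, Ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((px * i).sum())  # symmetric: mu_x == mu_y
    sig2 = float((px * (i - mu) ** 2).sum())
    diff = np.abs(I - J)
    pxmy = np.array([p[diff == k].sum() for k in range(Ng)])
    k_d = np.arange(Ng)
    pxpy = np.array([p[(I + J) == s].sum() for s in range(2, 2 * Ng + 1)])
    s_d = np.arange(2, 2 * Ng + 1)
    da = float((pxmy * k_d).sum())
    hxy = float(-_xlog2(p).sum())
    px_py = np.outer(px, px)
    hxy1 = float(-(p * np.where(px_py > 0, np.log2(np.where(px_py > 0, px_py, 1.0)), 0.0)).sum())
    hxy2 = float(-_xlog2(px_py).sum())
    hx = float(-_xlog2(px).sum())
    if max(hx, hx) > 0:
        imc1 = (hxy - hxy1) / hx
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0
    offdiag = diff > 0
    corr = float("nan")
    if sig2 > 0:
        corr = float(((p * I * J).sum() - mu * mu) / sig2)
    return {
        "Autocorrelation": float((p * I * J).sum()),
        "ClusterProminence": float((p * (I + J - 2 * mu) ** 4).sum()),
        "ClusterShade": float((p * (I + J - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((p * (I + J - 2 * mu) ** 2).sum()),
        "Contrast": float((p * (I - J) ** 2).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-_xlog2(pxmy).sum()),
        "DifferenceVariance": float((pxmy * (k_d - da) ** 2).sum()),
        "Id": float((p / (1.0 + diff)).sum()),
        "Idm": float((p / (1.0 + diff**2)).sum()),
        "Idmn": float((p / (1.0 + diff**2 / Ng**2)).sum()),
        "Idn": float((p / (1.0 + diff / Ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((p[offdiag] / diff[offdiag] ** 2).sum()),
        "JointAverage": mu,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "SumEntropy": float(-_xlog2(pxpy).sum()),
    }


_GLCM_NAMES = tuple(_glcm_features_one(np.array([[2.0]])).keys())


def glcm_features(
    quantized: np.ndarray, n_levels: int, directions=DIRECTIONS_13, distance: int = 1
) -> dict[str, float]:
    """Direction-averaged GLCM features."""
    per_dir = [
        _glcm_features_one(glcm_matrix(quantized, n_levels, tuple(distance * o for o in d)))
        for d in directions
    ]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN: undefined stays NaN
        return {k: float(np.nanmean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------- GLRLM


def glrlm_matrix(quantized: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Run-length counts P[level-1, length-1] along one direction."""
    q = quantized
    shape = np.asarray(q.shape)
    d = np.asarray(direction)
    prev_a, prev_b = _pair_views(q, tuple(d))
    # run starts: in-mask voxels whose predecessor along d is absent or different
    starts = q > 0
    same_as_prev = np.zeros(q.shape, dtype=bool)
    sl_b = tuple(
        slice(o, n) if o >= 0 else slice(0, n + o) for o, n in zip(d, shape)
    )
    same_as_prev[sl_b] = (prev_a == prev_b) & (prev_b > 0)
    starts &= ~same_as_prev
    coords = np.argwhere(starts)
    vals = q[starts]
    lengths = np.ones(len(coords), dtype=np.int64)
    alive = np.ones(len(coords), dtype=bool)
    k = 1
    max_len = int(np.abs(shape * np.sign(d)).max()) + 1
    while alive.any() and k < max_len:
        pos = coords[alive] + k * d
        inb = np.all((pos >= 0) & (pos < shape), axis=1)
        ok = np.zeros(inb.shape, dtype=bool)
        if inb.any():
            p_in = pos[inb]
            ok[inb] = q[p_in[:, 0], p_in[:, 1], p_in[:, 2]] == vals[alive][inb]
        idx_alive = np.flatnonzero(alive)
        lengths[idx_alive[ok]] += 1
        alive[idx_alive[~ok]] = False
        k += 1
    max_run = int(lengths.max(initial=1))
    P = np.zeros((n_levels, max_run))
    np.add.at(P, (vals - 1, lengths - 1), 1.0)
    return P


def _rlm_style_features(P: np.ndarray, n_voxels: int, kind: str) -> dict[str, float]:
    """Shared formula block for run-length (kind='run') and size-zone (kind='zone')."""
    Ng, Nj = P.shape
    Nr = P.sum()
    if Nr == 0:
        names = _GLRLM_ORDER if kind == "run" else _GLSZM_ORDER
        return dict.fromkeys(names, float("nan"))
    p = P / Nr
    i = np.arange(1, Ng + 1)[:, None]
    j = np.arange(1, Nj + 1)[None, :]
    pg = P.sum(axis=1)
    pr = P.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    vals = {
        "GrayLevelNonUniformity": float((pg**2).sum() / Nr),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / Nr**2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "HighE": float((P * i**2).sum() / Nr),
        "LowE": float((P / i**2).sum() / Nr),
        "LongE": float((P * j**2).sum() / Nr),
        "ShortE": float((P / j**2).sum() / Nr),
        "LongHigh": float((P * i**2 * j**2).sum() / Nr),
        "LongLow": float((P * j**2 / i**2).sum() / Nr),
        "ShortHigh": float((P * i**2 / j**2).sum() / Nr),
        "ShortLow": float((P / (i**2 * j**2)).sum() / Nr),
        "LengthNonUniformity": float((pr**2).sum() / Nr),
        "LengthNonUniformityNormalized": float((pr**2).sum() / Nr**2),
        "Percentage": float(Nr / n_voxels),
        "Variance": float((p * (j - mu_j) ** 2).sum()),
        "Entropy": float(-_xlog2(p).sum()),
    }
    if kind == "run":
        return {
            "GrayLevelNonUniformity": vals["GrayLevelNonUniformity"],
            "GrayLevelNonUniformityNormalized": vals["GrayLevelNonUniformityNormalized"],
            "GrayLevelVariance": vals["GrayLevelVariance"],
            "HighGrayLevelRunEmphasis": vals["HighE"],
            "LongRunEmphasis": vals["LongE"],
            "LongRunHighGrayLevelEmphasis": vals["LongHigh"],
            "LongRunLowGrayLevelEmphasis": vals["LongLow"],
            "LowGrayLevelRunEmphasis": vals["LowE"],
            "RunEntropy": vals["Entropy"],
            "RunLengthNonUniformity": vals["LengthNonUniformity"],
            "RunLengthNonUniformityNormalized": vals["LengthNonUniformityNormalized"],
            "RunPercentage": vals["Percentage"],
            "RunVariance": vals["Variance"],
            "ShortRunEmphasis": vals["ShortE"],
            "ShortRunHighGrayLevelEmphasis": vals["ShortHigh"],
            "ShortRunLowGrayLevelEmphasis": vals["ShortLow"],
        }
    return {
        "GrayLevelNonUniformity": vals["GrayLevelNonUniformity"],
        "GrayLevelNonUniformityNormalized": vals["GrayLevelNonUniformityNormalized"],
        "GrayLevelVariance": vals["GrayLevelVariance"],
        "HighGrayLevelZoneEmphasis": vals["HighE"],
        "LargeAreaEmphasis": vals["LongE"],
        "LargeAreaHighGrayLevelEmphasis": vals["LongHigh"],
        "LargeAreaLowGrayLevelEmphasis": vals["LongLow"],
        "LowGrayLevelZoneEmphasis": vals["LowE"],
        "SizeZoneNonUniformity": vals["LengthNonUniformity"],
        "SizeZoneNonUniformityNormalized": vals["LengthNonUniformityNormalized"],
        "SmallAreaEmphasis": vals["ShortE"],
        "SmallAreaHighGrayLevelEmphasis": vals["ShortHigh"],
        "SmallAreaLowGrayLevelEmphasis": vals["ShortLow"],
        "ZoneEntropy": vals["Entropy"],
        "ZonePercentage": vals["Percentage"],
        "ZoneVariance": vals["Variance"],
    }


_GLRLM_ORDER = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized", "GrayLevelVariance",
    "HighGrayLevelRunEmphasis", "LongRunEmphasis", "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LowGrayLevelRunEmphasis", "RunEntropy",
    "RunLengthNonUniformity", "RunLengthNonUniformityNormalized", "RunPercentage",
    "RunVariance", "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
_GLSZM_ORDER = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized", "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis", "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis", "ZoneEntropy",
    "ZonePercentage", "ZoneVariance",
)


def glrlm_features(
    quantized: np.ndarray, n_levels: int, directions=DIRECTIONS_13
) -> dict[str, float]:
    """Direction-averaged GLRLM features."""
    n_vox = int((quantized > 0).sum())
    per_dir = [
        _rlm_style_features(glrlm_matrix(quantized, n_levels, d), n_vox, "run")
        for d in directions
    ]
    return {k: float(np.nanmean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------- GLSZM


def glszm_matrix(quantized: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone counts P[level-1, size-1]; zones are 26-connected components."""
    sizes_per_level: list[tuple[int, int]] = []
    max_size = 1
    for lev in range(1, n_levels + 1):
        lab, n = ndimage.label(quantized == lev, structure=_STRUCT_26)
        if n:
            sizes = ndimage.sum(quantized == lev, lab, np.arange(1, n + 1)).astype(int)
            for s in sizes:
                sizes_per_level.append((lev, s))
                max_size = max(max_size, s)
    P = np.zeros((n_levels, max_size))
    for lev, s in sizes_per_level:
        P[lev - 1, s - 1] += 1
    return P


def glszm_features(quantized: np.ndarray, n_levels: int) -> dict[str, float]:
    n_vox = int((quantized > 0).sum())
    return _rlm_style_features(glszm_matrix(quantized, n_levels), n_vox, "zone")


# ----------------------------------------------------------------- GLDM


def gldm_matrix(quantized: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts P[level-1, d]; d = #26-neighbours within alpha of the centre."""
    q = quantized
    mask = q > 0
    dep = np.zeros(q.shape, dtype=np.int64)
    for off in np.argwhere(_STRUCT_26) - 1:
        if not off.any():
            continue
        a, b = _pair_views(q, tuple(off))
        sl_a = tuple(
            slice(0, n - o) if o >= 0 else slice(-o, n) for o, n in zip(off, q.shape)
        )
        contrib = np.zeros(q.shape, dtype=np.int64)
        contrib[sl_a] = ((b > 0) & (np.abs(a - b) <= alpha) & (a > 0)).astype(np.int64)
        dep += contrib
    levels = q[mask] - 1
    counts = dep[mask]
    P = np.zeros((n_levels, int(counts.max(initial=0)) + 1))
    np.add.at(P, (levels, counts), 1.0)
    return P


def gldm_features(quantized: np.ndarray, n_levels: int, alpha: int = 0) -> dict[str, float]:
    P = gldm_matrix(quantized, n_levels, alpha)
    Ng, Nd = P.shape
    Nz = P.sum()
    p = P / Nz
    i = np.arange(1, Ng + 1)[:, None]
    j = np.arange(1, Nd + 1)[None, :]  # dependence size = neighbour count + 1
    pg = P.sum(axis=1)
    pd_ = P.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    return {
        "DependenceEntropy": float(-_xlog2(p).sum()),
        "DependenceNonUniformity": float((pd_**2).sum() / Nz),
        "DependenceNonUniformityNormalized": float((pd_**2).sum() / Nz**2),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "GrayLevelNonUniformity": float((pg**2).sum() / Nz),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "HighGrayLevelEmphasis": float((P * i**2).sum() / Nz),
        "LargeDependenceEmphasis": float((P * j**2).sum() / Nz),
        "LargeDependenceHighGrayLevelEmphasis": float((P * i**2 * j**2).sum() / Nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * j**2 / i**2).sum() / Nz),
        "LowGrayLevelEmphasis": float((P / i**2).sum() / Nz),
        "SmallDependenceEmphasis": float((P / j**2).sum() / Nz),
        "SmallDependenceHighGrayLevelEmphasis": float((P * i**2 / j**2).sum() / Nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (i**2 * j**2)).sum() / Nz),
    }


# ---------------------------------------------------------------- NGTDM


def ngtdm_table(quantized: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-level (n_i, p_i, s_i); neighbourhood mean over in-mask 26-neighbours.

    Voxels with no in-mask neighbour are excluded from the table.
    """
    q = quantized
    mask = q > 0
    kern = _STRUCT_26.astype(float).copy()
    kern[1, 1, 1] = 0.0
    nb_sum = ndimage.convolve(np.where(mask, q, 0).astype(float), kern, mode="constant")
    nb_cnt = ndimage.convolve(mask.astype(float), kern, mode="constant")
    valid = mask & (nb_cnt > 0)
    abar = np.zeros(q.shape)
    abar[valid] = nb_sum[valid] / nb_cnt[valid]
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for lev in range(1, n_levels + 1):
        sel = valid & (q == lev)
        n_i[lev - 1] = sel.sum()
        s_i[lev - 1] = np.abs(lev - abar[sel]).sum()
    total = n_i.sum()
    p_i = n_i / total if total > 0 else n_i
    return n_i, p_i, s_i


def ngtdm_features(quantized: np.ndarray, n_levels: int) -> dict[str, float]:
    n_i, p_i, s_i = ngtdm_table(quantized, n_levels)
    Nvp = n_i.sum()
    i = np.arange(1, n_levels + 1, dtype=float)
    nz = p_i > 0
    Ngp = int(nz.sum())
    iv, pv, sv = i[nz], p_i[nz], s_i[nz]
    coarse_den = float((pv * sv).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6
    if Ngp > 1 and Nvp > 0:
        contrast = (
            float(np.sum(pv[:, None] * pv[None, :] * (iv[:, None] - iv[None, :]) ** 2))
            / (Ngp * (Ngp - 1))
        ) * float(s_i.sum() / Nvp)
        div = np.abs(iv[:, None] * pv[:, None] - iv[None, :] * pv[None, :])
        busy_den = float(div.sum())
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        complexity = float(
            np.sum(
                np.abs(iv[:, None] - iv[None, :])
                * (pv[:, None] * sv[:, None] + pv[None, :] * sv[None, :])
                / (pv[:, None] + pv[None, :])
            )
            / Nvp
        )
        s_sum = float(s_i.sum())
        strength = (
            float(np.sum((pv[:, None] + pv[None, :]) * (iv[:, None] - iv[None, :]) ** 2))
            / s_sum
            if s_sum > 0
            else 0.0
        )
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
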