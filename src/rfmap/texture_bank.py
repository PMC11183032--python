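"""Gray-level texture matrices and the 75-feature bank on small 2D windows.

The bank covers five texture-matrix families — co-occurrence (GLCM, 24
features), dependence (GLDM, 14), run length (GLRLM, 16), size zone
(GLSZM, 16) and neighbourhood gray-tone difference (NGTDM, 5) — evaluated
on a quantized window, typically the 7x7 kernel that the sliding feature-map
engine extracts around each pixel.

Formulas follow the IBSI-conformant definitions.  Degenerate windows
(constant intensity) yield defined limits rather than NaN: entropy-,
variance- and contrast-type features are 0, uniformity- and
maximum-probability-type features are 1, and NGTDM coarseness is capped at
``COARSENESS_CAP``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "QuantizedWindow",
    "MatrixConfig",
    "TextureMatrices",
    "FeatureVector",
    "FEATURE_NAMES",
    "FAMILY_COUNTS",
    "quantize",
    "build_glcm",
    "build_glrlm",
    "build_glszm",
    "build_gldm",
    "build_ngtdm",
    "features_75",
    "compute_features",
]

#: Cap applied to NGTDM Coarseness when the neighbourhood-difference sum is 0.
COARSENESS_CAP = 1e6

# Four standard 2D directions (0, 45, 90, 135 degrees) as (drow, dcol) offsets.
DIRECTIONS_2D = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
_GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)
_GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
_GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
_NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

#: Canonical 75 feature names in fixed order (GLCM, GLDM, GLRLM, GLSZM, NGTDM).
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"glcm_{n}" for n in _GLCM_NAMES)
    + tuple(f"gldm_{n}" for n in _GLDM_NAMES)
    + tuple(f"glrlm_{n}" for n in _GLRLM_NAMES)
    + tuple(f"glszm_{n}" for n in _GLSZM_NAMES)
    + tuple(f"ngtdm_{n}" for n in _NGTDM_NAMES)
)

FAMILY_COUNTS = {"glcm": 24, "gldm": 14, "glrlm": 16, "glszm": 16, "ngtdm": 5}

assert len(FEATURE_NAMES) == 75


@dataclass(frozen=True)
class QuantizedWindow:
    """An integer gray-level grid with values in ``1..n_levels``."""

    levels: np.ndarray
    n_levels: int
    origin_offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.size == 0:
            raise ValueError("quantized window is empty")
        if lv.min() < 1 or lv.max() > self.n_levels:
            raise ValueError("levels outside 1..n_levels")


@dataclass(frozen=True)
class MatrixConfig:
    """Parameters of the five texture-matrix constructions."""

    glcm_distance: int = 1
    directions: tuple[tuple[int, int], ...] = DIRECTIONS_2D
    symmetric: bool = True
    gldm_alpha: int = 0
    gldm_distance: int = 1
    ngtdm_distance: int = 1
    glszm_connectivity: int = 8


@dataclass
class TextureMatrices:
    """Bundle of the five matrices computed from one window."""

    glcm: np.ndarray
    glcm_levels: np.ndarray
    glrlm: np.ndarray
    glrlm_levels: np.ndarray
    glrlm_n_directions: int
    glszm: np.ndarray
    glszm_levels: np.ndarray
    gldm: np.ndarray
    gldm_levels: np.ndarray
    ngtdm: dict


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))


def quantize(
    patch: np.ndarray,
    n_bins: int = 16,
    range_policy: str = "global",
    intensity_range: tuple[float, float] | None = None,
) -> QuantizedWindow:
    """Equal-width gray-level quantization of an intensity grid.

    ``range_policy`` names where the bin endpoints come from: "global" uses
    the full range of the supplied grid (callers that quantize a whole patch
    before windowing get position-comparable levels), "window" is the same
    operation applied per window.  ``intensity_range`` overrides the
    endpoints explicitly.  A constant input maps to a single level.
    """
    a = np.asarray(patch, dtype=float)
    if a.size == 0:
        raise ValueError("empty patch")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if range_policy not in ("global", "window"):
        raise ValueError(f"unknown range_policy: {range_policy!r}")
    if intensity_range is not None:
        lo, hi = float(intensity_range[0]), float(intensity_range[1])
    else:
        lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        return QuantizedWindow(np.ones(a.shape, dtype=np.int64), 1)
    width = (hi - lo) / n_bins
    lv = np.floor((a - lo) / width).astype(np.int64) + 1
    np.clip(lv, 1, n_bins, out=lv)
    return QuantizedWindow(lv, n_bins)


def _offsets(directions: Iterable[tuple[int, int]], distance: int):
    return [(dr * distance, dc * distance) for dr, dc in directions]


def _level_index(levels_grid: np.ndarray):
    """Distinct level values present and a dense index over them."""
    levels = np.unique(levels_grid)
    idx = np.searchsorted(levels, levels_grid)
    return levels, idx


def build_glcm(
    w: QuantizedWindow,
    distance: int = 1,
    directions: Sequence[tuple[int, int]] = DIRECTIONS_2D,
    symmetric: bool = True,
):
    """Normalized gray-level co-occurrence matrix averaged over directions.

    Returns ``(P, levels)`` where ``P[i, j]`` is the probability of the level
    pair ``(levels[i], levels[j])`` and sums to 1.  Each direction is
    normalized separately, then the normalized matrices are averaged.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if not directions:
        raise ValueError("at least one direction required")
    levels, idx = _level_index(w.levels)
    ng = len(levels)
    rows, cols = idx.shape
    mats = []
    for dr, dc in _offsets(directions, distance):
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = idx[r0:r1, c0:c1].ravel()
        b = idx[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng)
        counts = counts.astype(float)
        if symmetric:
            counts = counts + counts.T
        total = counts.sum()
        if total > 0:
            mats.append(counts / total)
    if not mats:
        raise ValueError("window smaller than the offset in every direction")
    return np.mean(mats, axis=0), levels


def _run_lengths(line: np.ndarray):
    """(value, length) pairs of maximal equal-value runs along a 1D line."""
    if line.size == 0:
        return []
    change = np.flatnonzero(line[1:] != line[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [line.size]))
    return list(zip(line[starts], ends - starts))


def _lines(grid: np.ndarray, direction: tuple[int, int]):
    dr, dc = direction
    if (dr, dc) in ((0, 1), (0, -1)):
        return list(grid)
    if (dr, dc) in ((1, 0), (-1, 0)):
        return list(grid.T)
    if (dr, dc) in ((-1, 1), (1, -1)):  # anti-diagonals
        flipped = np.fliplr(grid)
        return [np.diag(flipped, k) for k in range(-grid.shape[0] + 1, grid.shape[1])]
    if (dr, dc) in ((1, 1), (-1, -1)):  # main diagonals
        return [np.diag(grid, k) for k in range(-grid.shape[0] + 1, grid.shape[1])]
    raise ValueError(f"unsupported run direction {direction}")


def build_glrlm(
    w: QuantizedWindow,
    directions: Sequence[tuple[int, int]] = DIRECTIONS_2D,
):
    """Run-length counts summed over directions.

    Returns ``(P, levels, n_directions)`` with ``P[i, j]`` the number of
    maximal runs of level ``levels[i]`` and length ``j + 1``.
    """
    levels, idx = _level_index(w.levels)
    ng = len(levels)
    max_len = max(w.levels.shape)
    P = np.zeros((ng, max_len), dtype=float)
    for d in directions:
        for line in _lines(idx, d):
            for value, length in _run_lengths(np.asarray(line)):
                P[value, length - 1] += 1
    return P, levels, len(directions)


def build_glszm(w: QuantizedWindow, connectivity: int = 8):
    """Size-zone counts: connected components of equal level by zone size.

    Returns ``(P, levels)``; ``P[i, s]`` counts zones of level ``levels[i]``
    with size ``s + 1``.  Zone sizes partition the window's pixels.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    levels, idx = _level_index(w.levels)
    ng = len(levels)
    P = np.zeros((ng, w.levels.size), dtype=float)
    for li in range(ng):
        lab, n = ndimage.label(idx == li, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            P[li, s - 1] += 1
    return P, levels


def build_gldm(w: QuantizedWindow, alpha: int = 0, distance: int = 1):
    """Dependence counts per (level, dependence + 1).

    A pixel's dependence is the number of in-window neighbours within
    Chebyshev ``distance`` whose level differs from the centre by at most
    ``alpha``.  Returns ``(P, levels)`` with column ``j`` holding dependence
    ``j`` (so the size index used in the features is ``j + 1``).
    """
    if alpha < 0 or distance < 1:
        raise ValueError("alpha must be >= 0 and distance >= 1")
    levels, idx = _level_index(w.levels)
    ng = len(levels)
    lv = w.levels.astype(np.int64)
    rows, cols = lv.shape
    dep = np.zeros((rows, cols), dtype=np.int64)
    for dr in range(-distance, distance + 1):
        for dc in range(-distance, distance + 1):
            if dr == 0 and dc == 0:
                continue
            r0, r1 = max(0, -dr), min(rows, rows - dr)
            c0, c1 = max(0, -dc), min(cols, cols - dc)
            if r0 >= r1 or c0 >= c1:
                continue
            close = np.abs(lv[r0:r1, c0:c1] - lv[r0 + dr:r1 + dr, c0 + dc:c1 + dc]) <= alpha
            dep[r0:r1, c0:c1] += close
    max_dep = int(dep.max())
    P = np.zeros((ng, max_dep + 1), dtype=float)
    np.add.at(P, (idx.ravel(), dep.ravel()), 1.0)
    return P, levels


def build_ngtdm(w: QuantizedWindow, distance: int = 1):
    """Neighbourhood gray-tone difference triples.

    For each level value ``i`` present: ``n_i`` pixels of that level,
    ``p_i = n_i / N`` and ``s_i``, the summed absolute difference between
    ``i`` and the mean level of each such pixel's in-window neighbourhood.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    levels, idx = _level_index(w.levels)
    lv = w.levels.astype(float)
    rows, cols = lv.shape
    nb_sum = np.zeros((rows, cols))
    nb_cnt = np.zeros((rows, cols))
    for dr in range(-distance, distance + 1):
        for dc in range(-distance, distance + 1):
            if dr == 0 and dc == 0:
                continue
            r0, r1 = max(0, -dr), min(rows, rows - dr)
            c0, c1 = max(0, -dc), min(cols, cols - dc)
            if r0 >= r1 or c0 >= c1:
                continue
            nb_sum[r0:r1, c0:c1] += lv[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
            nb_cnt[r0:r1, c0:c1] += 1
    valid = nb_cnt > 0
    diff = np.zeros((rows, cols))
    diff[valid] = np.abs(lv[valid] - nb_sum[valid] / nb_cnt[valid])
    ng = len(levels)
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for li in range(ng):
        sel = (idx == li) & valid
        n_i[li] = sel.sum()
        s_i[li] = diff[sel].sum()
    N = n_i.sum()
    p_i = n_i / N if N > 0 else n_i
    return {"levels": levels.astype(float), "n": n_i, "p": p_i, "s": s_i}


# ---------------------------------------------------------------------------
# feature formulas
# ---------------------------------------------------------------------------

def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    pos = p > 0
    out[pos] = p[pos] * np.log2(p[pos])
    return out


def glcm_features(P: np.ndarray, levels: np.ndarray) -> dict:
    """The 24 co-occurrence features from a normalized, averaged GLCM."""
    i = levels.astype(float)[:, None]
    j = levels.astype(float)[None, :]
    ng = len(levels)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((px * levels).sum())
    mu_y = float((py * levels).sum())
    sig_x = float(np.sqrt((px * (levels - mu_x) ** 2).sum()))
    sig_y = float(np.sqrt((py * (levels - mu_y) ** 2).sum()))

    # p_{x-y}(k), k = 0..ng-1 over |i-j| of level values; p_{x+y} over i+j
    absdiff = np.abs(i - j)
    sums = i + j
    kd = np.unique(absdiff)
    pd = np.array([P[absdiff == k].sum() for k in kd])
    ks = np.unique(sums)
    ps = np.array([P[sums == k].sum() for k in ks])

    contrast = float((P * (i - j) ** 2).sum())
    autoc = float((P * i * j).sum())
    joint_avg = mu_x
    clus = i + j - mu_x - mu_y
    cluster_tend = float((P * clus ** 2).sum())
    cluster_shade = float((P * clus ** 3).sum())
    cluster_prom = float((P * clus ** 4).sum())
    if sig_x > 0 and sig_y > 0:
        correlation = float((autoc - mu_x * mu_y) / (sig_x * sig_y))
    else:
        correlation = 1.0  # flat region convention
    diff_avg = float((kd * pd).sum())
    diff_ent = float(-_xlog2(pd).sum())
    diff_var = float(((kd - diff_avg) ** 2 * pd).sum())
    id_ = float((pd / (1.0 + kd)).sum())
    idm = float((pd / (1.0 + kd ** 2)).sum())
    idmn = float((pd / (1.0 + (kd / ng) ** 2)).sum())
    idn = float((pd / (1.0 + kd / ng)).sum())
    pos_k = kd > 0
    inv_var = float((pd[pos_k] / kd[pos_k] ** 2).sum())
    joint_energy = float((P ** 2).sum())
    joint_entropy = float(-_xlog2(P).sum())
    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxpy = px[:, None] * py[None, :]
    mask = (P > 0) & (pxpy > 0)
    hxy1 = float(-(P[mask] * np.log2(pxpy[mask])).sum())
    hxy2 = float(-_xlog2(pxpy).sum())
    hmax = max(hx, hy)
    imc1 = (joint_entropy - hxy1) / hmax if hmax > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy))
    imc2 = float(np.sqrt(max(arg, 0.0)))
    # MCC: sqrt of the second-largest eigenvalue of
    # Q(i,j) = sum_k P(i,k) P(j,k) / (px(i) py(k))
    if ng > 1:
        Q = np.zeros((ng, ng))
        for k in range(ng):
            if py[k] <= 0:
                continue
            Q += np.outer(
                np.where(px > 0, P[:, k] / np.where(px > 0, px, 1.0), 0.0),
                P[:, k],
            ) / py[k]
        eig = np.sort(np.real(np.linalg.eigvals(Q)))
        second = eig[-2] if len(eig) > 1 else 0.0
        mcc = float(np.sqrt(max(second, 0.0)))
    else:
        mcc = 1.0
    max_prob = float(P.max())
    sum_avg = float((ks * ps).sum())
    sum_ent = float(-_xlog2(ps).sum())
    sum_squares = float((P * (i - mu_x) ** 2).sum())
    return {
        "Autocorrelation": autoc, "ClusterProminence": cluster_prom,
        "ClusterShade": cluster_shade, "ClusterTendency": cluster_tend,
        "Contrast": contrast, "Correlation": correlation,
        "DifferenceAverage": diff_avg, "DifferenceEntropy": diff_ent,
        "DifferenceVariance": diff_var, "Id": id_, "Idm": idm, "Idmn": idmn,
        "Idn": idn, "Imc1": imc1, "Imc2": imc2, "InverseVariance": inv_var,
        "JointAverage": joint_avg, "JointEnergy": joint_energy,
        "JointEntropy": joint_entropy, "MCC": mcc,
        "MaximumProbability": max_prob, "SumAverage": sum_avg,
        "SumEntropy": sum_ent, "SumSquares": sum_squares,
    }


def _size_family_features(P: np.ndarray, levels: np.ndarray, norm: float):
    """Shared level/size emphasis statistics for GLRLM/GLSZM/GLDM.

    ``P[i, j]`` counts occurrences of level ``levels[i]`` at size ``j + 1``;
    ``norm`` is the total count the emphases divide by.
    """
    i = levels.astype(float)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    S = P.sum()
    p = P / S if S > 0 else P
    row = P.sum(axis=1)
    col = P.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    return {
        "gln": float((row ** 2).sum() / norm),
        "glnn": float((row ** 2).sum() / norm ** 2),
        "glv": float((p * (i - mu_i) ** 2).sum()),
        "hgle": float((P * i ** 2).sum() / norm),
        "large": float((P * j ** 2).sum() / norm),
        "lahgle": float((P * i ** 2 * j ** 2).sum() / norm),
        "lalgle": float((P * j ** 2 / i ** 2).sum() / norm),
        "lgle": float((P / i ** 2).sum() / norm),
        "sizen": float((col ** 2).sum() / norm),
        "sizenn": float((col ** 2).sum() / norm ** 2),
        "small": float((P / j ** 2).sum() / norm),
        "sahgle": float((P * i ** 2 / j ** 2).sum() / norm),
        "salgle": float((P / (i ** 2 * j ** 2)).sum() / norm),
        "entropy": float(-_xlog2(p).sum()),
        "sizevar": float((p * (j - mu_j) ** 2).sum()),
    }


def glrlm_features(P: np.ndarray, levels: np.ndarray, n_pixels: int,
                   n_directions: int) -> dict:
    nr = P.sum()
    f = _size_family_features(P, levels, nr)
    return {
        "GrayLevelNonUniformity": f["gln"],
        "GrayLevelNonUniformityNormalized": f["glnn"],
        "GrayLevelVariance": f["glv"],
        "HighGrayLevelRunEmphasis": f["hgle"],
        "LongRunEmphasis": f["large"],
        "LongRunHighGrayLevelEmphasis": f["lahgle"],
        "LongRunLowGrayLevelEmphasis": f["lalgle"],
        "LowGrayLevelRunEmphasis": f["lgle"],
        "RunEntropy": f["entropy"],
        "RunLengthNonUniformity": f["sizen"],
        "RunLengthNonUniformityNormalized": f["sizenn"],
        "RunPercentage": float(nr / (n_pixels * n_directions)),
        "RunVariance": f["sizevar"],
        "ShortRunEmphasis": f["small"],
        "ShortRunHighGrayLevelEmphasis": f["sahgle"],
        "ShortRunLowGrayLevelEmphasis": f["salgle"],
    }


def glszm_features(P: np.ndarray, levels: np.ndarray, n_pixels: int) -> dict:
    nz = P.sum()
    f = _size_family_features(P, levels, nz)
    return {
        "GrayLevelNonUniformity": f["gln"],
        "GrayLevelNonUniformityNormalized": f["glnn"],
        "GrayLevelVariance": f["glv"],
        "HighGrayLevelZoneEmphasis": f["hgle"],
        "LargeAreaEmphasis": f["large"],
        "LargeAreaHighGrayLevelEmphasis": f["lahgle"],
        "LargeAreaLowGrayLevelEmphasis": f["lalgle"],
        "LowGrayLevelZoneEmphasis": f["lgle"],
        "SizeZoneNonUniformity": f["sizen"],
        "SizeZoneNonUniformityNormalized": f["sizenn"],
        "SmallAreaEmphasis": f["small"],
        "SmallAreaHighGrayLevelEmphasis": f["sahgle"],
        "SmallAreaLowGrayLevelEmphasis": f["salgle"],
        "ZoneEntropy": f["entropy"],
        "ZonePercentage": float(nz / n_pixels),
        "ZoneVariance": f["sizevar"],
    }


def gldm_features(P: np.ndarray, levels: np.ndarray) -> dict:
    nz = P.sum()
    f = _size_family_features(P, levels, nz)
    return {
        "DependenceEntropy": f["entropy"],
        "DependenceNonUniformity": f["sizen"],
        "DependenceNonUniformityNormalized": f["sizenn"],
        "DependenceVariance": f["sizevar"],
        "GrayLevelNonUniformity": f["gln"],
        "GrayLevelVariance": f["glv"],
        "HighGrayLevelEmphasis": f["hgle"],
        "LargeDependenceEmphasis": f["large"],
        "LargeDependenceHighGrayLevelEmphasis": f["lahgle"],
        "LargeDependenceLowGrayLevelEmphasis": f["lalgle"],
        "LowGrayLevelEmphasis": f["lgle"],
        "SmallDependenceEmphasis": f["small"],
        "SmallDependenceHighGrayLevelEmphasis": f["sahgle"],
        "SmallDependenceLowGrayLevelEmphasis": f["salgle"],
    }


def ngtdm_features(tri: dict) -> dict:
    lv = tri["levels"]
    p = tri["p"]
    s = tri["s"]
    n = tri["n"]
    N = n.sum()
    present = p > 0
    lvp, pp, sp = lv[present], p[present], s[present]
    ngp = int(present.sum())
    ps_sum = float((pp * sp).sum())
    coarseness = 1.0 / ps_sum if ps_sum > 0 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)
    if ngp > 1:
        di = lvp[:, None] - lvp[None, :]
        pij = pp[:, None] * pp[None, :]
        contrast = float((pij * di ** 2).sum()) / (ngp * (ngp - 1)) * (s.sum() / N)
        busy_den = float(np.abs(lvp[:, None] * pp[:, None] - lvp[None, :] * pp[None, :]).sum())
        busyness = ps_sum / busy_den if busy_den > 0 else 0.0
        cplx = float(
            (np.abs(di) * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
             / (pp[:, None] + pp[None, :])).sum()
        ) / N
        s_sum = float(s.sum())
        strength = (
            float(((pp[:, None] + pp[None, :]) * di ** 2).sum()) / s_sum
            if s_sum > 0 else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        cplx = 0.0
        strength = 0.0
    return {
        "Busyness": busyness, "Coarseness": coarseness, "Complexity": cplx,
        "Contrast": contrast, "Strength": strength,
    }


def build_matrices(w: QuantizedWindow, cfg: MatrixConfig | None = None) -> TextureMatrices:
    cfg = cfg or MatrixConfig()
    glcm, glcm_lv = build_glcm(w, cfg.glcm_distance, cfg.directions, cfg.symmetric)
    glrlm, glrlm_lv, nd = build_glrlm(w, cfg.directions)
    glszm, glszm_lv = build_glszm(w, cfg.glszm_connectivity)
    gldm, gldm_lv = build_gldm(w, cfg.gldm_alpha, cfg.gldm_distance)
    ngtdm = build_ngtdm(w, cfg.ngtdm_distance)
    return TextureMatrices(glcm, glcm_lv, glrlm, glrlm_lv, nd, glszm, glszm_lv,
                           gldm, gldm_lv, ngtdm)


def compute_features(
    w: QuantizedWindow,
    cfg: MatrixConfig | None = None,
    names: Sequence[str] | None = None,
) -> dict:
    """Evaluate the requested features (default all 75) on one window.

    Only the matrix families actually requested are built, which matters when
    the sliding engine asks for a small subset per pixel.
    """
    cfg = cfg or MatrixConfig()
    wanted = tuple(names) if names is not None else FEATURE_NAMES
    unknown = set(wanted) - set(FEATURE_NAMES)
    if unknown:
        raise KeyError(f"unknown feature names: {sorted(unknown)}")
    families = {n.split("_", 1)[0] for n in wanted}
    n_pixels = w.levels.size
    out: dict[str, float] = {}
    if "glcm" in families:
        P, lv = build_glcm(w, cfg.glcm_distance, cfg.directions, cfg.symmetric)
        out.update({f"glcm_{k}": v for k, v in glcm_features(P, lv).items()})
    if "gldm" in families:
        P, lv = build_gldm(w, cfg.gldm_alpha, cfg.gldm_distance)
        out.update({f"gldm_{k}": v for k, v in gldm_features(P, lv).items()})
    if "glrlm" in families:
        P, lv, nd = build_glrlm(w, cfg.directions)
        out.update({f"glrlm_{k}": v
                    for k, v in glrlm_features(P, lv, n_pixels, nd).items()})
    if "glszm" in families:
        P, lv = build_glszm(w, cfg.glszm_connectivity)
        out.update({f"glszm_{k}": v
                    for k, v in glszm_features(P, lv, n_pixels).items()})
    if "ngtdm" in families:
        tri = build_ngtdm(w, cfg.ngtdm_distance)
        out.update({f"ngtdm_{k}": v for k, v in ngtdm_features(tri).items()})
    return {n: out[n] for n in wanted}


def features_75(w: QuantizedWindow, cfg: MatrixConfig | None = None) -> FeatureVector:
    """All 75 features in canonical order as a :class:`FeatureVector`."""
    vals = compute_features(w, cfg, FEATURE_NAMES)
    return FeatureVector(np.array([vals[n] for n in FEATURE_NAMES]), FEATURE_NAMES)
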