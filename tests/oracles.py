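"""Naive, loop-based reference implementations of the 75 texture features.

Everything here is computed from the written formula with explicit Python
loops and dictionaries — no shared code with the package implementation.
Used as the independent oracle in the equivalence tests.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

COARSENESS_CAP = 1e6
DIRS4 = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]


def naive_quantize(patch, n_bins=16, lo=None, hi=None):
    a = np.asarray(patch, dtype=float)
    lo = a.min() if lo is None else lo
    hi = a.max() if hi is None else hi
    if hi <= lo:
        return np.ones(a.shape, dtype=int), 1
    out = np.zeros(a.shape, dtype=int)
    width = (hi - lo) / n_bins
    for r in range(a.shape[0]):
        for c in range(a.shape[1]):
            b = int(math.floor((a[r, c] - lo) / width)) + 1
            out[r, c] = min(max(b, 1), n_bins)
    return out, n_bins


def naive_glcm(levels, distance=1, dirs=DIRS4, symmetric=True):
    """Direction-wise normalized co-occurrence, then averaged."""
    vals = sorted(set(levels.ravel().tolist()))
    pos = {v: k for k, v in enumerate(vals)}
    ng = len(vals)
    rows, cols = levels.shape
    mats = []
    for dr, dc in dirs:
        dr, dc = dr * distance, dc * distance
        m = np.zeros((ng, ng))
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    m[pos[levels[r, c]], pos[levels[r2, c2]]] += 1
        if symmetric:
            m = m + m.T
        if m.sum() > 0:
            mats.append(m / m.sum())
    return sum(mats) / len(mats), np.array(vals, dtype=float)


def naive_glcm_features(P, lv):
    ng = len(lv)
    px = [sum(P[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i][j] for i in range(ng)) for j in range(ng)]
    mux = sum(px[i] * lv[i] for i in range(ng))
    muy = sum(py[j] * lv[j] for j in range(ng))
    sigx = math.sqrt(sum(px[i] * (lv[i] - mux) ** 2 for i in range(ng)))
    sigy = math.sqrt(sum(py[j] * (lv[j] - muy) ** 2 for j in range(ng)))
    pd: Counter = Counter()
    ps: Counter = Counter()
    for i in range(ng):
        for j in range(ng):
            pd[abs(lv[i] - lv[j])] += P[i][j]
            ps[lv[i] + lv[j]] += P[i][j]

    def ent(items):
        return -sum(v * math.log2(v) for v in items if v > 0)

    out = {}
    out["Autocorrelation"] = sum(P[i][j] * lv[i] * lv[j] for i in range(ng) for j in range(ng))
    for power, name in [(2, "ClusterTendency"), (3, "ClusterShade"), (4, "ClusterProminence")]:
        out[name] = sum(P[i][j] * (lv[i] + lv[j] - mux - muy) ** power
                        for i in range(ng) for j in range(ng))
    out["Contrast"] = sum(P[i][j] * (lv[i] - lv[j]) ** 2 for i in range(ng) for j in range(ng))
    if sigx > 0 and sigy > 0:
        out["Correlation"] = (out["Autocorrelation"] - mux * muy) / (sigx * sigy)
    else:
        out["Correlation"] = 1.0
    da = sum(k * v for k, v in pd.items())
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = ent(pd.values())
    out["DifferenceVariance"] = sum((k - da) ** 2 * v for k, v in pd.items())
    out["Id"] = sum(v / (1 + k) for k, v in pd.items())
    out["Idm"] = sum(v / (1 + k * k) for k, v in pd.items())
    out["Idmn"] = sum(v / (1 + (k / ng) ** 2) for k, v in pd.items())
    out["Idn"] = sum(v / (1 + k / ng) for k, v in pd.items())
    hxy = ent(P.ravel())
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(P[i][j] * math.log2(px[i] * py[j])
                for i in range(ng) for j in range(ng)
                if P[i][j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j])
                for i in range(ng) for j in range(ng) if px[i] * py[j] > 0)
    out["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["Imc2"] = math.sqrt(max(1 - math.exp(-2 * (hxy2 - hxy)), 0.0))
    out["InverseVariance"] = sum(v / k ** 2 for k, v in pd.items() if k > 0)
    out["JointAverage"] = mux
    out["JointEnergy"] = sum(P[i][j] ** 2 for i in range(ng) for j in range(ng))
    out["JointEntropy"] = hxy
    if ng > 1:
        Q = np.zeros((ng, ng))
        for i in range(ng):
            for j in range(ng):
                acc = 0.0
                for k in range(ng):
                    if px[i] > 0 and py[k] > 0:
                        acc += P[i][k] * P[j][k] / (px[i] * py[k])
                Q[i, j] = acc
        ev = sorted(np.real(np.linalg.eigvals(Q)))
        out["MCC"] = math.sqrt(max(ev[-2], 0.0))
    else:
        out["MCC"] = 1.0
    out["MaximumProbability"] = P.max()
    out["SumAverage"] = sum(k * v for k, v in ps.items())
    out["SumEntropy"] = ent(ps.values())
    out["SumSquares"] = sum(P[i][j] * (lv[i] - mux) ** 2 for i in range(ng) for j in range(ng))
    return out


def naive_glrlm(levels, dirs=DIRS4):
    """Maximal runs per (level, length), directions summed."""
    rows, cols = levels.shape
    counts: Counter = Counter()
    for dr, dc in dirs:
        seen = set()
        for r in range(rows):
            for c in range(cols):
                # start of a run: predecessor out of bounds or different level
                pr, pc = r - dr, c - dc
                if 0 <= pr < rows and 0 <= pc < cols and levels[pr, pc] == levels[r, c]:
                    continue
                length = 1
                r2, c2 = r + dr, c + dc
                while 0 <= r2 < rows and 0 <= c2 < cols and levels[r2, c2] == levels[r, c]:
                    length += 1
                    r2, c2 = r2 + dr, c2 + dc
                counts[(levels[r, c], length)] += 1
                seen.add((r, c))
    return counts, len(dirs)


def _naive_size_stats(counts):
    total = sum(counts.values())
    by_level: Counter = Counter()
    by_size: Counter = Counter()
    for (lv, sz), v in counts.items():
        by_level[lv] += v
        by_size[sz] += v
    mu_i = sum(lv * v for (lv, _), v in counts.items()) / total
    mu_j = sum(sz * v for (_, sz), v in counts.items()) / total
    return total, by_level, by_size, mu_i, mu_j


def naive_runlength_features(counts, n_pixels, n_dirs):
    nr, by_level, by_size, mu_i, mu_j = _naive_size_stats(counts)
    f = {}
    f["GrayLevelNonUniformity"] = sum(v ** 2 for v in by_level.values()) / nr
    f["GrayLevelNonUniformityNormalized"] = sum(v ** 2 for v in by_level.values()) / nr ** 2
    f["GrayLevelVariance"] = sum(v * (lv - mu_i) ** 2 for (lv, _), v in counts.items()) / nr
    f["HighGrayLevelRunEmphasis"] = sum(v * lv ** 2 for (lv, _), v in counts.items()) / nr
    f["LongRunEmphasis"] = sum(v * sz ** 2 for (_, sz), v in counts.items()) / nr
    f["LongRunHighGrayLevelEmphasis"] = sum(v * lv ** 2 * sz ** 2 for (lv, sz), v in counts.items()) / nr
    f["LongRunLowGrayLevelEmphasis"] = sum(v * sz ** 2 / lv ** 2 for (lv, sz), v in counts.items()) / nr
    f["LowGrayLevelRunEmphasis"] = sum(v / lv ** 2 for (lv, _), v in counts.items()) / nr
    f["RunEntropy"] = -sum((v / nr) * math.log2(v / nr) for v in counts.values() if v > 0)
    f["RunLengthNonUniformity"] = sum(v ** 2 for v in by_size.values()) / nr
    f["RunLengthNonUniformityNormalized"] = sum(v ** 2 for v in by_size.values()) / nr ** 2
    f["RunPercentage"] = nr / (n_pixels * n_dirs)
    f["RunVariance"] = sum(v * (sz - mu_j) ** 2 for (_, sz), v in counts.items()) / nr
    f["ShortRunEmphasis"] = sum(v / sz ** 2 for (_, sz), v in counts.items()) / nr
    f["ShortRunHighGrayLevelEmphasis"] = sum(v * lv ** 2 / sz ** 2 for (lv, sz), v in counts.items()) / nr
    f["ShortRunLowGrayLevelEmphasis"] = sum(v / (lv ** 2 * sz ** 2) for (lv, sz), v in counts.items()) / nr
    return f


def naive_glszm(levels, connectivity=8):
    """Flood-fill connected zones of equal level."""
    rows, cols = levels.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros((rows, cols), dtype=bool)
    counts: Counter = Counter()
    for r in range(rows):
        for c in range(cols):
            if seen[r, c]:
                continue
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in nbrs:
                    r2, c2 = rr + dr, cc + dc
                    if (0 <= r2 < rows and 0 <= c2 < cols and not seen[r2, c2]
                            and levels[r2, c2] == levels[r, c]):
                        seen[r2, c2] = True
                        stack.append((r2, c2))
            counts[(levels[r, c], size)] += 1
    return counts


def naive_sizezone_features(counts, n_pixels):
    nz, by_level, by_size, mu_i, mu_j = _naive_size_stats(counts)
    f = {}
    f["GrayLevelNonUniformity"] = sum(v ** 2 for v in by_level.values()) / nz
    f["GrayLevelNonUniformityNormalized"] = sum(v ** 2 for v in by_level.values()) / nz ** 2
    f["GrayLevelVariance"] = sum(v * (lv - mu_i) ** 2 for (lv, _), v in counts.items()) / nz
    f["HighGrayLevelZoneEmphasis"] = sum(v * lv ** 2 for (lv, _), v in counts.items()) / nz
    f["LargeAreaEmphasis"] = sum(v * sz ** 2 for (_, sz), v in counts.items()) / nz
    f["LargeAreaHighGrayLevelEmphasis"] = sum(v * lv ** 2 * sz ** 2 for (lv, sz), v in counts.items()) / nz
    f["LargeAreaLowGrayLevelEmphasis"] = sum(v * sz ** 2 / lv ** 2 for (lv, sz), v in counts.items()) / nz
    f["LowGrayLevelZoneEmphasis"] = sum(v / lv ** 2 for (lv, _), v in counts.items()) / nz
    f["SizeZoneNonUniformity"] = sum(v ** 2 for v in by_size.values()) / nz
    f["SizeZoneNonUniformityNormalized"] = sum(v ** 2 for v in by_size.values()) / nz ** 2
    f["SmallAreaEmphasis"] = sum(v / sz ** 2 for (_, sz), v in counts.items()) / nz
    f["SmallAreaHighGrayLevelEmphasis"] = sum(v * lv ** 2 / sz ** 2 for (lv, sz), v in counts.items()) / nz
    f["SmallAreaLowGrayLevelEmphasis"] = sum(v / (lv ** 2 * sz ** 2) for (lv, sz), v in counts.items()) / nz
    f["ZoneEntropy"] = -sum((v / nz) * math.log2(v / nz) for v in counts.values() if v > 0)
    f["ZonePercentage"] = nz / n_pixels
    f["ZoneVariance"] = sum(v * (sz - mu_j) ** 2 for (_, sz), v in counts.items()) / nz
    return f


def naive_gldm(levels, alpha=0, distance=1):
    """Per-pixel dependence counting; matrix keyed by (level, dependence+1)."""
    rows, cols = levels.shape
    counts: Counter = Counter()
    for r in range(rows):
        for c in range(cols):
            dep = 0
            for dr in range(-distance, distance + 1):
                for dc in range(-distance, distance + 1):
                    if dr == 0 and dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < rows and 0 <= c2 < cols:
                        if abs(int(levels[r2, c2]) - int(levels[r, c])) <= alpha:
                            dep += 1
            counts[(levels[r, c], dep + 1)] += 1
    return counts


def naive_gldm_features(counts):
    nz, by_level, by_size, mu_i, mu_j = _naive_size_stats(counts)
    f = {}
    f["DependenceEntropy"] = -sum((v / nz) * math.log2(v / nz) for v in counts.values() if v > 0)
    f["DependenceNonUniformity"] = sum(v ** 2 for v in by_size.values()) / nz
    f["DependenceNonUniformityNormalized"] = sum(v ** 2 for v in by_size.values()) / nz ** 2
    f["DependenceVariance"] = sum(v * (sz - mu_j) ** 2 for (_, sz), v in counts.items()) / nz
    f["GrayLevelNonUniformity"] = sum(v ** 2 for v in by_level.values()) / nz
    f["GrayLevelVariance"] = sum(v * (lv - mu_i) ** 2 for (lv, _), v in counts.items()) / nz
    f["HighGrayLevelEmphasis"] = sum(v * lv ** 2 for (lv, _), v in counts.items()) / nz
    f["LargeDependenceEmphasis"] = sum(v * sz ** 2 for (_, sz), v in counts.items()) / nz
    f["LargeDependenceHighGrayLevelEmphasis"] = sum(v * lv ** 2 * sz ** 2 for (lv, sz), v in counts.items()) / nz
    f["LargeDependenceLowGrayLevelEmphasis"] = sum(v * sz ** 2 / lv ** 2 for (lv, sz), v in counts.items()) / nz
    f["LowGrayLevelEmphasis"] = sum(v / lv ** 2 for (lv, _), v in counts.items()) / nz
    f["SmallDependenceEmphasis"] = sum(v / sz ** 2 for (_, sz), v in counts.items()) / nz
    f["SmallDependenceHighGrayLevelEmphasis"] = sum(v * lv ** 2 / sz ** 2 for (lv, sz), v in counts.items()) / nz
    f["SmallDependenceLowGrayLevelEmphasis"] = sum(v / (lv ** 2 * sz ** 2) for (lv, sz), v in counts.items()) / nz
    return f


def naive_ngtdm(levels, distance=1):
    rows, cols = levels.shape
    vals = sorted(set(levels.ravel().tolist()))
    n = {v: 0 for v in vals}
    s = {v: 0.0 for v in vals}
    for r in range(rows):
        for c in range(cols):
            nb = []
            for dr in range(-distance, distance + 1):
                for dc in range(-distance, distance + 1):
                    if dr == 0 and dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < rows and 0 <= c2 < cols:
                        nb.append(float(levels[r2, c2]))
            if not nb:
                continue
            v = levels[r, c]
            n[v] += 1
            s[v] += abs(float(v) - sum(nb) / len(nb))
    return vals, n, s


def naive_ngtdm_features(vals, n, s):
    N = sum(n.values())
    p = {v: n[v] / N for v in vals}
    present = [v for v in vals if p[v] > 0]
    ngp = len(present)
    ps_sum = sum(p[v] * s[v] for v in present)
    f = {}
    f["Coarseness"] = min(1.0 / ps_sum if ps_sum > 0 else COARSENESS_CAP, COARSENESS_CAP)
    if ngp > 1:
        f["Contrast"] = (
            sum(p[a] * p[b] * (a - b) ** 2 for a in present for b in present)
            / (ngp * (ngp - 1)) * sum(s.values()) / N
        )
        busy_den = sum(abs(a * p[a] - b * p[b]) for a in present for b in present)
        f["Busyness"] = ps_sum / busy_den if busy_den > 0 else 0.0
        f["Complexity"] = sum(
            abs(a - b) * (p[a] * s[a] + p[b] * s[b]) / (p[a] + p[b])
            for a in present for b in present
        ) / N
        s_sum = sum(s.values())
        f["Strength"] = (
            sum((p[a] + p[b]) * (a - b) ** 2 for a in present for b in present) / s_sum
            if s_sum > 0 else 0.0
        )
    else:
        f["Contrast"] = 0.0
        f["Busyness"] = 0.0
        f["Complexity"] = 0.0
        f["Strength"] = 0.0
    return f


def naive_features_75(levels):
    """All 75 features of a quantized window, canonical order, naive path."""
    n_pixels = levels.size
    glcm, lv = naive_glcm(levels)
    out = {f"glcm_{k}": v for k, v in naive_glcm_features(glcm, lv).items()}
    out.update({f"gldm_{k}": v for k, v in naive_gldm_features(naive_gldm(levels)).items()})
    runs, nd = naive_glrlm(levels)
    out.update({f"glrlm_{k}": v for k, v in naive_runlength_features(runs, n_pixels, nd).items()})
    out.update({f"glszm_{k}": v for k, v in naive_sizezone_features(naive_glszm(levels), n_pixels).items()})
    vals, n, s = naive_ngtdm(levels)
    out.update({f"ngtdm_{k}": v for k, v in naive_ngtdm_features(vals, n, s).items()})
    return out
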