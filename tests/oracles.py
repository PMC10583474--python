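"""Independent brute-force oracles.

Deliberately naive implementations (plain Python loops, direct definitions)
used to cross-check the package's vectorised code. Nothing here imports the
package's computational internals beyond type-free numpy.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# first-order
# ---------------------------------------------------------------------------

def naive_first_order(values, bin_width=25.0, voxel_volume_mm3=1.0):
    v = sorted(float(x) for x in values)
    n = len(v)
    mean = sum(v) / n
    mn, mx = v[0], v[-1]

    def percentile(q):
        pos = q / 100.0 * (n - 1)
        lo, hi = math.floor(pos), math.ceil(pos)
        frac = pos - lo
        return v[lo] * (1 - frac) + v[hi] * frac

    p10, p25, p50, p75, p90 = (percentile(q) for q in (10, 25, 50, 75, 90))
    m2 = sum((x - mean) ** 2 for x in v) / n
    m3 = sum((x - mean) ** 3 for x in v) / n
    m4 = sum((x - mean) ** 4 for x in v) / n
    energy = sum(x * x for x in v)
    sub = [x for x in v if p10 <= x <= p90]
    if sub:
        sm = sum(sub) / len(sub)
        rmad = sum(abs(x - sm) for x in sub) / len(sub)
    else:
        rmad = 0.0
    counts = {}
    for x in v:
        b = math.floor((x - mn) / bin_width)
        counts[b] = counts.get(b, 0) + 1
    probs = [c / n for c in counts.values()]
    entropy = -sum(p * math.log2(p) for p in probs)
    uniformity = sum(p * p for p in probs)
    return {
        "firstorder_Energy": energy,
        "firstorder_TotalEnergy": energy * voxel_volume_mm3,
        "firstorder_Entropy": entropy,
        "firstorder_Minimum": mn,
        "firstorder_10Percentile": p10,
        "firstorder_90Percentile": p90,
        "firstorder_Maximum": mx,
        "firstorder_Mean": mean,
        "firstorder_Median": p50,
        "firstorder_InterquartileRange": p75 - p25,
        "firstorder_Range": mx - mn,
        "firstorder_MeanAbsoluteDeviation": sum(abs(x - mean) for x in v) / n,
        "firstorder_RobustMeanAbsoluteDeviation": rmad,
        "firstorder_RootMeanSquared": math.sqrt(energy / n),
        "firstorder_StandardDeviation": math.sqrt(m2),
        "firstorder_Variance": m2,
        "firstorder_Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "firstorder_Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "firstorder_Uniformity": uniformity,
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def naive_glcm_matrix(levels, mask, offset, n_levels):
    """Symmetric normalised co-occurrence matrix by looping over all voxels."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    P = np.zeros((n_levels, n_levels), dtype=float)
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                xx, yy, zz = x + offset[0], y + offset[1], z + offset[2]
                if not (0 <= xx < shape[0] and 0 <= yy < shape[1] and 0 <= zz < shape[2]):
                    continue
                if not mask[xx, yy, zz]:
                    continue
                i, j = levels[x, y, z] - 1, levels[xx, yy, zz] - 1
                P[i, j] += 1
                P[j, i] += 1
    s = P.sum()
    return P / s if s > 0 else P


def naive_glcm_features(P):
    """Feature formulas written directly from their definitions."""
    Ng = P.shape[0]
    idx = range(1, Ng + 1)
    px = [sum(P[i - 1, j - 1] for j in idx) for i in idx]
    mu = sum(i * px[i - 1] for i in idx)
    sigma2 = sum((i - mu) ** 2 * px[i - 1] for i in idx)

    def s2(f):
        return sum(f(i, j) * P[i - 1, j - 1] for i in idx for j in idx)

    p_diff = {}
    p_sum = {}
    for i in idx:
        for j in idx:
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + P[i - 1, j - 1]
            p_sum[i + j] = p_sum.get(i + j, 0.0) + P[i - 1, j - 1]
    da = sum(k * p for k, p in p_diff.items())
    hxy = -sum(p * math.log2(p) for p in P.ravel() if p > 0)
    hx = -sum(p * math.log2(p) for p in px if p > 0)
    eps = np.finfo(float).eps
    hxy1 = -s2(lambda i, j: math.log2(px[i - 1] * px[j - 1] + eps) if P[i - 1, j - 1] > 0 else 0.0)
    hxy2 = -sum(
        px[i - 1] * px[j - 1] * math.log2(px[i - 1] * px[j - 1])
        for i in idx
        for j in idx
        if px[i - 1] * px[j - 1] > 0
    )
    autoc = s2(lambda i, j: i * j)
    out = {
        "glcm_Autocorrelation": autoc,
        "glcm_ClusterProminence": s2(lambda i, j: (i + j - 2 * mu) ** 4),
        "glcm_ClusterShade": s2(lambda i, j: (i + j - 2 * mu) ** 3),
        "glcm_ClusterTendency": s2(lambda i, j: (i + j - 2 * mu) ** 2),
        "glcm_Contrast": s2(lambda i, j: (i - j) ** 2),
        "glcm_Correlation": (autoc - mu * mu) / sigma2 if sigma2 > eps else 1.0,
        "glcm_DifferenceAverage": da,
        "glcm_DifferenceEntropy": -sum(p * math.log2(p) for p in p_diff.values() if p > 0),
        "glcm_DifferenceVariance": sum((k - da) ** 2 * p for k, p in p_diff.items()),
        "glcm_Id": s2(lambda i, j: 1.0 / (1 + abs(i - j))),
        "glcm_Idm": s2(lambda i, j: 1.0 / (1 + (i - j) ** 2)),
        "glcm_Idmn": s2(lambda i, j: 1.0 / (1 + (i - j) ** 2 / Ng**2)),
        "glcm_Idn": s2(lambda i, j: 1.0 / (1 + abs(i - j) / Ng)),
        "glcm_Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "glcm_Imc2": math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy)))),
        "glcm_InverseVariance": sum(
            P[i - 1, j - 1] / (i - j) ** 2 for i in idx for j in idx if i != j
        ),
        "glcm_JointAverage": mu,
        "glcm_JointEnergy": float((P**2).sum()),
        "glcm_JointEntropy": hxy,
        "glcm_MaximumProbability": float(P.max()),
        "glcm_SumEntropy": -sum(p * math.log2(p) for p in p_sum.values() if p > 0),
        "glcm_SumSquares": s2(lambda i, j: (i - mu) ** 2),
    }
    return out


# ---------------------------------------------------------------------------
# information gain / statistics
# ---------------------------------------------------------------------------

def naive_information_gain(x, y, n_bins=10):
    """IG over equal-frequency bins, computed with dictionaries."""
    x = list(map(float, x))
    y = list(y)
    n = len(x)
    qs = [np.quantile(x, k / n_bins) for k in range(1, n_bins)]
    edges = sorted(set(qs))

    def binof(v):
        b = 0
        for e in edges:
            if v > e:
                b += 1
        return b

    def entropy(labels):
        h = 0.0
        for c in set(labels):
            p = labels.count(c) / len(labels)
            h -= p * math.log2(p)
        return h

    bins = [binof(v) for v in x]
    hy = entropy(y)
    cond = 0.0
    for b in set(bins):
        sub = [y[i] for i in range(n) if bins[i] == b]
        cond += len(sub) / n * entropy(sub)
    return max(0.0, hy - cond)


def naive_mann_whitney_u(x, y):
    """U as a direct count of winning/tied pairs."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def naive_exact_mw_p(x, y):
    """Two-sided exact p by enumerating every group assignment."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = naive_mann_whitney_u(x, y)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        grp = [pooled[i] for i in comb]
        rest = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(naive_mann_whitney_u(grp, rest))
    us = np.array(us)
    p_le = float(np.mean(us <= u_obs + 1e-9))
    p_ge = float(np.mean(us >= u_obs - 1e-9))
    return min(1.0, 2 * min(p_le, p_ge))


def naive_auc(scores, labels):
    """AUC as the fraction of (positive, negative) pairs won, ties half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    return naive_mann_whitney_u(pos, neg) / (len(pos) * len(neg))
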