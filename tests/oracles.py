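"""Independent brute-force oracles used by the test suite.

Everything here is written with explicit loops and naive formulas, on
purpose: these functions re-derive expected values without touching the
package's vectorised implementations.
"""

from __future__ import annotations

import numpy as np

# 13 unique distance-1 3D directions (one of each +/- pair), mirroring the
# convention under test but re-derived here independently.
NAIVE_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]

FEATURES = (
    "ClusterProminence", "ClusterShade", "Correlation", "Energy", "Entropy",
    "HaralickCorrelation", "Inertia", "InverseDifferenceMoment",
)


def naive_quantize(a, G, lo=None, hi=None):
    a = np.asarray(a, dtype=float)
    lo = a.min() if lo is None else lo
    hi = a.max() if hi is None else hi
    if hi == lo:
        return np.zeros(a.shape, dtype=int)
    out = np.empty(a.shape, dtype=int)
    for idx in np.ndindex(a.shape):
        x = min(max(a[idx], lo), hi)
        b = int(np.floor(G * (x - lo) / (hi - lo)))
        out[idx] = min(b, G - 1)
    return out


def naive_glcm(window, offset, G):
    """Symmetric normalized pair counts by exhaustive enumeration."""
    w = np.asarray(window)
    counts = np.zeros((G, G))
    for i in range(w.shape[0]):
        for j in range(w.shape[1]):
            for k in range(w.shape[2]):
                i2, j2, k2 = i + offset[0], j + offset[1], k + offset[2]
                if 0 <= i2 < w.shape[0] and 0 <= j2 < w.shape[1] and 0 <= k2 < w.shape[2]:
                    counts[w[i, j, k], w[i2, j2, k2]] += 1
                    counts[w[i2, j2, k2], w[i, j, k]] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def naive_features(p):
    """The eight Haralick statistics by double loops over the GLCM."""
    G = p.shape[0]
    energy = entropy = inertia = idm = 0.0
    mu_i = mu_j = 0.0
    for i in range(G):
        for j in range(G):
            mu_i += i * p[i, j]
            mu_j += j * p[i, j]
    var_i = var_j = 0.0
    for i in range(G):
        for j in range(G):
            var_i += (i - mu_i) ** 2 * p[i, j]
            var_j += (j - mu_j) ** 2 * p[i, j]
    corr_num = shade = prom = 0.0
    for i in range(G):
        for j in range(G):
            v = p[i, j]
            energy += v * v
            if v > 0:
                entropy -= v * np.log2(v)
            inertia += (i - j) ** 2 * v
            idm += v / (1.0 + (i - j) ** 2)
            corr_num += (i - mu_i) * (j - mu_j) * v
            s = (i - mu_i) + (j - mu_j)
            shade += s**3 * v
            prom += s**4 * v
    sig = np.sqrt(var_i * var_j)
    correlation = corr_num / sig if sig > 1e-12 else 0.0
    # marginal-moment form for HaralickCorrelation
    px = p.sum(axis=1)
    mu_t = sum(i * px[i] for i in range(G))
    var_t = sum((i - mu_t) ** 2 * px[i] for i in range(G))
    raw = sum(i * j * p[i, j] for i in range(G) for j in range(G))
    hcorr = (raw - mu_t**2) / var_t if var_t > 1e-12 else 0.0
    return {
        "ClusterProminence": prom, "ClusterShade": shade, "Correlation": correlation,
        "Energy": energy, "Entropy": entropy, "HaralickCorrelation": hcorr,
        "Inertia": inertia, "InverseDifferenceMoment": idm,
    }


def naive_texture_maps(a, G, window=3, lo=None, hi=None):
    """Per-voxel offset-averaged features with replicate borders, all loops."""
    q = naive_quantize(a, G, lo, hi)
    r = window // 2
    P = np.pad(q, r, mode="edge")
    out = {n: np.zeros(a.shape) for n in FEATURES}
    for x in range(a.shape[0]):
        for y in range(a.shape[1]):
            for z in range(a.shape[2]):
                win = P[x : x + window, y : y + window, z : z + window]
                acc = {n: 0.0 for n in FEATURES}
                for o in NAIVE_OFFSETS:
                    f = naive_features(naive_glcm(win, o, G))
                    for n in FEATURES:
                        acc[n] += f[n]
                for n in FEATURES:
                    out[n][x, y, z] = acc[n] / len(NAIVE_OFFSETS)
    return out


def naive_rollout(mats, normalize=True):
    """Explicit (A + I) product across layers."""
    n = mats[0].shape[0]
    R = np.eye(n)
    for A in mats:
        M = np.asarray(A) + np.eye(n)
        if normalize:
            M = M / M.sum(axis=1, keepdims=True)
        R = M @ R
    return R


def mann_whitney_auc(scores, labels):
    """AUC as the normalized Mann-Whitney U statistic (pair counting)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))
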