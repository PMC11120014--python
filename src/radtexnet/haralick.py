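"""Per-voxel 3D Haralick texture maps from sliding-window co-occurrence matrices.

For every voxel a gray-level co-occurrence matrix (GLCM) is accumulated over
all voxel pairs inside the centered cubic window, separately for each of the
13 unique 3D offset directions at Chebyshev distance 1.  Eight Haralick
statistics of the GLCM are computed per offset and averaged across offsets,
yielding one full-size texture map per feature.

The public surface offers both the exact definition on a single window
(:func:`glcm_window` + :func:`haralick_features`) and a vectorised whole-volume
path (:func:`texture_maps`) that produces identical values.  The vectorised
path never materialises per-voxel GLCMs: for each offset it loops over the
gray-level pairs present in the volume and turns the per-voxel pair counts
into running moments from which all eight features follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .preprocess import CTVolume

FEATURE_NAMES: Tuple[str, ...] = (
    "ClusterProminence",
    "ClusterShade",
    "Correlation",
    "Energy",
    "Entropy",
    "HaralickCorrelation",
    "Inertia",
    "InverseDifferenceMoment",
)

#: The 13 unique direction offsets at Chebyshev distance 1 (one per +/- pair).
OFFSETS_13: Tuple[Tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_VAR_EPS = 1e-12  # below this the marginal variance counts as degenerate


@dataclass
class GLCM:
    """A symmetric, normalized gray-level co-occurrence distribution."""

    p: np.ndarray
    G: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError(f"GLCM must be square, got shape {self.p.shape}")
        if self.p.shape[0] != self.G:
            raise ValueError("GLCM size does not match G")


@dataclass
class TextureSpec:
    """Window size, offset distance, quantization depth and feature order."""

    window: int = 3
    offset_distance: int = 1
    gray_levels: int = 32
    feature_names: Tuple[str, ...] = FEATURE_NAMES
    #: fixed quantization range (lo, hi); None quantizes over each volume's range
    quant_range: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if self.gray_levels < 2:
            raise ValueError(f"gray_levels must be >= 2, got {self.gray_levels}")
        if self.offset_distance < 1:
            raise ValueError("offset_distance must be positive")
        if tuple(self.feature_names) != FEATURE_NAMES:
            raise ValueError(f"feature_names must be {FEATURE_NAMES}")


@dataclass
class TextureMapSet:
    """Eight named texture maps co-registered with their source volume."""

    maps: Dict[str, np.ndarray]
    spec: TextureSpec

    def __post_init__(self) -> None:
        if set(self.maps) != set(FEATURE_NAMES):
            raise ValueError("all 8 named maps must be present")
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) != 1:
            raise ValueError(f"maps must share one shape, got {shapes}")

    @property
    def shape(self) -> Tuple[int, ...]:
        return next(iter(self.maps.values())).shape

    def stacked(self, order: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        return np.stack([self.maps[k] for k in order], axis=0)


def quantize(a: np.ndarray, G: int, value_range: Optional[Tuple[float, float]] = None) -> np.ndarray:
    """Equal-width quantization into integer gray levels 0..G-1.

    The bin of value x is ``floor(G * (x - lo) / (hi - lo))`` with x == hi
    mapped to G-1; values outside a fixed ``value_range`` are clipped.
    A constant array (degenerate range) maps to all zeros.
    """
    if G < 2:
        raise ValueError(f"G must be >= 2, got {G}")
    a = np.asarray(a, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise ValueError("array contains NaN or Inf")
    if value_range is None:
        lo, hi = float(a.min()), float(a.max())
    else:
        lo, hi = map(float, value_range)
        if not lo < hi:
            raise ValueError(f"invalid quantization range {value_range}")
    if hi == lo:
        return np.zeros(a.shape, dtype=np.int64)
    q = np.floor(G * (np.clip(a, lo, hi) - lo) / (hi - lo)).astype(np.int64)
    return np.clip(q, 0, G - 1)


def glcm_window(q: np.ndarray, offset: Sequence[int], G: int) -> GLCM:
    """Symmetric normalized GLCM of one cubic window for one offset.

    Every in-window voxel pair (v, v + offset) is counted in both orderings
    and the counts are normalized to sum to one.
    """
    q = np.asarray(q)
    if q.ndim != 3:
        raise ValueError("window must be 3D")
    o = tuple(int(c) for c in offset)
    if len(o) != 3 or all(c == 0 for c in o):
        raise ValueError(f"offset must be a nonzero 3-vector, got {offset}")
    if any(abs(c) >= s for c, s in zip(o, q.shape)):
        raise ValueError(f"offset {o} has no valid pairs inside window {q.shape}")
    sl_a = tuple(slice(max(0, -c), s - max(0, c)) for c, s in zip(o, q.shape))
    sl_b = tuple(slice(max(0, c), s - max(0, -c)) for c, s in zip(o, q.shape))
    i = q[sl_a].ravel()
    j = q[sl_b].ravel()
    if i.size == 0:
        raise ValueError(f"offset {o} has no valid pairs inside window {q.shape}")
    counts = np.zeros((G, G), dtype=np.float64)
    np.add.at(counts, (i, j), 1.0)
    np.add.at(counts, (j, i), 1.0)
    return GLCM(p=counts / counts.sum(), G=G)


def haralick_features(m: GLCM) -> Dict[str, float]:
    """The eight Haralick statistics of a normalized GLCM.

    Correlation uses the joint central moment over sigma^2 of the GLCM means;
    HaralickCorrelation is computed from the marginal distribution's mean and
    variance.  On a symmetric GLCM the two coincide; both return 0 when the
    relevant variance is degenerate (constant window).
    """
    p = m.p
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"GLCM is not normalized (sum={total})")
    G = m.G
    idx = np.arange(G, dtype=np.float64)
    ii = idx[:, None] * np.ones((1, G))
    jj = ii.T

    energy = float(np.sum(p * p))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    diff2 = (ii - jj) ** 2
    inertia = float(np.sum(diff2 * p))
    idm = float(np.sum(p / (1.0 + diff2)))

    mu = float(np.sum(ii * p))  # mean of i under p (== mean of j if symmetric)
    mu_j = float(np.sum(jj * p))
    var_i = float(np.sum((ii - mu) ** 2 * p))
    var_j = float(np.sum((jj - mu_j) ** 2 * p))
    sigma2 = np.sqrt(var_i * var_j)
    if sigma2 > _VAR_EPS:
        correlation = float(np.sum((ii - mu) * (jj - mu_j) * p) / sigma2)
    else:
        correlation = 0.0

    s = (ii - mu) + (jj - mu_j)
    shade = float(np.sum(s**3 * p))
    prominence = float(np.sum(s**4 * p))

    # marginal p_x with mean mu_t and variance sigma_t^2
    px = p.sum(axis=1)
    mu_t = float(np.sum(idx * px))
    sigma_t2 = float(np.sum((idx - mu_t) ** 2 * px))
    if sigma_t2 > _VAR_EPS:
        hcorr = float((np.sum(ii * jj * p) - mu_t * mu_t) / sigma_t2)
    else:
        hcorr = 0.0

    return {
        "ClusterProminence": prominence,
        "ClusterShade": shade,
        "Correlation": correlation,
        "Energy": energy,
        "Entropy": entropy,
        "HaralickCorrelation": hcorr,
        "Inertia": inertia,
        "InverseDifferenceMoment": idm,
    }


def _offset_kernel(window: int, o: Tuple[int, int, int]) -> np.ndarray:
    """Ones over pair-start displacements d (relative to the window center)
    such that both d and d+o lie inside the window; zero elsewhere."""
    r = window // 2
    k = np.zeros((window,) * 3)
    sl = tuple(
        slice(max(0, -c), window - max(0, c)) for c in o
    )
    k[sl] = 1.0
    return k


def texture_maps(v: CTVolume, spec: Optional[TextureSpec] = None) -> TextureMapSet:
    """All eight per-voxel texture maps for a volume.

    Borders are handled by edge replication so every map has the source
    volume's shape.  Quantization is computed once per volume (over the
    volume's range or ``spec.quant_range``), shared by all windows.
    """
    spec = spec or TextureSpec()
    a = np.asarray(v.voxels, dtype=np.float64)
    w = spec.window
    if any(s < w for s in a.shape):
        raise ValueError(f"volume {a.shape} smaller than window {w}")
    G = spec.gray_levels
    q = quantize(a, G, spec.quant_range)

    r = w // 2
    pad = r + spec.offset_distance
    P = np.pad(q, pad, mode="edge")
    shape = a.shape
    center = tuple(slice(pad, pad + s) for s in shape)

    sums = {name: np.zeros(shape) for name in FEATURE_NAMES}
    offsets = [tuple(spec.offset_distance * c for c in o) for o in OFFSETS_13]
    for o in offsets:
        feats = _offset_feature_maps(P, o, G, w, center, shape)
        for name in FEATURE_NAMES:
            sums[name] += feats[name]
    maps = {name: sums[name] / len(offsets) for name in FEATURE_NAMES}
    return TextureMapSet(maps=maps, spec=spec)


def _offset_feature_maps(P, o, G, w, center, shape):
    """Per-voxel Haralick features for a single offset direction.

    ``P`` is the padded quantized volume.  For the gray-level pair (lo, hi)
    at each pair-start site, the windowed geometric pair count W(v) is a
    box correlation with an offset-trimmed kernel; features are assembled
    from running moments of the symmetric ordered counts M = 2W.
    """
    sl_a = tuple(slice(max(0, -c), s - max(0, c)) for c, s in zip(o, P.shape))
    sl_b = tuple(slice(max(0, c), s - max(0, -c)) for c, s in zip(o, P.shape))
    A = P[sl_a]
    B = P[sl_b]
    lo = np.minimum(A, B)
    hi = np.maximum(A, B)
    code = lo * G + hi

    # Embed pair-start codes at their global (padded) coordinates.
    code_global = np.full(P.shape, -1, dtype=np.int64)
    code_global[sl_a] = code

    kernel = _offset_kernel(w, o)
    n_geo = float(np.prod([w - abs(c) for c in o]))  # pairs per window
    m_tot = 2.0 * n_geo  # ordered pair count

    acc = {k: np.zeros(shape) for k in ("E2", "H", "T1", "T2", "T3", "T4", "S2", "U", "V2", "D")}
    for c in np.unique(code):
        gi, gj = divmod(int(c), G)
        ind = (code_global == c).astype(np.float64)
        W = ndimage.correlate(ind, kernel, mode="constant", cval=0.0)[center]
        if gi == gj:
            M_cell = 2.0 * W  # single diagonal cell holding both orderings
            acc["E2"] += M_cell**2
            acc["H"] += np.where(W > 0, M_cell * np.log2(np.maximum(M_cell, 1e-300)), 0.0)
        else:
            # two symmetric cells, each with count W
            acc["E2"] += 2.0 * W**2
            acc["H"] += 2.0 * np.where(W > 0, W * np.log2(np.maximum(W, 1e-300)), 0.0)
        M = 2.0 * W  # total ordered count for this unordered pair
        s = float(gi + gj)
        acc["T1"] += s * M
        acc["T2"] += s**2 * M
        acc["T3"] += s**3 * M
        acc["T4"] += s**4 * M
        acc["S2"] += float(gi * gi + gj * gj) * M
        acc["U"] += float(gi * gj) * M
        acc["V2"] += float((gi - gj) ** 2) * M
        acc["D"] += M / (1.0 + (gi - gj) ** 2)

    m = m_tot
    energy = acc["E2"] / (m * m)
    entropy = np.log2(m) - acc["H"] / m
    inertia = acc["V2"] / m
    idm = acc["D"] / m
    mu = acc["T1"] / (2.0 * m)
    sigma2 = acc["S2"] / (2.0 * m) - mu**2
    cov = acc["U"] / m - mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        correlation = np.where(sigma2 > _VAR_EPS, cov / np.maximum(sigma2, _VAR_EPS), 0.0)
        hcorr = correlation.copy()  # marginal-moment form coincides (symmetric GLCM)
    c2 = 2.0 * mu
    shade = (acc["T3"] - 3 * c2 * acc["T2"] + 3 * c2**2 * acc["T1"] - c2**3 * m) / m
    prominence = (acc["T4"] - 4 * c2 * acc["T3"] + 6 * c2**2 * acc["T2"] - 4 * c2**3 * acc["T1"] + c2**4 * m) / m

    return {
        "ClusterProminence": prominence,
        "ClusterShade": shade,
        "Correlation": correlation,
        "Energy": energy,
        "Entropy": np.maximum(entropy, 0.0),
        "HaralickCorrelation": hcorr,
        "Inertia": inertia,
        "InverseDifferenceMoment": idm,
    }
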