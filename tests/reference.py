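"""Independent brute-force reference implementations for texture features.

Everything here is written with plain Python loops and flood fills, kept
deliberately separate from the production code paths in ``tumorad.texture``
so it can serve as an oracle on small fixtures.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

DIRS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def ref_discretize(values: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    levels = np.zeros(values.shape, dtype=int)
    inside = [tuple(v) for v in np.argwhere(mask)]
    vals = [values[v] for v in inside]
    vmin, vmax = min(vals), max(vals)
    for v in inside:
        if vmax == vmin:
            levels[v] = 1
        else:
            lv = int(math.floor((values[v] - vmin) / ((vmax - vmin) / n_bins))) + 1
            levels[v] = min(lv, n_bins)
    return levels


def _inside(shape, v):
    return all(0 <= c < n for c, n in zip(v, shape))


def ref_glcm(levels: np.ndarray, mask: np.ndarray, n_bins: int, distance: int = 1,
             dirs=DIRS_13) -> np.ndarray:
    counts = np.zeros((n_bins, n_bins))
    shape = levels.shape
    for v in map(tuple, np.argwhere(mask)):
        for d in dirs:
            w = tuple(c + distance * o for c, o in zip(v, d))
            if _inside(shape, w) and mask[w]:
                counts[levels[v] - 1, levels[w] - 1] += 1
                counts[levels[w] - 1, levels[v] - 1] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no pairs")
    return counts / total


def ref_glcm_features(glcm: np.ndarray) -> dict[str, float]:
    ng = glcm.shape[0]
    contrast = homog = 0.0
    mu = 0.0
    for i in range(ng):
        for j in range(ng):
            p = glcm[i, j]
            contrast += p * (i - j) ** 2
            homog += p / (1 + abs(i - j))
    px = glcm.sum(axis=1)
    mu = sum((i + 1) * px[i] for i in range(ng))
    var = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    if var <= 0:
        corr = float("nan")
    else:
        eij = sum((i + 1) * (j + 1) * glcm[i, j] for i in range(ng) for j in range(ng))
        corr = (eij - mu * mu) / var
    return {"Homogeneity": homog, "Correlation": corr, "Contrast": contrast}


def ref_ngtdm(levels: np.ndarray, mask: np.ndarray, n_bins: int, eps: float = 1e-6):
    shape = levels.shape
    n_i = np.zeros(n_bins)
    s_i = np.zeros(n_bins)
    n_valid = 0
    for v in map(tuple, np.argwhere(mask)):
        nbrs = []
        for d in NEIGHBORS_26:
            w = tuple(c + o for c, o in zip(v, d))
            if _inside(shape, w) and mask[w]:
                nbrs.append(levels[w])
        if not nbrs:
            continue
        n_valid += 1
        a = sum(nbrs) / len(nbrs)
        i = levels[v]
        n_i[i - 1] += 1
        s_i[i - 1] += abs(i - a)
    if n_valid < 2:
        raise ValueError("degenerate")
    p = n_i / n_valid
    num = sum(p[i] * s_i[i] for i in range(n_bins))
    coarseness = 1.0 / (eps + num)
    denom = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            if p[i] > 0 and p[j] > 0:
                denom += abs((i + 1) * p[i] - (j + 1) * p[j])
    busyness = num / denom if denom > 0 else 0.0
    complexity = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            if p[i] > 0 and p[j] > 0:
                complexity += abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (n_valid * (p[i] + p[j]))
    return {"Coarseness": coarseness, "Busyness": busyness, "Complexity": complexity}


def ref_glrlm(levels: np.ndarray, mask: np.ndarray, n_bins: int, dirs=DIRS_13) -> np.ndarray:
    """Maximal runs per direction, by walking each run start to its end."""
    shape = levels.shape
    runs = []  # (level, length)
    for d in dirs:
        for v in map(tuple, np.argwhere(mask)):
            prev = tuple(c - o for c, o in zip(v, d))
            if _inside(shape, prev) and mask[prev] and levels[prev] == levels[v]:
                continue  # not a run start
            length = 1
            w = tuple(c + o for c, o in zip(v, d))
            while _inside(shape, w) and mask[w] and levels[w] == levels[v]:
                length += 1
                w = tuple(c + o for c, o in zip(w, d))
            runs.append((levels[v], length))
    rmax = max(l for _, l in runs)
    mat = np.zeros((n_bins, rmax))
    for lv, l in runs:
        mat[lv - 1, l - 1] += 1
    return mat


def ref_glszm(levels: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Zones by explicit 26-connected flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for v in map(tuple, np.argwhere(mask)):
        if seen[v]:
            continue
        lv = levels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for d in NEIGHBORS_26:
                w = tuple(c + o for c, o in zip(u, d))
                if _inside(shape, w) and mask[w] and not seen[w] and levels[w] == lv:
                    seen[w] = True
                    stack.append(w)
        zones.append((lv, size))
    smax = max(s for _, s in zones)
    mat = np.zeros((n_bins, smax))
    for lv, s in zones:
        mat[lv - 1, s - 1] += 1
    return mat


def ref_emphasis(mat: np.ndarray, n_voxels: int, n_directions: int, names: list[str]):
    total = mat.sum()
    vals = dict.fromkeys(names, 0.0)
    sre = lre = lgre = hgre = srlge = srhge = lrlge = lrhge = 0.0
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            c = mat[i, j]
            if c == 0:
                continue
            gi, rj = i + 1.0, j + 1.0
            sre += c / rj**2
            lre += c * rj**2
            lgre += c / gi**2
            hgre += c * gi**2
            srlge += c / (gi**2 * rj**2)
            srhge += c * gi**2 / rj**2
            lrlge += c * rj**2 / gi**2
            lrhge += c * gi**2 * rj**2
    gln = sum(mat[i, :].sum() ** 2 for i in range(mat.shape[0]))
    rln = sum(mat[:, j].sum() ** 2 for j in range(mat.shape[1]))
    raw = [sre, lre, lgre, hgre, srlge, srhge, lrlge, lrhge, gln, rln]
    for name, val in zip(names[:10], raw):
        vals[name] = val / total
    vals[names[10]] = total / (n_directions * n_voxels)
    return vals


GLRLM_NAMES = [
    "Short-Run Emphasis", "Long-Run Emphasis",
    "Low Gray-Level Run Emphasis", "High Gray-Level Run Emphasis",
    "Short-Run Low Gray-Level Emphasis", "Short-Run High Gray-Level Emphasis",
    "Long-Run Low Gray-Level Emphasis", "Long-Run High Gray-Level Emphasis",
    "Gray-Level Non-Uniformity (GLRLM)", "Run-Length Non-Uniformity", "Run Percentage",
]
GLSZM_NAMES = [
    "Short-Zone Emphasis", "Long-Zone Emphasis",
    "Low Gray-Level Zone Emphasis", "High Gray-Level Zone Emphasis",
    "Short-Zone Low Gray-Level Emphasis", "Short-Zone High Gray-Level Emphasis",
    "Long-Zone Low Gray-Level Emphasis", "Long-Zone High Gray-Level Emphasis",
    "Gray-Level Non-Uniformity (GLSZM)", "Zone Length Non-Uniformity", "Zone Percentage",
]


def ref_max_diameter(mask: np.ndarray, spacing) -> float:
    pts = [tuple(c * s for c, s in zip(v, spacing)) for v in np.argwhere(mask)]
    best = 0.0
    for a, b in itertools.combinations(pts, 2):
        d = math.dist(a, b)
        if d > best:
            best = d
    return best


def ref_primary(values: np.ndarray, mask: np.ndarray, levels: np.ndarray, n_bins: int,
                spacing, glszm: np.ndarray) -> dict[str, float]:
    vals = [float(values[tuple(v)]) for v in np.argwhere(mask)]
    n = len(vals)
    mean = sum(vals) / n
    var = sum((x - mean) ** 2 for x in vals) / n
    counts = [0] * n_bins
    for v in map(tuple, np.argwhere(mask)):
        counts[levels[v] - 1] += 1
    entropy = -sum((c / n) * math.log2(c / n) for c in counts if c > 0)
    zone_sizes = []
    for i in range(glszm.shape[0]):
        for j in range(glszm.shape[1]):
            zone_sizes.extend([j + 1] * int(round(glszm[i, j])))
    zmean = sum(zone_sizes) / len(zone_sizes)
    zvar = sum((z - zmean) ** 2 for z in zone_sizes) / len(zone_sizes)
    kurt = (sum((x - mean) ** 4 for x in vals) / n) / var**2 if var > 0 else float("nan")
    return {
        "Deviation": math.sqrt(var),
        "Mean": mean,
        "Max": max(vals),
        "Min": min(vals),
        "Sum": sum(vals),
        "Volume": n * spacing[0] * spacing[1] * spacing[2],
        "Max. Diameter": ref_max_diameter(mask, spacing),
        "Entropy": entropy,
        "Size Variance": zvar,
        "Intensity Variance": var,
        "Kurtosis": kurt,
    }


def ref_all_features(values: np.ndarray, mask: np.ndarray, n_bins: int, spacing,
                     distance: int = 1) -> dict[str, float]:
    """All 39 features via the brute-force paths above (merged directions)."""
    levels = ref_discretize(values, mask, n_bins)
    glszm = ref_glszm(levels, mask, n_bins)
    n_vox = int(mask.sum())
    out = {}
    out.update(ref_primary(values, mask, levels, n_bins, spacing, glszm))
    out.update(ref_glcm_features(ref_glcm(levels, mask, n_bins, distance)))
    out.update(ref_ngtdm(levels, mask, n_bins))
    out.update(ref_emphasis(ref_glrlm(levels, mask, n_bins), n_vox, len(DIRS_13), GLRLM_NAMES))
    out.update(ref_emphasis(glszm, n_vox, 1, GLSZM_NAMES))
    return out
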