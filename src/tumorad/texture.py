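"""3D radiomic texture features over a tumor volume of interest.

Implements the 39-feature panel used for longitudinal tumor phenotyping:

* 11 primary (histogram/morphometric) features — Deviation, Mean, Max, Min,
  Sum, Volume, Max. Diameter, Entropy, Size Variance, Intensity Variance,
  Kurtosis;
* 6 higher-order features from the gray-level co-occurrence matrix block —
  Homogeneity, Correlation, Contrast, plus Coarseness, Busyness and
  Complexity (the latter three via the neighbourhood gray-tone difference
  matrix, their canonical definition);
* 11 gray-level run-length matrix (GLRLM) features ending in Run Percentage;
* 11 gray-level size-zone matrix (GLSZM) features ending in Zone Percentage.

Intensities are first discretized to ``n_bins`` equal-width gray levels over
the in-mask min–max range.  GLCM and GLRLM aggregate the 13 unique 3D
directions at a configurable voxel distance (merged-matrix convention by
default); GLSZM zones are maximal 26-connected components of equal level.
Runs, co-occurrences and zones are defined on the voxel grid irrespective of
physical anisotropy; Volume and Max. Diameter use physical spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .volumes import ImageVolume, VOIMask, check_aligned
from .volumetry import voi_volume

__all__ = [
    "DiscretizedVOI",
    "TextureMatrices",
    "TextureParams",
    "FEATURE_NAMES",
    "discretize",
    "build_glcm",
    "glcm_features",
    "ngtdm_features",
    "build_glrlm",
    "glrlm_features",
    "build_glszm",
    "glszm_features",
    "primary_features",
    "extract_all",
]

log = logging.getLogger(__name__)

#: The 13 unique 3D direction offsets (each with its negation covers all 26).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

#: Canonical order and naming of the 39-feature panel.
PRIMARY_NAMES = (
    "Deviation", "Mean", "Max", "Min", "Sum", "Volume", "Max. Diameter",
    "Entropy", "Size Variance", "Intensity Variance", "Kurtosis",
)
GLCM_BLOCK_NAMES = (
    "Homogeneity", "Correlation", "Contrast", "Coarseness", "Busyness", "Complexity",
)
GLRLM_NAMES = (
    "Short-Run Emphasis", "Long-Run Emphasis",
    "Low Gray-Level Run Emphasis", "High Gray-Level Run Emphasis",
    "Short-Run Low Gray-Level Emphasis", "Short-Run High Gray-Level Emphasis",
    "Long-Run Low Gray-Level Emphasis", "Long-Run High Gray-Level Emphasis",
    "Gray-Level Non-Uniformity (GLRLM)", "Run-Length Non-Uniformity",
    "Run Percentage",
)
GLSZM_NAMES = (
    "Short-Zone Emphasis", "Long-Zone Emphasis",
    "Low Gray-Level Zone Emphasis", "High Gray-Level Zone Emphasis",
    "Short-Zone Low Gray-Level Emphasis", "Short-Zone High Gray-Level Emphasis",
    "Long-Zone Low Gray-Level Emphasis", "Long-Zone High Gray-Level Emphasis",
    "Gray-Level Non-Uniformity (GLSZM)", "Zone Length Non-Uniformity",
    "Zone Percentage",
)
FEATURE_NAMES: tuple[str, ...] = PRIMARY_NAMES + GLCM_BLOCK_NAMES + GLRLM_NAMES + GLSZM_NAMES
assert len(FEATURE_NAMES) == 39

_NGTDM_EPS = 1e-6  # guard on the Coarseness denominator


class DegenerateVOIError(ValueError):
    """VOI too small / structureless for the requested texture matrix."""


@dataclass
class TextureParams:
    """Discretization and matrix-construction parameters.

    n_bins: gray levels for equal-width discretization (vendor default
        unpublished; 32 is the package default and is recorded in outputs).
    distance: co-occurrence offset length in voxels.
    connectivity: zone connectivity (26 = faces+edges+corners).
    direction_mode: 'merged' sums counts over the 13 directions before
        feature computation; 'average' computes per-direction features and
        averages them.
    """

    n_bins: int = 32
    distance: int = 1
    connectivity: int = 26
    direction_mode: str = "merged"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.distance < 1:
            raise ValueError(f"distance must be >= 1, got {self.distance}")
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if self.direction_mode not in ("merged", "average"):
            raise ValueError(f"direction_mode must be 'merged' or 'average', got {self.direction_mode!r}")


@dataclass(eq=False)
class DiscretizedVOI:
    """Gray-level grid restricted to the mask (levels 1..Ng, 0 outside)."""

    levels: np.ndarray  # int array, 0 = outside mask
    mask: np.ndarray  # bool
    n_bins: int
    vmin: float
    vmax: float
    voxel_spacing: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(eq=False)
class TextureMatrices:
    glcm: np.ndarray  # Ng x Ng probabilities (merged, symmetric)
    glrlm: np.ndarray  # Ng x Rmax counts (merged over directions)
    glszm: np.ndarray  # Ng x Smax counts
    n_directions: int
    params: TextureParams = field(default_factory=TextureParams)


def discretize(image: ImageVolume, mask: VOIMask, n_bins: int = 32) -> DiscretizedVOI:
    """Equal-width gray-level discretization of in-mask intensities.

    Levels span 1..n_bins over the in-mask [min, max] range; a constant
    region maps entirely to level 1.  Out-of-mask voxels carry level 0 and
    are excluded from every texture matrix.
    """
    check_aligned(image, mask)
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    m = mask.data
    if not m.any():
        raise ValueError("empty mask: nothing to discretize")
    vals = image.data[m]
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(image.shape, dtype=np.int32)
    if vmax > vmin:
        width = (vmax - vmin) / n_bins
        lv = np.floor((image.data[m] - vmin) / width).astype(np.int32) + 1
        np.clip(lv, 1, n_bins, out=lv)
        levels[m] = lv
    else:
        levels[m] = 1
    return DiscretizedVOI(
        levels=levels, mask=m, n_bins=n_bins, vmin=vmin, vmax=vmax,
        voxel_spacing=mask.spacing,
    )


def _shifted_pairs(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int, int]):
    """In-mask (level_a, level_b) pairs at +offset, as two flat arrays."""
    sl_a, sl_b = [], []
    for n, o in zip(levels.shape, offset):
        if abs(o) >= n:
            return None, None
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    valid = mask[sl_a] & mask[sl_b]
    return levels[sl_a][valid], levels[sl_b][valid]


def _glcm_counts_one(d: DiscretizedVOI, offset: tuple[int, int, int]) -> np.ndarray:
    ng = d.n_bins
    counts = np.zeros((ng, ng), dtype=np.float64)
    a, b = _shifted_pairs(d.levels, d.mask, offset)
    if a is not None and a.size:
        idx = (a - 1) * ng + (b - 1)
        flat = np.bincount(idx, minlength=ng * ng).astype(np.float64).reshape(ng, ng)
        counts += flat + flat.T  # symmetric: count each pair in both orders
    return counts


def build_glcm(
    d: DiscretizedVOI,
    distance: int = 1,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> np.ndarray:
    """Normalized symmetric GLCM merged over the given 3D directions."""
    if distance < 1:
        raise ValueError(f"distance must be >= 1, got {distance}")
    counts = np.zeros((d.n_bins, d.n_bins), dtype=np.float64)
    for direction in directions:
        off = tuple(distance * c for c in direction)
        counts += _glcm_counts_one(d, off)  # type: ignore[arg-type]
    total = counts.sum()
    if total == 0:
        raise DegenerateVOIError(
            "degenerate VOI: no in-mask voxel pair at the requested offsets"
        )
    return counts / total


def glcm_features(glcm: np.ndarray) -> dict[str, float]:
    """Homogeneity (inverse difference), Correlation and Contrast of a GLCM."""
    glcm = np.asarray(glcm, dtype=np.float64)
    if glcm.ndim != 2 or glcm.shape[0] != glcm.shape[1]:
        raise ValueError(f"GLCM must be square, got shape {glcm.shape}")
    if not np.isclose(glcm.sum(), 1.0, atol=1e-8):
        raise ValueError(f"GLCM must be normalized to probabilities (sum={glcm.sum():.6g})")
    ng = glcm.shape[0]
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ng + 1)[None, :]
    diff = i - j
    contrast = float((glcm * diff**2).sum())
    homogeneity = float((glcm / (1.0 + np.abs(diff))).sum())
    px = glcm.sum(axis=1)
    mu_x = float((np.arange(1, ng + 1) * px).sum())
    var_x = float(((np.arange(1, ng + 1) - mu_x) ** 2 * px).sum())
    # symmetric GLCM: both marginals identical
    if var_x <= 0:
        correlation = float("nan")
    else:
        e_ij = float((glcm * i * j).sum())
        correlation = (e_ij - mu_x * mu_x) / var_x
    return {"Homogeneity": homogeneity, "Correlation": correlation, "Contrast": contrast}


def _ngtdm_table(d: DiscretizedVOI) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level occurrence probabilities p_i and difference sums s_i.

    Neighbourhoods are the 26 adjacent voxels; only in-mask neighbours enter
    the average, and only in-mask voxels with at least one in-mask neighbour
    are counted.
    """
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    m = d.mask.astype(np.float64)
    nbr_sum = ndimage.convolve(d.levels * m, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(m, kernel, mode="constant", cval=0.0)
    valid = d.mask & (nbr_cnt > 0)
    n_valid = int(valid.sum())
    if n_valid < 2:
        raise DegenerateVOIError("degenerate VOI: fewer than 2 voxels with in-mask neighbours")
    avg = np.zeros_like(nbr_sum)
    avg[valid] = nbr_sum[valid] / nbr_cnt[valid]
    lv = d.levels[valid]
    absdiff = np.abs(lv - avg[valid])
    ng = d.n_bins
    n_i = np.bincount(lv - 1, minlength=ng).astype(np.float64)
    s_i = np.bincount(lv - 1, weights=absdiff, minlength=ng)
    return n_i / n_valid, s_i, n_valid


def ngtdm_features(d: DiscretizedVOI) -> dict[str, float]:
    """Coarseness, Busyness and Complexity from the NGTDM."""
    p, s, n_valid = _ngtdm_table(d)
    i = np.arange(1, d.n_bins + 1, dtype=np.float64)
    present = p > 0
    coarseness = 1.0 / (_NGTDM_EPS + float((p * s).sum()))
    ip = i * p
    pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
    ipi, ipj = np.meshgrid(ip[present], ip[present], indexing="ij")
    denom = float(np.abs(ipi - ipj).sum())
    busyness = float((p * s).sum()) / denom if denom > 0 else 0.0
    ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
    si, sj = np.meshgrid(s[present], s[present], indexing="ij")
    complexity = float(
        (np.abs(ii - jj) * (pi * si + pj * sj) / (n_valid * (pi + pj))).sum()
    )
    return {"Coarseness": coarseness, "Busyness": busyness, "Complexity": complexity}


def _run_lengths_one(d: DiscretizedVOI, direction: tuple[int, int, int]):
    """(level, run_length) arrays of maximal runs along one direction."""
    lv, m = d.levels, d.mask

    def shift(arr, off, fill=0):
        # result[v] = arr[v + off], out-of-grid -> fill
        out = np.full_like(arr, fill)
        src, dst = [], []
        for n, o in zip(arr.shape, off):
            if abs(o) >= n:
                return out
            if o >= 0:
                src.append(slice(o, n))
                dst.append(slice(0, n - o))
            else:
                src.append(slice(0, n + o))
                dst.append(slice(-o, n))
        out[tuple(dst)] = arr[tuple(src)]
        return out

    nxt_lv = shift(lv, direction)
    nxt_m = shift(m.astype(np.int32), direction).astype(bool)
    cont = m & nxt_m & (lv == nxt_lv)  # run continues one step in +direction
    # streak[v] = number of consecutive continuation steps starting at v
    streak = np.zeros(lv.shape, dtype=np.int32)
    while True:
        new = np.where(cont, 1 + shift(streak, direction), 0).astype(np.int32)
        if np.array_equal(new, streak):
            break
        streak = new
    neg = tuple(-c for c in direction)
    prev_cont = shift(cont.astype(np.int32), neg).astype(bool)
    starts = m & ~prev_cont
    return lv[starts], 1 + streak[starts]


def build_glrlm(
    d: DiscretizedVOI,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> np.ndarray:
    """GLRLM: counts of maximal equal-level runs, merged over directions.

    Rows are gray levels 1..Ng, columns run lengths 1..Rmax.  Runs truncate
    at the mask boundary; per direction, sum(length × count) equals the
    in-mask voxel count.
    """
    if d.n_voxels == 0:
        raise DegenerateVOIError("empty mask")
    all_lv, all_rl = [], []
    for direction in directions:
        lv, rl = _run_lengths_one(d, direction)
        all_lv.append(lv)
        all_rl.append(rl)
    lv = np.concatenate(all_lv)
    rl = np.concatenate(all_rl)
    rmax = int(rl.max())
    mat = np.zeros((d.n_bins, rmax), dtype=np.float64)
    np.add.at(mat, (lv - 1, rl - 1), 1.0)
    return mat


def _emphasis_features(
    mat: np.ndarray, n_voxels: int, n_directions: int, zone: bool
) -> dict[str, float]:
    """Shared run/zone emphasis formulas; `zone` switches the naming."""
    mat = np.asarray(mat, dtype=np.float64)
    total = mat.sum()
    if mat.size == 0 or total == 0:
        raise ValueError("empty run/zone matrix")
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, mat.shape[1] + 1, dtype=np.float64)[None, :]
    sre = float((mat / j**2).sum() / total)
    lre = float((mat * j**2).sum() / total)
    lgre = float((mat / i**2).sum() / total)
    hgre = float((mat * i**2).sum() / total)
    srlge = float((mat / (i**2 * j**2)).sum() / total)
    srhge = float((mat * i**2 / j**2).sum() / total)
    lrlge = float((mat * j**2 / i**2).sum() / total)
    lrhge = float((mat * i**2 * j**2).sum() / total)
    gln = float((mat.sum(axis=1) ** 2).sum() / total)
    rln = float((mat.sum(axis=0) ** 2).sum() / total)
    pct = float(total / (n_directions * n_voxels))
    names = GLSZM_NAMES if zone else GLRLM_NAMES
    vals = (sre, lre, lgre, hgre, srlge, srhge, lrlge, lrhge, gln, rln, pct)
    return dict(zip(names, vals))


def glrlm_features(glrlm: np.ndarray, n_voxels: int, n_directions: int = 13) -> dict[str, float]:
    """The 11 run-length features (… Run Percentage).

    With the merged-matrix convention Run Percentage is
    total_runs / (n_directions × n_voxels), which stays in (0, 1] and
    reduces to runs/voxels for a single direction.
    """
    return _emphasis_features(glrlm, n_voxels, n_directions, zone=False)


def build_glszm(d: DiscretizedVOI, connectivity: int = 26) -> np.ndarray:
    """GLSZM: zones = maximal connected components of equal level in the mask."""
    if d.n_voxels == 0:
        raise DegenerateVOIError("empty mask")
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    sizes_per_level: list[np.ndarray] = []
    present = np.unique(d.levels[d.mask])
    zone_entries = []  # (level, size)
    for lv in present:
        lab, n = ndimage.label(d.levels == lv, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            for s in sizes:
                zone_entries.append((int(lv), int(s)))
    smax = max(s for _, s in zone_entries)
    mat = np.zeros((d.n_bins, smax), dtype=np.float64)
    for lv, s in zone_entries:
        mat[lv - 1, s - 1] += 1.0
    return mat


def glszm_features(glszm: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 11 size-zone features (… Zone Percentage = zones / voxels)."""
    return _emphasis_features(glszm, n_voxels, 1, zone=True)


def _zone_sizes(glszm: np.ndarray) -> np.ndarray:
    """Expand a GLSZM into the flat array of zone sizes it counts."""
    sizes = []
    counts = glszm.sum(axis=0)
    for sz, c in enumerate(counts, start=1):
        sizes.extend([sz] * int(round(c)))
    return np.asarray(sizes, dtype=np.float64)


def max_diameter(mask: VOIMask) -> float:
    """Maximum pairwise Euclidean distance between in-mask voxel centers (mm).

    Computed over surface voxels only (interior voxels cannot realize the
    maximum); exact, with a convex-hull reduction for large surfaces.
    """
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    if m.sum() == 1:
        return 0.0
    surface = m & ~ndimage.binary_erosion(m, ndimage.generate_binary_structure(3, 1))
    pts = np.argwhere(surface).astype(np.float64) * np.asarray(mask.spacing)
    if len(pts) > 1500:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (e.g. coplanar) surface: fall through to exact pdist
    if len(pts) == 1:
        return 0.0
    return float(pdist(pts).max())


def primary_features(
    image: ImageVolume,
    mask: VOIMask,
    d: DiscretizedVOI,
    glszm: np.ndarray | None = None,
) -> dict[str, float]:
    """The 11 primary histogram / morphometric features.

    Deviation and Intensity Variance are population moments of the raw
    in-mask intensities; Entropy is Shannon entropy (bits) of the
    discretized-level histogram; Size Variance is the population variance
    of GLSZM zone sizes; Kurtosis is the Pearson (non-excess) standardized
    fourth moment, NaN for a zero-variance VOI.
    """
    check_aligned(image, mask)
    vals = image.data[mask.data]
    if vals.size == 0:
        raise ValueError("empty mask")
    mean = float(vals.mean())
    var = float(vals.var())
    sd = float(np.sqrt(var))
    counts = np.bincount(d.levels[d.mask] - 1, minlength=d.n_bins).astype(np.float64)
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    if glszm is None:
        glszm = build_glszm(d)
    zs = _zone_sizes(glszm)
    size_var = float(zs.var()) if zs.size else float("nan")
    if var > 0:
        kurt = float(np.mean((vals - mean) ** 4) / var**2)
    else:
        kurt = float("nan")
    return {
        "Deviation": sd,
        "Mean": mean,
        "Max": float(vals.max()),
        "Min": float(vals.min()),
        "Sum": float(vals.sum()),
        "Volume": voi_volume(mask),
        "Max. Diameter": max_diameter(mask),
        "Entropy": entropy,
        "Size Variance": size_var,
        "Intensity Variance": var,
        "Kurtosis": kurt,
    }


def _averaged_glcm_features(d: DiscretizedVOI, distance: int) -> dict[str, float]:
    per_dir = []
    for direction in DIRECTIONS_13:
        try:
            g = build_glcm(d, distance=distance, directions=(direction,))
        except DegenerateVOIError:
            continue
        per_dir.append(glcm_features(g))
    if not per_dir:
        raise DegenerateVOIError("no direction produced a valid GLCM")
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def _averaged_glrlm_features(d: DiscretizedVOI) -> dict[str, float]:
    per_dir = []
    for direction in DIRECTIONS_13:
        m = build_glrlm(d, directions=(direction,))
        per_dir.append(glrlm_features(m, d.n_voxels, n_directions=1))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def extract_all(
    image: ImageVolume,
    mask: VOIMask,
    params: TextureParams | None = None,
) -> pd.Series:
    """Extract the full 39-feature panel for one (image, mask) pair.

    Returns a :class:`pandas.Series` indexed by the canonical feature names
    (:data:`FEATURE_NAMES`), deterministic for fixed inputs.  Non-finite
    values (e.g. Correlation of a constant VOI) are carried as NaN, never
    dropped; downstream statistics handle them pairwise.
    """
    params = params or TextureParams()
    check_aligned(image, mask)
    d = discretize(image, mask, n_bins=params.n_bins)
    glszm = build_glszm(d, connectivity=params.connectivity)
    out: dict[str, float] = {}
    out.update(primary_features(image, mask, d, glszm=glszm))
    if params.direction_mode == "average":
        out.update(_averaged_glcm_features(d, params.distance))
        out.update(ngtdm_features(d))
        out.update(_averaged_glrlm_features(d))
    else:
        glcm = build_glcm(d, distance=params.distance)
        out.update(glcm_features(glcm))
        out.update(ngtdm_features(d))
        glrlm = build_glrlm(d)
        out.update(glrlm_features(glrlm, d.n_voxels, n_directions=len(DIRECTIONS_13)))
    out.update(glszm_features(glszm, d.n_voxels))
    vec = pd.Series({name: out[name] for name in FEATURE_NAMES}, dtype=float)
    n_nonfinite = int((~np.isfinite(vec.to_numpy())).sum())
    if n_nonfinite:
        log.info("feature vector carries %d non-finite value(s), flagged as NaN", n_nonfinite)
    return vec
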