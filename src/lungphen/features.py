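"""Lattice-based 3-D radiomic texture features.

The lung field is tiled with non-overlapping cubic windows of edge length
``W`` millimetres.  Within each window that is sufficiently covered by the
lung mask, a 26-element feature vector is computed from three families:

* 6 gray-level histogram (first-order) features,
* 9 gray-level co-occurrence matrix (GLCM / Haralick) features, and
* 11 gray-level run-length matrix (GLRLM, Galloway/Chu) features.

Per-window vectors are averaged over the feature map to yield one
per-scan descriptor per window size.  HU values are quantized to a fixed
number of gray levels over a fixed HU range so that levels are comparable
across windows, scans and kernels.  Co-occurrence and run-length counts
are accumulated over all 13 unique 3-D directions into a single matrix
before features are computed; pairs and runs never cross the lung-mask or
window boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .volume import CtVolume, LungMask

HISTOGRAM_FEATURES = [
    "hist_mean",
    "hist_variance",
    "hist_skewness",
    "hist_kurtosis",
    "hist_entropy",
    "hist_uniformity",
]
GLCM_FEATURES = [
    "glcm_contrast",
    "glcm_correlation",
    "glcm_energy",
    "glcm_homogeneity",
    "glcm_entropy",
    "glcm_dissimilarity",
    "glcm_cluster_shade",
    "glcm_cluster_prominence",
    "glcm_max_probability",
]
GLRLM_FEATURES = [
    "glrlm_sre",
    "glrlm_lre",
    "glrlm_gln",
    "glrlm_rln",
    "glrlm_rp",
    "glrlm_lgre",
    "glrlm_hgre",
    "glrlm_srlge",
    "glrlm_srhge",
    "glrlm_lrlge",
    "glrlm_lrhge",
]

#: The 26 per-scan radiomic feature names, in canonical order.
FEATURE_NAMES: list[str] = HISTOGRAM_FEATURES + GLCM_FEATURES + GLRLM_FEATURES

N_FEATURES = len(FEATURE_NAMES)

# The 13 unique direction vectors of the 26-neighbourhood (one per
# antipodal pair); symmetry adds the opposite offsets implicitly.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)


@dataclass
class LatticeSpec:
    """Configuration of the lattice extraction.

    Parameters
    ----------
    window_mm : float
        Window edge length W in mm (the analysis uses 4, 8 and 20 mm).
    min_occupancy : float
        Minimum in-mask voxel fraction for a window to be evaluated.
    n_gray_levels : int
        Number of equal-width quantization levels.
    hu_clip : (float, float)
        Fixed HU range for quantization; values outside are clamped.
    glcm_distance : int
        Neighbour offset in voxels for co-occurrence pairs.
    """

    window_mm: float = 8.0
    min_occupancy: float = 0.5
    n_gray_levels: int = 32
    hu_clip: tuple[float, float] = (-1024.0, 200.0)
    glcm_distance: int = 1

    def __post_init__(self) -> None:
        if self.window_mm <= 0:
            raise ValueError("window_mm must be positive")
        if not 0 < self.min_occupancy <= 1:
            raise ValueError("min_occupancy must be in (0, 1]")
        if self.n_gray_levels < 2:
            raise ValueError("n_gray_levels must be >= 2")
        if not self.hu_clip[0] < self.hu_clip[1]:
            raise ValueError("hu_clip lower bound must be below upper bound")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")


@dataclass
class FeatureVector:
    """Per-scan 26-element radiomic descriptor for one window size."""

    values: dict[str, float]
    window_mm: float
    scan_id: str = ""
    kernel_label: str = ""
    n_windows_used: int = 0

    def __post_init__(self) -> None:
        if set(self.values) != set(FEATURE_NAMES):
            raise ValueError("FeatureVector must contain exactly the 26 canonical features")
        arr = np.array([self.values[k] for k in FEATURE_NAMES], dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = [k for k in FEATURE_NAMES if not np.isfinite(self.values[k])]
            raise ValueError(f"non-finite feature values: {bad}")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES], dtype=float)


def quantize(values: np.ndarray, spec: LatticeSpec) -> np.ndarray:
    """Quantize HU values to gray levels ``1..n`` over the fixed HU range.

    The range is ``spec.hu_clip`` for every window and scan — not the
    window's own min/max — so levels are comparable across the cohort.
    The upper clip bound maps to level ``n``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot quantize an empty value list")
    lo, hi = spec.hu_clip
    clipped = np.clip(values, lo, hi)
    levels = np.floor((clipped - lo) / (hi - lo) * spec.n_gray_levels).astype(np.int64) + 1
    np.clip(levels, 1, spec.n_gray_levels, out=levels)
    return levels


def histogram_features(window_values: np.ndarray, spec: LatticeSpec | None = None) -> dict[str, float]:
    """First-order statistics of the HU distribution within a window.

    Mean and variance (population), Fisher skewness and excess kurtosis
    are computed on raw HU; Shannon entropy (natural log) and uniformity
    (energy) on the quantized-level probabilities.  Zero-variance windows
    return skewness and kurtosis of 0 by convention.
    """
    if spec is None:
        spec = LatticeSpec()
    x = np.asarray(window_values, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    mean = float(x.mean())
    var = float(x.var())
    if var > 0:
        z = (x - mean) / np.sqrt(var)
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    levels = quantize(x, spec)
    counts = np.bincount(levels, minlength=spec.n_gray_levels + 1)[1:]
    p = counts[counts > 0] / x.size
    entropy = float(-np.sum(p * np.log(p)))
    uniformity = float(np.sum(p**2))
    return {
        "hist_mean": mean,
        "hist_variance": var,
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_entropy": entropy,
        "hist_uniformity": uniformity,
    }


def glcm_matrix(
    window_levels: np.ndarray,
    distance: int = 1,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix accumulated over directions.

    ``window_levels`` holds gray levels ``1..n`` with 0 marking voxels
    outside the lung mask; only pairs with both voxels in-mask count.
    Returns an ``(n+1, n+1)`` matrix indexed by level (row/col 0 unused),
    summing to 1, or all zeros if no valid pair exists.
    """
    lv = np.asarray(window_levels, dtype=np.int64)
    n = int(lv.max(initial=0))
    counts = np.zeros((n + 1, n + 1), dtype=np.float64)
    for dx, dy, dz in directions:
        off = (dx * distance, dy * distance, dz * distance)
        a, b = _shifted_pairs(lv, off)
        valid = (a > 0) & (b > 0)
        if valid.any():
            np.add.at(counts, (a[valid], b[valid]), 1.0)
    counts = counts + counts.T  # symmetrize (adds antipodal directions)
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts


def _shifted_pairs(lv: np.ndarray, off: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Flattened (source, neighbour) level arrays for one voxel offset."""
    slices_a, slices_b = [], []
    for size, o in zip(lv.shape, off):
        if abs(o) >= size:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        if o >= 0:
            slices_a.append(slice(0, size - o))
            slices_b.append(slice(o, size))
        else:
            slices_a.append(slice(-o, size))
            slices_b.append(slice(0, size + o))
    return lv[tuple(slices_a)].ravel(), lv[tuple(slices_b)].ravel()


def glcm_features(
    window_levels: np.ndarray,
    distance: int = 1,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> dict[str, float] | None:
    """Nine Haralick-style features from the direction-aggregated GLCM.

    Returns ``None`` when the window admits no valid in-mask voxel pair
    (the window is then skipped by the lattice).  Zero-variance matrices
    return correlation 0 by convention.
    """
    p = glcm_matrix(window_levels, distance, directions)
    if p.sum() == 0:
        return None
    n = p.shape[0] - 1
    i = np.arange(n + 1, dtype=float)
    pij = p
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float(np.sum(pij * (ii - jj) ** 2))
    dissim = float(np.sum(pij * np.abs(ii - jj)))
    asm = float(np.sum(pij**2))
    homog = float(np.sum(pij / (1.0 + (ii - jj) ** 2)))
    nz = pij[pij > 0]
    entropy = float(-np.sum(nz * np.log(nz)))
    maxp = float(pij.max())
    px = pij.sum(axis=1)
    mu_i = float(np.sum(i * px))
    var_i = float(np.sum((i - mu_i) ** 2 * px))
    # symmetric matrix: marginals coincide
    if var_i > 0:
        corr = float(np.sum(pij * (ii - mu_i) * (jj - mu_i)) / var_i)
    else:
        corr = 0.0
    shade = float(np.sum(pij * (ii + jj - 2 * mu_i) ** 3))
    prom = float(np.sum(pij * (ii + jj - 2 * mu_i) ** 4))
    return {
        "glcm_contrast": contrast,
        "glcm_correlation": corr,
        "glcm_energy": asm,
        "glcm_homogeneity": homog,
        "glcm_entropy": entropy,
        "glcm_dissimilarity": dissim,
        "glcm_cluster_shade": shade,
        "glcm_cluster_prominence": prom,
        "glcm_max_probability": maxp,
    }


def glrlm_matrix(
    window_levels: np.ndarray,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> tuple[np.ndarray, int]:
    """Run-length matrix accumulated over directions, plus the voxel total.

    A run is a maximal string of in-mask voxels with the same gray level
    along one direction; runs are broken by the window edge and by
    out-of-mask voxels (level 0).  Returns ``(R, n_p)`` where
    ``R[g, l]`` counts runs of level ``g`` and length ``l`` (row/col 0
    unused) and ``n_p`` is the in-mask voxel count per direction summed
    over directions (the run-percentage denominator).
    """
    lv = np.asarray(window_levels, dtype=np.int64)
    n = int(lv.max(initial=0))
    max_len = max(lv.shape) if lv.size else 0
    # diagonal rays can be longer than any single axis extent
    max_len = int(np.ceil(np.sqrt(3)) * max_len) + 1
    R = np.zeros((n + 1, max_len + 1), dtype=np.float64)
    in_mask = int((lv > 0).sum())
    shape = lv.shape
    for d in directions:
        for start in _ray_starts(shape, d):
            x, y, z = start
            run_level, run_len = 0, 0
            while 0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]:
                g = lv[x, y, z]
                if g == run_level:
                    run_len += 1
                else:
                    if run_level > 0:
                        R[run_level, run_len] += 1
                    run_level, run_len = g, 1
                x += d[0]
                y += d[1]
                z += d[2]
            if run_level > 0:
                R[run_level, run_len] += 1
    return R, in_mask * len(directions)


def _ray_starts(shape: tuple[int, ...], d: tuple[int, int, int]):
    """Start voxels of all rays crossing the window along direction d.

    A voxel starts a ray iff its predecessor along ``d`` falls outside
    the window, i.e. it lies on the entry face for some nonzero component.
    """
    start_mask = np.zeros(shape, dtype=bool)
    for axis, dd in enumerate(d):
        if dd == 1:
            sl = [slice(None)] * 3
            sl[axis] = slice(0, 1)
            start_mask[tuple(sl)] = True
        elif dd == -1:
            sl = [slice(None)] * 3
            sl[axis] = slice(shape[axis] - 1, shape[axis])
            start_mask[tuple(sl)] = True
    return [tuple(int(v) for v in c) for c in np.argwhere(start_mask)]


def glrlm_features(
    window_levels: np.ndarray,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> dict[str, float] | None:
    """Eleven Galloway/Chu run-length features from the aggregated GLRLM.

    SRE/LRE weight runs by inverse/direct squared length, GLN/RLN measure
    gray-level and run-length nonuniformity, RP is runs per voxel, and the
    four joint emphases weight by gray level and length together.
    """
    R, n_p = glrlm_matrix(window_levels, directions)
    n_r = R.sum()
    if n_r == 0 or n_p == 0:
        return None
    g = np.arange(R.shape[0], dtype=float)
    l = np.arange(R.shape[1], dtype=float)
    g2 = g**2
    l2 = l**2
    with np.errstate(divide="ignore"):
        inv_g2 = np.where(g > 0, 1.0 / np.maximum(g2, 1e-300), 0.0)
        inv_l2 = np.where(l > 0, 1.0 / np.maximum(l2, 1e-300), 0.0)
    row = R.sum(axis=1)  # per gray level
    col = R.sum(axis=0)  # per run length
    return {
        "glrlm_sre": float((col @ inv_l2) / n_r),
        "glrlm_lre": float((col @ l2) / n_r),
        "glrlm_gln": float((row**2).sum() / n_r),
        "glrlm_rln": float((col**2).sum() / n_r),
        "glrlm_rp": float(n_r / n_p),
        "glrlm_lgre": float((row @ inv_g2) / n_r),
        "glrlm_hgre": float((row @ g2) / n_r),
        "glrlm_srlge": float((inv_g2 @ R @ inv_l2) / n_r),
        "glrlm_srhge": float((g2 @ R @ inv_l2) / n_r),
        "glrlm_lrlge": float((inv_g2 @ R @ l2) / n_r),
        "glrlm_lrhge": float((g2 @ R @ l2) / n_r),
    }


def window_features(
    window_hu: np.ndarray,
    window_mask: np.ndarray,
    spec: LatticeSpec,
) -> dict[str, float] | None:
    """All 26 features for one window; ``None`` if the window is degenerate."""
    m = np.asarray(window_mask, dtype=bool)
    if not m.any():
        return None
    hu = np.asarray(window_hu, dtype=float)
    levels = np.zeros(hu.shape, dtype=np.int64)
    levels[m] = quantize(hu[m], spec)
    glcm = glcm_features(levels, spec.glcm_distance)
    glrlm = glrlm_features(levels)
    if glcm is None or glrlm is None:
        return None
    out = histogram_features(hu[m], spec)
    out.update(glcm)
    out.update(glrlm)
    return out


def lattice_extract(
    volume: CtVolume,
    mask: LungMask,
    spec: LatticeSpec,
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Evaluate the 26 features on every qualifying lattice window.

    Windows tile the mask's bounding box on a non-overlapping grid
    (stride = window edge).  The edge in voxels per axis is
    ``round(window_mm / spacing_axis)`` with a minimum of 1, so windows
    are cubic in mm, not necessarily in voxels.  A window is evaluated
    only if at least ``min_occupancy`` of its voxels are in-mask, and
    features use in-mask voxels only.

    Returns
    -------
    features : ndarray of shape (n_windows, 26)
    origins : list of window origin voxel coordinates
    """
    if mask.voxel_count == 0:
        raise ValueError(f"empty lung mask for scan {volume.scan_id!r}")
    edge = tuple(max(1, int(round(spec.window_mm / s))) for s in volume.spacing)
    nz = np.nonzero(mask.mask)
    lo = tuple(int(c.min()) for c in nz)
    hi = tuple(int(c.max()) + 1 for c in nz)
    rows: list[list[float]] = []
    origins: list[tuple[int, int, int]] = []
    for x0 in range(lo[0], hi[0], edge[0]):
        for y0 in range(lo[1], hi[1], edge[1]):
            for z0 in range(lo[2], hi[2], edge[2]):
                sl = (
                    slice(x0, min(x0 + edge[0], volume.shape[0])),
                    slice(y0, min(y0 + edge[1], volume.shape[1])),
                    slice(z0, min(z0 + edge[2], volume.shape[2])),
                )
                wm = mask.mask[sl]
                n_total = edge[0] * edge[1] * edge[2]
                if wm.sum() / n_total < spec.min_occupancy:
                    continue
                feats = window_features(volume.voxels[sl], wm, spec)
                if feats is None:
                    continue
                rows.append([feats[k] for k in FEATURE_NAMES])
                origins.append((x0, y0, z0))
    if not rows:
        raise ValueError(
            f"no valid lattice windows for scan {volume.scan_id!r} at W={spec.window_mm} mm"
        )
    return np.asarray(rows, dtype=float), origins


def aggregate_scan(
    window_vectors: np.ndarray,
    window_mm: float,
    scan_id: str = "",
    kernel_label: str = "",
) -> FeatureVector:
    """Unweighted mean over evaluated windows → one per-scan vector."""
    arr = np.asarray(window_vectors, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate zero windows")
    arr = arr.reshape(-1, N_FEATURES)
    mean = arr.mean(axis=0)
    return FeatureVector(
        values=dict(zip(FEATURE_NAMES, mean.tolist())),
        window_mm=window_mm,
        scan_id=scan_id,
        kernel_label=kernel_label,
        n_windows_used=arr.shape[0],
    )


class LatticeFeatureExtractor(BaseEstimator):
    """Scan-level lattice feature extraction as an estimator.

    A stateless transformer: :meth:`transform` maps a list of
    ``(CtVolume, LungMask)`` pairs to an ``(n_scans, 26)`` array of
    per-scan features at the configured window size.

    Parameters mirror :class:`LatticeSpec`.
    """

    def __init__(
        self,
        window_mm: float = 8.0,
        min_occupancy: float = 0.5,
        n_gray_levels: int = 32,
        hu_clip: tuple[float, float] = (-1024.0, 200.0),
        glcm_distance: int = 1,
    ) -> None:
        self.window_mm = window_mm
        self.min_occupancy = min_occupancy
        self.n_gray_levels = n_gray_levels
        self.hu_clip = hu_clip
        self.glcm_distance = glcm_distance

    def _spec(self) -> LatticeSpec:
        return LatticeSpec(
            window_mm=self.window_mm,
            min_occupancy=self.min_occupancy,
            n_gray_levels=self.n_gray_levels,
            hu_clip=tuple(self.hu_clip),
            glcm_distance=self.glcm_distance,
        )

    def fit(self, X=None, y=None) -> "LatticeFeatureExtractor":
        self.spec_ = self._spec()
        return self

    def extract_scan(self, volume: CtVolume, mask: LungMask, kernel_label: str = "") -> FeatureVector:
        spec = self._spec()
        windows, _ = lattice_extract(volume, mask, spec)
        return aggregate_scan(windows, spec.window_mm, scan_id=volume.scan_id, kernel_label=kernel_label)

    def transform(self, X: list[tuple[CtVolume, LungMask]]) -> np.ndarray:
        self.fit()
        return np.vstack([self.extract_scan(v, m).as_array() for v, m in X])
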