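"""Intensity-based 3-D lung-field segmentation.

The lung field is separated from soft tissue by 1-D K-means on voxel HU
(air/parenchyma attenuate far below soft tissue), exterior air is removed
as connected components touching the volume border, small spurious
components are dropped, the mask is morphologically closed, and bright
vessel-like voxels above a HU threshold are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .volume import CtVolume, LungMask


class NoLungFieldError(ValueError):
    """Raised when segmentation yields an empty mask."""


@dataclass
class SegmentationParams:
    """Tunables of the lung-field segmentation.

    ``vessel_hu_threshold`` (-300 HU default) excludes vessel-like bright
    voxels; ``min_component_fraction`` drops candidate components smaller
    than that fraction of the candidate set; ``closing_radius`` is the
    morphological closing radius in mm.  None of these are dictated by
    the underlying analysis — they are conventional lung-CT choices and
    all exposed here.
    """

    kmeans_k: int = 2
    vessel_hu_threshold: float = -300.0
    min_component_fraction: float = 0.01
    closing_radius: float = 2.0
    connectivity: int = 3  # ndimage rank connectivity: 3 => 26-neighbourhood

    def __post_init__(self) -> None:
        if self.kmeans_k < 2:
            raise ValueError("kmeans_k must be >= 2")
        if not np.isfinite(self.vessel_hu_threshold):
            raise ValueError("vessel_hu_threshold must be finite")


def _kmeans_1d(values: np.ndarray, k: int, tol: float = 1e-3, max_iter: int = 200) -> np.ndarray:
    """Deterministic 1-D Lloyd iteration with percentile initialization.

    Centers start at evenly spaced percentiles (10th and 90th for k=2),
    so the result does not depend on a random seed.
    """
    qs = np.linspace(10, 90, k)
    centers = np.percentile(values, qs).astype(float)
    for _ in range(max_iter):
        assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for j in range(k):
            sel = assign == j
            if sel.any():
                new[j] = values[sel].mean()
        if np.max(np.abs(new - centers)) < tol:
            centers = new
            break
        centers = new
    return centers


def _ellipsoid_structure(radius_vox: tuple[float, float, float]) -> np.ndarray:
    r = [max(1, int(round(rv))) for rv in radius_vox]
    grids = np.meshgrid(*[np.arange(-ri, ri + 1) for ri in r], indexing="ij")
    return sum((g / ri) ** 2 for g, ri in zip(grids, r)) <= 1.0


def segment_lung(volume: CtVolume, params: SegmentationParams | None = None) -> LungMask:
    """Segment the lung field of one CT volume.

    Steps: (1) K-means on HU; the lowest-center cluster is the air/lung
    candidate set; (2) 26-connected components touching the volume
    border are removed (exterior air); (3) components below
    ``min_component_fraction`` of the candidate set are dropped;
    (4) morphological closing; (5) voxels brighter than
    ``vessel_hu_threshold`` are excluded.

    Raises
    ------
    NoLungFieldError
        If no lung field survives, naming the scan.
    """
    if params is None:
        params = SegmentationParams()
    hu = volume.voxels
    centers = _kmeans_1d(hu.ravel(), params.kmeans_k)
    low = np.argmin(centers)
    assign = np.argmin(np.abs(hu[..., None] - centers[None, None, None, :]), axis=-1)
    candidate = assign == low
    n_candidate = int(candidate.sum())
    if n_candidate == 0:
        raise NoLungFieldError(f"no lung field found in scan {volume.scan_id!r}")

    structure = ndimage.generate_binary_structure(3, params.connectivity)
    labels, n_comp = ndimage.label(candidate, structure=structure)
    if n_comp == 0:
        raise NoLungFieldError(f"no lung field found in scan {volume.scan_id!r}")

    border_labels = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            border_labels.update(np.unique(labels[tuple(sl)]))
    border_labels.discard(0)

    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
    keep = np.zeros(n_comp + 1, dtype=bool)
    for lab in range(1, n_comp + 1):
        if lab in border_labels:
            continue
        if sizes[lab - 1] < params.min_component_fraction * n_candidate:
            continue
        keep[lab] = True
    mask = keep[labels]
    if not mask.any():
        raise NoLungFieldError(f"no lung field found in scan {volume.scan_id!r}")

    if params.closing_radius > 0:
        struct = _ellipsoid_structure(tuple(params.closing_radius / s for s in volume.spacing))
        mask = ndimage.binary_closing(mask, structure=struct)

    mask &= hu <= params.vessel_hu_threshold
    # the lung interior never includes the outer faces
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            mask[tuple(sl)] = False
    if not mask.any():
        raise NoLungFieldError(f"no lung field found in scan {volume.scan_id!r}")
    return LungMask(mask, scan_id=volume.scan_id)


class LungSegmenter(BaseEstimator):
    """Estimator-style wrapper over :func:`segment_lung`.

    Stateless; ``predict`` maps a list of volumes to masks.
    """

    def __init__(
        self,
        kmeans_k: int = 2,
        vessel_hu_threshold: float = -300.0,
        min_component_fraction: float = 0.01,
        closing_radius: float = 2.0,
        connectivity: int = 3,
    ) -> None:
        self.kmeans_k = kmeans_k
        self.vessel_hu_threshold = vessel_hu_threshold
        self.min_component_fraction = min_component_fraction
        self.closing_radius = closing_radius
        self.connectivity = connectivity

    def _params(self) -> SegmentationParams:
        return SegmentationParams(
            kmeans_k=self.kmeans_k,
            vessel_hu_threshold=self.vessel_hu_threshold,
            min_component_fraction=self.min_component_fraction,
            closing_radius=self.closing_radius,
            connectivity=self.connectivity,
        )

    def fit(self, X=None, y=None) -> "LungSegmenter":
        self.params_ = self._params()
        return self

    def predict(self, X: list[CtVolume]) -> list[LungMask]:
        params = self._params()
        return [segment_lung(v, params) for v in X]
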