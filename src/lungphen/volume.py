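"""Volumetric containers for CT data.

A :class:`CtVolume` is a 3-D scalar grid of Hounsfield units (HU) together
with its voxel spacing in millimetres; a :class:`LungMask` is the binary
lung-field mask on the same grid.  NIfTI round-trips go through nibabel,
with the spacing carried in the affine diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0


@dataclass
class CtVolume:
    """3-D CT volume in Hounsfield units.

    Parameters
    ----------
    voxels : ndarray of shape (nx, ny, nz)
        Scalar HU grid.  Values are clamped to ``[-1024, 3071]`` on
        construction, the representable HU range of 12-bit CT.
    spacing : tuple of float
        Voxel edge length in mm per axis; strictly positive.
    scan_id : str
        Identifier used in error messages and output tables.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        np.clip(self.voxels, HU_MIN, HU_MAX, out=self.voxels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class LungMask:
    """Binary lung-field mask aligned with a :class:`CtVolume`."""

    mask: np.ndarray
    scan_id: str = ""
    voxel_count: int = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3-D array")
        self.voxel_count = int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]


def _affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(volume: CtVolume, path: str) -> None:
    """Write a volume as NIfTI with spacing on the affine diagonal."""
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), _affine_from_spacing(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, path)


def load_volume(path: str, scan_id: str = "") -> CtVolume:
    """Read a NIfTI volume; HU values are clamped on load."""
    img = nib.load(path)
    zooms = img.header.get_zooms()[:3]
    return CtVolume(np.asanyarray(img.dataobj), tuple(float(z) for z in zooms), scan_id=scan_id)


def save_mask(mask: LungMask, spacing: tuple[float, float, float], path: str) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine_from_spacing(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, path)


def load_mask(path: str, scan_id: str = "") -> LungMask:
    img = nib.load(path)
    return LungMask(np.asanyarray(img.dataobj) > 0, scan_id=scan_id)
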