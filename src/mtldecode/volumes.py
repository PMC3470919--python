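"""Volume and ROI-mask data model with NIfTI I/O and Gaussian smoothing.

Voxel grids are indexed 0-based; world coordinates exist only through the
4x4 affine. 4-D arrays stack trials (or scans) on the *last* axis, in
trial-table row order. Masks are stored as uint8 NIfTI images where any
nonzero voxel is inside the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "ROIMask",
    "SmoothingSpec",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "gaussian_smooth",
    "fwhm_to_sigma",
]

#: conversion factor between FWHM and standard deviation of a Gaussian
_FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

ROI_NAMES = ("HC", "EC", "PHG")
HEMISPHERES = ("L", "R")


class VolumeFormatError(ValueError):
    """Raised when a file is not a readable NIfTI volume."""


class ConsistencyError(ValueError):
    """Raised when shapes/affines disagree within a dataset."""


@dataclass
class Volume:
    """A 3-D voxel grid, or a 4-D stack of grids (trials/scans last).

    Parameters
    ----------
    data
        Real-valued array, 3-D or 4-D.
    voxel_size_mm
        Edge lengths of a voxel in mm, strictly positive. Default 1.5 mm
        isotropic, the classifier resolution used throughout.
    affine
        4x4 voxel-to-world map. Defaults to a diagonal scaling by the
        voxel size.
    """

    data: np.ndarray
    voxel_size_mm: np.ndarray = field(default=None)  # type: ignore[assignment]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"volume must be 3-D or 4-D, got {self.data.ndim}-D")
        if self.voxel_size_mm is None:
            self.voxel_size_mm = np.array([1.5, 1.5, 1.5])
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        if self.voxel_size_mm.shape != (3,) or np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel_size_mm must be 3 strictly positive lengths")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size_mm, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    def check_compatible(self, other: "Volume | ROIMask") -> None:
        """Raise :class:`ConsistencyError` unless grids and affines match."""
        other_shape = other.grid_shape if isinstance(other, Volume) else other.mask.shape
        other_affine = other.affine
        if self.grid_shape != tuple(other_shape):
            raise ConsistencyError(
                f"grid shape mismatch: {self.grid_shape} vs {tuple(other_shape)}"
            )
        if not np.allclose(self.affine, other_affine):
            raise ConsistencyError("affine mismatch between volumes")


@dataclass
class ROIMask:
    """A named binary region-of-interest mask on the common voxel grid.

    ``name`` is one of HC (hippocampus), EC (entorhinal cortex) or PHG
    (parahippocampal gyrus); ``hemisphere`` is 'L' or 'R'.
    """

    name: str
    hemisphere: str
    mask: np.ndarray
    voxel_size_mm: np.ndarray = field(default=None)  # type: ignore[assignment]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.name not in ROI_NAMES:
            raise ValueError(f"ROI name must be one of {ROI_NAMES}, got {self.name!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.mask.any():
            raise ValueError("mask must contain at least one voxel")
        if self.voxel_size_mm is None:
            self.voxel_size_mm = np.array([1.5, 1.5, 1.5])
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size_mm, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def label(self) -> str:
        return f"{self.name}-{self.hemisphere}"

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def indices(self) -> np.ndarray:
        """(n_voxels, 3) integer coordinates of in-mask voxels, C order."""
        return np.argwhere(self.mask)


@dataclass(frozen=True)
class SmoothingSpec:
    """Isotropic Gaussian smoothing kernel width; 0 means identity."""

    fwhm_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be nonnegative")


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm: np.ndarray) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a given FWHM in mm."""
    return fwhm_mm * _FWHM_TO_SD / np.asarray(voxel_size_mm, dtype=float)


def gaussian_smooth(vol: Volume, spec: SmoothingSpec) -> Volume:
    """Smooth a 3-D volume with a separable Gaussian kernel.

    Boundaries are zero-padded; the kernel sigma per axis is
    ``fwhm / (2 sqrt(2 ln 2)) / voxel_size``. FWHM 0 returns the input
    data unchanged.
    """
    if not isinstance(spec, SmoothingSpec):
        spec = SmoothingSpec(float(spec))
    if vol.data.ndim != 3:
        raise ValueError("gaussian_smooth expects a 3-D volume")
    if spec.fwhm_mm == 0:
        return Volume(vol.data.copy(), vol.voxel_size_mm, vol.affine)
    sigma = fwhm_to_sigma(spec.fwhm_mm, vol.voxel_size_mm)
    # generous truncation: kernel tails matter for the Gaussian semigroup
    out = ndimage.gaussian_filter(vol.data, sigma=sigma, mode="constant",
                                  cval=0.0, truncate=8.0)
    return Volume(out, vol.voxel_size_mm, vol.affine)


def _voxel_size_from_affine(img: nib.Nifti1Image) -> np.ndarray:
    return np.asarray(img.header.get_zooms()[:3], dtype=float)


def read_volume(path) -> Volume:
    """Read a NIfTI-1 file into a :class:`Volume`."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"could not read NIfTI volume {path}: {exc}") from exc
    return Volume(data, _voxel_size_from_affine(img), np.asarray(img.affine))


def write_volume(vol: Volume, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    img.header.set_zooms((*vol.voxel_size_mm,) + ((1.0,) if vol.data.ndim == 4 else ()))
    nib.save(img, str(path))


def read_mask(path, name: str, hemisphere: str) -> ROIMask:
    """Read a uint8 NIfTI mask; nonzero voxels are inside the ROI."""
    vol = read_volume(path)
    if vol.data.ndim != 3:
        raise VolumeFormatError("mask file must be 3-D")
    return ROIMask(name, hemisphere, vol.data != 0, vol.voxel_size_mm, vol.affine)


def write_mask(mask: ROIMask, path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), mask.affine)
    img.header.set_zooms(tuple(mask.voxel_size_mm))
    nib.save(img, str(path))
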