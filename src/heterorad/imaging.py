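"""Volume / mask IO, ROI sampling, and intensity quantization.

Axis convention: arrays are indexed (x, y, z), fixed at read time; the z axis
is the slice (axial) direction.  Spacing is in millimetres.  Values are
assumed to already be in Hounsfield units — no rescale slope is applied.
Masks must be supplied on the image grid; there is no resampling stage, and
voxels outside the mask are excluded from every downstream computation.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .config import QuantizationProfile
from .errors import (
    AlignmentError,
    DegenerateRangeError,
    DimensionalityError,
    EmptyRoiError,
)

CHANNELS = ("non_contrast", "iodine")


@dataclass
class ImageVolume:
    """A 3D grid of HU values with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    channel: str = "non_contrast"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise DimensionalityError(
                f"expected a 3D scalar volume, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or not all(
            np.isfinite(s) and s > 0 for s in self.spacing
        ):
            raise ValueError(f"spacing must be three positive mm values: {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite HU values")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}: {self.channel!r}")


@dataclass
class RoiMask:
    """Binary tumor mask on the same grid as its paired volume."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data) != 0
        if self.data.ndim != 3:
            raise DimensionalityError(f"mask must be 3D, got shape {self.data.shape}")
        if not self.data.any():
            raise EmptyRoiError("mask has no foreground voxels")


@dataclass
class RoiSample:
    """HU values at the mask foreground, in lexicographic voxel order."""

    values: np.ndarray
    coords: np.ndarray  # (n, 3) integer voxel coordinates
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]  # grid shape the coords live on


@dataclass
class QuantizedRoi:
    """Integer level grid; 0 marks background, foreground levels are 1..n."""

    levels: np.ndarray
    n_levels: int
    bin_edges: np.ndarray


def _read_nifti(path: str):
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    # zooms are stored float32; round-trip through short repr to drop the
    # representation error (0.7 -> 0.699999988)
    return data, tuple(float(np.format_float_positional(z)) for z in zooms)


def _read_nrrd(path: str):
    import SimpleITK as sitk

    img = sitk.ReadImage(path)
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise DimensionalityError(f"{path}: vector image, expected scalar")
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.transpose(data, range(data.ndim)[::-1])  # back to (x, y, z)
    return data, tuple(float(s) for s in img.GetSpacing()[:3])


def read_volume(path: str, channel: str = "non_contrast") -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) scalar volume.

    Spacing is taken from the file header; HU values are returned unmodified.
    """
    if not os.path.exists(path):
        raise IOError(f"no such image file: {path}")
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        data, spacing = _read_nifti(path)
    elif lower.endswith(".nrrd"):
        data, spacing = _read_nrrd(path)
    else:
        raise IOError(f"unsupported image format (expect NIfTI or NRRD): {path}")
    data = np.squeeze(data)
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected 3D scalar image, got {data.ndim}D"
        )
    return ImageVolume(data=data, spacing=spacing, channel=channel)


def read_mask(path: str) -> RoiMask:
    """Read a mask volume; any nonzero voxel is foreground."""
    vol = read_volume(path)
    return RoiMask(data=vol.data != 0)


def extract_roi(volume: ImageVolume, mask: RoiMask) -> RoiSample:
    """Sample the HU values under the mask in deterministic voxel order."""
    if volume.data.shape != mask.data.shape:
        raise AlignmentError(
            f"mask shape {mask.data.shape} != volume shape {volume.data.shape}"
        )
    coords = np.argwhere(mask.data)  # lexicographic order from np.argwhere
    if coords.shape[0] == 0:
        raise EmptyRoiError("mask has no foreground voxels")
    values = volume.data[mask.data]
    return RoiSample(
        values=values,
        coords=coords,
        spacing=volume.spacing,
        shape=volume.data.shape,
    )


def quantize(
    roi: RoiSample,
    n_levels: int,
    hu_range: tuple[float, float] | None = None,
) -> QuantizedRoi:
    """Equal-width quantization of ROI intensities onto levels 1..n_levels.

    Level ``l`` covers HU in [edge_l, edge_{l+1}); the topmost bin is
    right-closed.  Values outside ``hu_range`` are clipped into it.  When
    ``hu_range`` is omitted the observed ROI min/max is used, which fails
    for a constant ROI (pass an explicit range in that case).
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    values = np.asarray(roi.values, dtype=float)
    if hu_range is None:
        lo, hi = float(values.min()), float(values.max())
        if lo == hi:
            raise DegenerateRangeError(
                "constant ROI: observed range is degenerate, pass hu_range"
            )
    else:
        lo, hi = float(hu_range[0]), float(hu_range[1])
        if not hi > lo:
            raise ValueError(f"hu_range must be increasing, got ({lo}, {hi})")
    edges = np.linspace(lo, hi, n_levels + 1)
    clipped = np.clip(values, lo, hi)
    width = (hi - lo) / n_levels
    lv = np.floor((clipped - lo) / width).astype(np.int64) + 1
    np.clip(lv, 1, n_levels, out=lv)
    levels = np.zeros(roi.shape, dtype=np.int64)
    levels[tuple(roi.coords.T)] = lv
    return QuantizedRoi(levels=levels, n_levels=int(n_levels), bin_edges=edges)


def quantize_with_profile(roi: RoiSample, profile: QuantizationProfile) -> QuantizedRoi:
    return quantize(roi, profile.n_levels, profile.hu_range)
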