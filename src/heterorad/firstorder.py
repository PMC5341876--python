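"""Physical and histogram features of a tumor ROI.

Physical features follow the CT mass convention: a voxel's physical density
in g/mL is (HU + 1000)/1000 (air -1000 HU -> 0, water 0 HU -> 1), floored at
zero; tumor mass is ROI volume times mean density.  Size is the largest
in-plane (axial) diameter between foreground voxel centers, the clinical
tumor-size measurement; a 3D maximum diameter is available via ``size_3d``.

Histogram features use non-excess kurtosis (normal = 3) and central moments
with 1/N normalization; percentiles use linear interpolation between order
statistics.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .errors import EmptyRoiError
from .imaging import RoiSample

log = logging.getLogger(__name__)


@dataclass
class PhysicalFeatures:
    volume_cm3: float
    density_gpml: float
    mass_g: float
    size_mm: float


@dataclass
class HistogramFeatures:
    skewness: float  # NaN when ROI variance is zero
    kurtosis: float  # non-excess; NaN when ROI variance is zero
    p2_5: float
    p25: float
    p50: float
    p75: float
    p97_5: float


def _max_pairwise(points: np.ndarray) -> float:
    if points.shape[0] < 2:
        return 0.0
    return float(pdist(points).max())


def compute_physical(roi: RoiSample, size_3d: bool = False) -> PhysicalFeatures:
    """Volume (cm3), mean density (g/mL), mass (g) and diameter (mm)."""
    values = np.asarray(roi.values, dtype=float)
    if values.size == 0:
        raise EmptyRoiError("empty ROI")
    dx, dy, dz = roi.spacing
    volume_cm3 = values.size * dx * dy * dz / 1000.0
    density = float(np.mean(np.maximum((values + 1000.0) / 1000.0, 0.0)))
    mass_g = volume_cm3 * density

    mm = roi.coords.astype(float) * np.array([dx, dy, dz])
    if size_3d:
        size_mm = _max_pairwise(mm)
    else:
        # max over axial slices of the in-plane diameter
        size_mm = 0.0
        for z in np.unique(roi.coords[:, 2]):
            inplane = mm[roi.coords[:, 2] == z, :2]
            size_mm = max(size_mm, _max_pairwise(inplane))
    if size_mm == 0.0:
        # single voxel (or a single voxel per slice): use the voxel footprint
        size_mm = float(max(dx, dy) if not size_3d else max(dx, dy, dz))
    return PhysicalFeatures(volume_cm3, density, mass_g, size_mm)


def compute_histogram_features(roi: RoiSample) -> HistogramFeatures:
    values = np.asarray(roi.values, dtype=float)
    if values.size == 0:
        raise EmptyRoiError("empty ROI")
    m = values.mean()
    d = values - m
    m2 = np.mean(d**2)
    if m2 == 0.0:
        log.warning("ROI variance is zero; skewness/kurtosis reported missing")
        skew = kurt = float("nan")
    else:
        skew = float(np.mean(d**3) / m2**1.5)
        kurt = float(np.mean(d**4) / m2**2)
    p = np.percentile(values, [2.5, 25, 50, 75, 97.5], method="linear")
    return HistogramFeatures(skew, kurt, *map(float, p))
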