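"""Regional features: gray-level size-zone matrix and histogram statistics.

A zone is a maximal 26-connected (configurable to 6) component of equal
quantized level inside the mask.  The size-zone matrix z(g, s) counts zones
of level g and size s voxels.

Of the four regional features, uniformity and entropy are first-order
statistics of a fine-binned HU histogram (their natural scale), while the
two variability features are the standard size-zone non-uniformities of the
zone matrix, each normalized by the zone count.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyRoiError
from .imaging import QuantizedRoi


@dataclass
class Glszm:
    z: np.ndarray  # rows: level 1..n_levels; columns: zone size 1..max_size
    n_zones: int

    @property
    def max_size(self) -> int:
        return self.z.shape[1]


_STRUCTS = {
    26: np.ones((3, 3, 3), dtype=bool),
    6: ndimage.generate_binary_structure(3, 1),
}


def build_glszm(qroi: QuantizedRoi, connectivity: int = 26) -> Glszm:
    """Label equal-level connected zones and tabulate them by level and size."""
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    structure = _STRUCTS[connectivity]
    levels = qroi.levels
    if not (levels > 0).any():
        raise EmptyRoiError("quantized ROI has no foreground voxels")
    zone_sizes: list[tuple[int, int]] = []  # (level, size)
    max_size = 1
    for g in range(1, qroi.n_levels + 1):
        binary = levels == g
        if not binary.any():
            continue
        labels, n = ndimage.label(binary, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        for s in sizes:
            zone_sizes.append((g, int(s)))
            max_size = max(max_size, int(s))
    z = np.zeros((qroi.n_levels, max_size), dtype=np.int64)
    for g, s in zone_sizes:
        z[g - 1, s - 1] += 1
    return Glszm(z=z, n_zones=int(z.sum()))


def histogram_statistics(values, n_bins: int, hu_range) -> tuple[float, float]:
    """(uniformity, entropy in bits) of the fine-binned HU histogram."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyRoiError("empty ROI")
    counts, _ = np.histogram(np.clip(values, *hu_range), bins=n_bins, range=hu_range)
    h = counts / counts.sum()
    h = h[h > 0]
    uniformity = float((h**2).sum())
    entropy = float(-(h * np.log2(h)).sum())
    return uniformity, entropy


def zone_variabilities(glszm: Glszm) -> tuple[float, float]:
    """(intensity_variability, size_zone_variability).

    Gray-level non-uniformity sum_g (sum_s z)^2 / n_zones and zone-size
    non-uniformity sum_s (sum_g z)^2 / n_zones; both equal 1 when every zone
    shares one level / one size, and grow with zone diversity.
    """
    z = glszm.z.astype(float)
    n = glszm.n_zones
    if n == 0:
        raise EmptyRoiError("zone matrix is empty")
    intensity = float((z.sum(axis=1) ** 2).sum() / n)
    size_zone = float((z.sum(axis=0) ** 2).sum() / n)
    return intensity, size_zone


def regional_features(
    hist_qroi: QuantizedRoi, glszm: Glszm
) -> tuple[float, float, float, float]:
    """(uniformity, entropy, intensity_variability, size_zone_variability).

    ``hist_qroi`` is the ROI quantized with the fine histogram profile (its
    level counts are the histogram); ``glszm`` is built from the coarse
    texture quantization.
    """
    lv = hist_qroi.levels[hist_qroi.levels > 0]
    counts = np.bincount(lv, minlength=hist_qroi.n_levels + 1)[1:]
    h = counts / counts.sum()
    h = h[h > 0]
    uniformity = float((h**2).sum())
    entropy = float(-(h * np.log2(h)).sum())
    intensity, size_zone = zone_variabilities(glszm)
    return uniformity, entropy, intensity, size_zone
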