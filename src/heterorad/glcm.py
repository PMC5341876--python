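"""3D gray-level co-occurrence matrices and local (Haralick-style) texture.

A GLCM is built per direction and per voxel distance d (1, 2, 3 voxels along
the offset vector, spacing ignored), over the 13 canonical non-collinear 3D
neighbor directions.  Pairs are counted symmetrically ((i,j) and (j,i)) among
voxels that are both inside the mask, then normalized to probabilities.

Twelve features are computed per matrix.  Conventions: entropy in bits
(log base 2, 0*log 0 = 0); contrast is the first-order difference moment
sum(|i-j| p) while inertia is the second-order moment sum((i-j)^2 p) — the
standard Haralick "contrast" — keeping the two columns distinct; homogeneity
is normalized (probabilities, hence in (0, 1]).  Per-distance values are the
unweighted mean over the directions that produced at least one pair.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import FeatureSetMissingError
from .imaging import QuantizedRoi

#: The 13 canonical non-collinear 3D neighbor directions (half of the 26).
DIRECTIONS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0),
    (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1),
)

FEATURE_NAMES = (
    "energy", "entropy", "correlation", "contrast", "variance", "sum_mean",
    "inertia", "cluster_shade", "cluster_tendency", "homogeneity",
    "maximum_probability", "inverse_variance",
)


@dataclass
class Glcm:
    p: np.ndarray  # n_levels x n_levels symmetric probabilities
    offset: tuple[int, int, int]
    n_pairs: int


def _offset_views(levels: np.ndarray, offset):
    src, dst = [], []
    for ax, o in enumerate(offset):
        n = levels.shape[ax]
        if abs(o) >= n:
            return None, None
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return levels[tuple(src)], levels[tuple(dst)]


def build_glcm(qroi: QuantizedRoi, direction, distance: int) -> Glcm:
    """Count co-occurrences at ``offset = distance * direction`` inside the mask."""
    direction = tuple(int(v) for v in direction)
    if direction not in DIRECTIONS:
        raise ValueError(f"direction {direction} is not one of the 13 canonical ones")
    if distance not in (1, 2, 3):
        raise ValueError(f"distance must be 1, 2 or 3, got {distance}")
    offset = tuple(distance * d for d in direction)
    n = qroi.n_levels
    a, b = _offset_views(qroi.levels, offset)
    if a is None:
        return Glcm(p=np.zeros((n, n)), offset=offset, n_pairs=0)
    valid = (a > 0) & (b > 0)
    i, j = a[valid] - 1, b[valid] - 1
    counts = np.bincount(i * n + j, minlength=n * n).reshape(n, n).astype(float)
    counts = counts + counts.T  # symmetrize: count (i,j) and (j,i)
    total = counts.sum()
    if total == 0:
        return Glcm(p=np.zeros((n, n)), offset=offset, n_pairs=0)
    return Glcm(p=counts / total, offset=offset, n_pairs=int(total))


def glcm_features(glcm: Glcm) -> dict[str, float]:
    """Evaluate the 12 local texture statistics on one co-occurrence matrix."""
    if glcm.n_pairs == 0:
        raise ValueError("empty GLCM (n_pairs == 0); caller should skip it")
    p = glcm.p
    n = p.shape[0]
    lv = np.arange(1, n + 1, dtype=float)
    i = lv[:, None]
    j = lv[None, :]
    px = p.sum(axis=1)  # marginal (symmetric, px == py)
    mu_x = float(px @ lv)
    mu_y = mu_x
    var_x = float(px @ (lv - mu_x) ** 2)

    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    diff = np.abs(i - j)
    feats = {
        "energy": float((p**2).sum()),
        "entropy": entropy,
        "contrast": float((diff * p).sum()),
        "variance": float((((i - mu_x) ** 2) * p).sum()),
        "inertia": float((((i - j) ** 2) * p).sum()),
        "cluster_shade": float((((i + j - mu_x - mu_y) ** 3) * p).sum()),
        "cluster_tendency": float((((i + j - mu_x - mu_y) ** 2) * p).sum()),
        "homogeneity": float((p / (1.0 + diff)).sum()),
        "maximum_probability": float(p.max()),
    }
    # sum_mean over the diagonal-sum distribution p_{x+y}(k)
    k = i + j
    feats["sum_mean"] = float((k * p).sum())
    if var_x > 0:
        cov = float((((i - mu_x) * (j - mu_y)) * p).sum())
        feats["correlation"] = cov / var_x  # sigma_x == sigma_y by symmetry
    else:
        feats["correlation"] = float("nan")  # single occupied level
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(off, p / np.where(off, (i - j) ** 2, 1.0), 0.0)
    feats["inverse_variance"] = float(inv.sum())
    return {name: feats[name] for name in FEATURE_NAMES}


def aggregate_glcm_features(qroi: QuantizedRoi, distance: int) -> dict[str, float]:
    """Mean of the 12 features over the 13 directions with at least one pair.

    The returned dict carries an extra ``n_directions`` entry recording how
    many directions contributed.  Directions whose offset finds no in-mask
    pair are dropped from the mean.
    """
    per_dir: list[dict[str, float]] = []
    for direction in DIRECTIONS:
        g = build_glcm(qroi, direction, distance)
        if g.n_pairs > 0:
            per_dir.append(glcm_features(g))
    if not per_dir:
        raise FeatureSetMissingError(
            f"no direction produced voxel pairs at distance {distance}"
        )
    out: dict[str, float] = {}
    for name in FEATURE_NAMES:
        vals = [f[name] for f in per_dir if not math.isnan(f[name])]
        out[name] = float(np.mean(vals)) if vals else float("nan")
    out["n_directions"] = float(len(per_dir))
    return out
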