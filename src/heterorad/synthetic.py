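"""Synthetic DECT tumor phantoms and cohorts with known ground truth.

A phantom is an ellipsoidal tumor mask partitioned into 1-4 spatial
compartments, one per histologic growth pattern present in its composition.
Compartments are grown around seeded interior points by nearest-seed
assignment under volume quotas, giving contiguous irregular regions whose
volume fractions match the composition (a capacity-constrained Voronoi
partition).  Each compartment's voxels are drawn from its subtype's HU
distribution — defaults ordered along the radiologic ground-glass -> solid
spectrum — plus global additive Gaussian noise; the iodine channel is
generated analogously from per-subtype enhancement distributions.

Compositions are drawn from a flat Dirichlet over the chosen subtypes,
quantized to the nearest 5% summing to 100%, with subtype combinations
weighted toward the mixtures most frequent in published stage I/II lung
adenocarcinoma cohorts (lepidic+acinar above all).

The module also ships two small literature-shaped fixtures:
``reference_composition_table`` (an 89-tumor composition table reproducing
published predominant-subtype and mixture frequencies) and
``patient_flow_table`` (93 resected lesions of which 4 carry exclusion
flags).
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .config import (
    DEFAULT_SUBTYPE_HU,
    DEFAULT_SUBTYPE_IODINE,
    SUBTYPES,
    RunConfig,
)
from .errors import PhantomSizeError
from .imaging import ImageVolume, RoiMask
from .pathology import (
    SubtypeComposition,
    heterogeneity_profile,
    validate_composition,
)

# Subtype combinations by mixture count, weighted by published cohort
# frequencies (counts out of 89 tumors).
COMBO_PATTERNS: dict[int, list[tuple[tuple[str, ...], int]]] = {
    1: [(("lepidic",), 5), (("acinar",), 11), (("papillary",), 3)],
    2: [
        (("lepidic", "acinar"), 31),
        (("acinar", "papillary"), 13),
        (("acinar", "micropapillary"), 1),
        (("acinar", "solid"), 9),
    ],
    3: [
        (("lepidic", "acinar", "papillary"), 6),
        (("lepidic", "acinar", "solid"), 2),
        (("acinar", "papillary", "micropapillary"), 4),
        (("acinar", "micropapillary", "solid"), 2),
    ],
    4: [(("lepidic", "acinar", "papillary", "micropapillary"), 2)],
}

#: Published subtype-count frequencies (1, 2, 3, 4 mixtures) in 89 tumors.
SUBTYPE_COUNT_FREQUENCIES = {1: 19, 2: 54, 3: 14, 4: 2}


@dataclass
class PhantomSpec:
    composition: SubtypeComposition
    shape: tuple[int, int, int] = (28, 28, 14)
    spacing: tuple[float, float, float] = (0.7, 0.7, 1.0)
    subtype_hu: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_HU)
    )
    subtype_iodine: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_IODINE)
    )
    noise_sd: float = 20.0
    seed: int = 0


@dataclass
class CohortSpec:
    n_tumors: int = 89
    count_distribution: dict[int, float] = field(
        default_factory=lambda: {
            k: v / 89.0 for k, v in SUBTYPE_COUNT_FREQUENCIES.items()
        }
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be >= 1")
        total = sum(self.count_distribution.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"count distribution sums to {total}, expected 1")


def sample_composition(k_subtypes: int, seed=None) -> SubtypeComposition:
    """Draw a valid nearest-5% composition with exactly k strictly positive parts."""
    if k_subtypes not in COMBO_PATTERNS:
        raise ValueError(f"k_subtypes must be in 1..4, got {k_subtypes}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    combos, weights = zip(*COMBO_PATTERNS[k_subtypes])
    w = np.array(weights, dtype=float)
    combo = combos[rng.choice(len(combos), p=w / w.sum())]
    props = rng.dirichlet(np.ones(len(combo)))
    units = _positive_units(props, 20)
    percent = {s: 0 for s in SUBTYPES}
    for s, u in zip(combo, units):
        percent[s] = int(u * 5)
    return SubtypeComposition(percent=percent)


def _positive_units(props: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment with every part at least one unit."""
    k = props.size
    exact = props * total
    units = np.floor(exact).astype(int)
    order = np.argsort(-(exact - units), kind="stable")
    for idx in order[: total - units.sum()]:
        units[idx] += 1
    while (units == 0).any():
        units[np.argmin(units)] += 1
        units[np.argmax(units)] -= 1
    return units


def make_phantom(spec: PhantomSpec):
    """Build (non-contrast volume, iodine volume, mask, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    present = [s for s in SUBTYPES if spec.composition.percent[s] > 0]
    k = len(present)

    center = (np.array(shape) - 1) / 2.0
    semi = np.maximum(np.array(shape) * 0.42, 1.0)
    grid = np.indices(shape).reshape(3, -1).T
    inside = (((grid - center) / semi) ** 2).sum(axis=1) <= 1.0
    mask = inside.reshape(shape)
    n_vox = int(mask.sum())
    if n_vox < 10 * k:
        raise PhantomSizeError(
            f"mask of {n_vox} voxels cannot host {k} compartments"
        )

    coords = np.argwhere(mask)
    mm = coords * np.array(spec.spacing)
    seed_idx = rng.choice(n_vox, size=k, replace=False)
    dist = np.linalg.norm(mm[:, None, :] - mm[seed_idx][None, :, :], axis=2)

    fracs = np.array([spec.composition.percent[s] / 100.0 for s in present])
    quotas = _positive_units(fracs, n_vox) if k > 1 else np.array([n_vox])
    # capacity-constrained nearest-seed growth, largest compartment first
    assign = np.full(n_vox, -1, dtype=int)
    for c in np.argsort(-quotas, kind="stable"):
        free = np.flatnonzero(assign < 0)
        take = free[np.argsort(dist[free, c], kind="stable")[: quotas[c]]]
        assign[take] = c
    assign[assign < 0] = int(np.argmin(quotas))

    nc = np.zeros(shape)
    iod = np.zeros(shape)
    for c, s in enumerate(present):
        sel = tuple(coords[assign == c].T)
        m_nc, sd_nc = spec.subtype_hu[s]
        m_io, sd_io = spec.subtype_iodine[s]
        nvox_c = len(sel[0])
        nc[sel] = rng.normal(m_nc, sd_nc, size=nvox_c)
        iod[sel] = rng.normal(m_io, sd_io, size=nvox_c)
    if spec.noise_sd > 0:
        nc[mask] += rng.normal(0.0, spec.noise_sd, size=n_vox)
        iod[mask] += rng.normal(0.0, spec.noise_sd, size=n_vox)
    nc[~mask] = -1000.0
    iod[~mask] = 0.0

    realized = {
        s: float((assign == c).sum() / n_vox) for c, s in enumerate(present)
    }
    profile = heterogeneity_profile(spec.composition)
    truth = {
        "composition": dict(spec.composition.percent),
        "realized_fractions": realized,
        "index": profile.index,
        "n_subtypes": profile.n_subtypes,
        "group": profile.group.value,
        "seed": spec.seed,
    }
    vol_nc = ImageVolume(nc, spec.spacing, channel="non_contrast")
    vol_io = ImageVolume(iod, spec.spacing, channel="iodine")
    return vol_nc, vol_io, RoiMask(mask), truth


def _save_nifti(volume_data: np.ndarray, spacing, path: str) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume_data, dtype=np.float32), affine)
    img.header.set_zooms(spacing)
    nib.save(img, path)


def make_cohort(spec: CohortSpec, out_dir: str, config: RunConfig | None = None):
    """Write a full phantom cohort: NIfTI volumes/masks, pathology CSV, manifest.

    Returns the manifest dict (also saved as ``manifest.json``): one row per
    tumor with file paths, the per-tumor seed and the ground-truth
    composition, heterogeneity index and group.
    """
    config = config or RunConfig()
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    ks = sorted(spec.count_distribution)
    probs = np.array([spec.count_distribution[k] for k in ks], dtype=float)
    rows = []
    path_rows = []
    for t in range(spec.n_tumors):
        k = int(np.asarray(ks)[rng.choice(len(ks), p=probs / probs.sum())])
        tumor_seed = int(rng.integers(0, 2**31 - 1))
        comp = sample_composition(k, np.random.default_rng(tumor_seed))
        # tumors vary in size, as in any surgical cohort
        scale = rng.uniform(0.75, 1.5)
        shape = tuple(max(10, round(s * scale)) for s in (28, 28, 14))
        pspec = PhantomSpec(
            composition=comp,
            shape=shape,
            subtype_hu=config.subtype_hu,
            subtype_iodine=config.subtype_iodine,
            noise_sd=config.noise_sd,
            seed=tumor_seed,
        )
        vol_nc, vol_io, mask, truth = make_phantom(pspec)
        tid = f"tumor_{t:03d}"
        paths = {
            "non_contrast": os.path.join(out_dir, f"{tid}_nc.nii"),
            "iodine": os.path.join(out_dir, f"{tid}_iod.nii"),
            "mask": os.path.join(out_dir, f"{tid}_mask.nii"),
        }
        _save_nifti(vol_nc.data, pspec.spacing, paths["non_contrast"])
        _save_nifti(vol_io.data, pspec.spacing, paths["iodine"])
        _save_nifti(mask.data.astype(np.uint8), pspec.spacing, paths["mask"])
        rows.append({"tumor_id": tid, **truth})
        path_rows.append({"tumor_id": tid, **paths, "seed": tumor_seed})

    pathology = pd.DataFrame(
        [
            {
                "tumor_id": r["tumor_id"],
                **{s: r["composition"][s] for s in SUBTYPES},
                "fibrosis": 0,
            }
            for r in rows
        ]
    )
    pathology_path = os.path.join(out_dir, "pathology.csv")
    pathology.to_csv(pathology_path, index=False)
    manifest = {
        "seed": spec.seed,
        "n_tumors": spec.n_tumors,
        "config": config.to_dict(),
        "pathology_csv": pathology_path,
        "tumors": path_rows,
        "ground_truth": rows,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Literature-shaped fixtures (synthetic reconstructions, not patient data)
# ---------------------------------------------------------------------------

def _rows(combo_percents: dict[str, int], n: int) -> list[dict[str, int]]:
    base = {s: 0 for s in SUBTYPES}
    base.update(combo_percents)
    return [dict(base) for _ in range(n)]


def reference_composition_table() -> pd.DataFrame:
    """An 89-tumor composition table shaped like a published stage I/II cohort.

    Synthetic reconstruction: mixture patterns, subtype-count group sizes
    (19/54/14/2) and predominant-subtype counts (lepidic 18, acinar 53,
    papillary 11, micropapillary 6, solid 1) match the published frequency
    table; the individual percentages are invented consistent values.
    """
    rows: list[dict[str, int]] = []
    rows += _rows({"lepidic": 100}, 5)
    rows += _rows({"acinar": 100}, 11)
    rows += _rows({"papillary": 100}, 3)
    rows += _rows({"lepidic": 60, "acinar": 40}, 13)
    rows += _rows({"lepidic": 40, "acinar": 60}, 18)
    rows += _rows({"acinar": 60, "papillary": 40}, 8)
    rows += _rows({"acinar": 40, "papillary": 60}, 5)
    rows += _rows({"acinar": 45, "micropapillary": 55}, 1)
    rows += _rows({"acinar": 70, "solid": 30}, 8)
    rows += _rows({"acinar": 45, "solid": 55}, 1)
    rows += _rows({"lepidic": 25, "acinar": 30, "papillary": 45}, 3)
    rows += _rows({"lepidic": 25, "acinar": 45, "papillary": 30}, 3)
    rows += _rows({"lepidic": 30, "acinar": 50, "solid": 20}, 2)
    rows += _rows({"acinar": 30, "papillary": 20, "micropapillary": 50}, 3)
    rows += _rows({"acinar": 50, "papillary": 25, "micropapillary": 25}, 1)
    rows += _rows({"acinar": 25, "micropapillary": 45, "solid": 30}, 2)
    rows += _rows({"lepidic": 20, "acinar": 40, "papillary": 25, "micropapillary": 15}, 2)
    df = pd.DataFrame(rows)
    df.insert(0, "tumor_id", [f"ref_{i:03d}" for i in range(len(df))])
    df["fibrosis"] = 0
    return df


def patient_flow_table() -> pd.DataFrame:
    """93 resected lesions with exclusion flags; 89 survive all filters.

    Synthetic reconstruction of the published patient flow: of 93 resected
    lesions, one benign lesion, one mucinous adenocarcinoma and two with
    insufficient pathologic slides are excluded, leaving 89 study tumors.
    """
    df = reference_composition_table()
    df["benign"] = 0
    df["mucinous"] = 0
    df["insufficient_slides"] = 0
    excluded = []
    for i, flag in enumerate(
        ["benign", "mucinous", "insufficient_slides", "insufficient_slides"]
    ):
        row = {"tumor_id": f"excl_{i:03d}", **{s: 0 for s in SUBTYPES}}
        row["acinar"] = 100
        row["fibrosis"] = 0
        row["benign"] = row["mucinous"] = row["insufficient_slides"] = 0
        row[flag] = 1
        excluded.append(row)
    out = pd.concat([df, pd.DataFrame(excluded)], ignore_index=True)
    for c in ("benign", "mucinous", "insufficient_slides"):
        out[c] = out[c].astype(int)
    return out
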