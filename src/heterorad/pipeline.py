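"""Cohort-level orchestration: extraction, reports, validation, stability.

The unit of analysis is one tumor on one channel (non-contrast or iodine).
Every tumor yields 51 radiomic features: 4 physical, 7 histogram, 4
regional, and 36 local (12 co-occurrence statistics x 3 voxel distances).
Reports mirror the standard presentation: a correlation table of every
feature against the pathologic heterogeneity index, a three-group
comparison by number of mixed histologic subtypes, a stepwise-AIC model
validated by 10-fold cross-validation, and an inter-reader stability table
of Lin concordance coefficients.

Every report CSV starts with ``#``-prefixed header lines embedding the
serialized run configuration, so a report is reproducible byte-for-byte
from its own header.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import glszm as glszm_mod
from .config import SUBTYPES, RunConfig
from .errors import (
    GroupDefinitionError,
    HeteroradError,
    InsufficientDataError,
    RunError,
)
from .firstorder import compute_histogram_features, compute_physical
from .glcm import FEATURE_NAMES as GLCM_FEATURE_NAMES
from .glcm import aggregate_glcm_features
from .imaging import ImageVolume, RoiMask, extract_roi, quantize_with_profile, read_mask, read_volume
from .pathology import Group, heterogeneity_profile, validate_composition
from .stats import (
    anova_tukey,
    cross_validated_prediction,
    lin_ccc,
    spearman,
    stepwise_aic_fit,
)

log = logging.getLogger(__name__)

PHYSICAL_NAMES = ("volume_cm3", "density_gpml", "mass_g", "size_mm")
HISTOGRAM_NAMES = ("skewness", "kurtosis", "p2_5", "p25", "p50", "p75", "p97_5")
REGIONAL_NAMES = (
    "uniformity",
    "entropy_regional",
    "intensity_variability",
    "size_zone_variability",
)
LOCAL_NAMES = tuple(
    f"{feat}_d{d}" for feat in GLCM_FEATURE_NAMES for d in (1, 2, 3)
)


def feature_names() -> tuple[str, ...]:
    """The frozen 51-feature schema: physical, histogram, regional, local."""
    return PHYSICAL_NAMES + HISTOGRAM_NAMES + REGIONAL_NAMES + LOCAL_NAMES


def extract_features(
    volume: ImageVolume, mask: RoiMask, config: RunConfig | None = None
) -> dict[str, float]:
    """All 51 features for one tumor on one channel; degenerate ones are NaN."""
    config = config or RunConfig()
    roi = extract_roi(volume, mask)
    out: dict[str, float] = {name: float("nan") for name in feature_names()}

    phys = compute_physical(roi, size_3d=config.size_3d)
    out["volume_cm3"] = phys.volume_cm3
    out["density_gpml"] = phys.density_gpml
    out["mass_g"] = phys.mass_g
    out["size_mm"] = phys.size_mm

    hist = compute_histogram_features(roi)
    for name in HISTOGRAM_NAMES:
        out[name] = getattr(hist, name)

    try:
        tex_qroi = quantize_with_profile(roi, config.texture_profile)
        hist_qroi = quantize_with_profile(roi, config.histogram_profile)
    except HeteroradError as exc:
        log.warning("quantization failed, texture features missing: %s", exc)
        return out

    try:
        zones = glszm_mod.build_glszm(tex_qroi, connectivity=config.zone_connectivity)
        uni, ent, ivar, szvar = glszm_mod.regional_features(hist_qroi, zones)
        out["uniformity"] = uni
        out["entropy_regional"] = ent
        out["intensity_variability"] = ivar
        out["size_zone_variability"] = szvar
    except HeteroradError as exc:
        log.warning("regional features missing: %s", exc)

    for d in (1, 2, 3):
        try:
            agg = aggregate_glcm_features(tex_qroi, d)
        except HeteroradError as exc:
            log.warning("local features missing at distance %d: %s", d, exc)
            continue
        for feat in GLCM_FEATURE_NAMES:
            out[f"{feat}_d{d}"] = agg[feat]
    return out


def _load_manifest(manifest) -> dict:
    if isinstance(manifest, (str,)):
        with open(manifest) as fh:
            return json.load(fh)
    return manifest


def run_extraction(manifest, config: RunConfig | None = None) -> pd.DataFrame:
    """Extract the 51-feature battery for every tumor and channel in a manifest.

    ``manifest`` is the dict (or path to the JSON) written by
    ``synthetic.make_cohort``: rows with ``tumor_id`` and file paths for the
    ``non_contrast``, ``iodine`` and ``mask`` grids.  Unreadable rows are
    recorded and skipped; the run only fails if every row fails.
    """
    config = config or RunConfig()
    manifest = _load_manifest(manifest)
    rows = []
    failures = []
    for entry in manifest["tumors"]:
        tid = entry["tumor_id"]
        try:
            mask = read_mask(entry["mask"])
            for channel in ("non_contrast", "iodine"):
                if not entry.get(channel):
                    continue
                vol = read_volume(entry[channel], channel=channel)
                feats = extract_features(vol, mask, config)
                rows.append({"tumor_id": tid, "channel": channel, **feats})
        except (HeteroradError, OSError) as exc:
            log.error("tumor %s failed: %s", tid, exc)
            failures.append((tid, str(exc)))
    if not rows:
        raise RunError(f"all {len(failures)} manifest rows failed")
    df = pd.DataFrame(rows, columns=["tumor_id", "channel", *feature_names()])
    return df.sort_values(["channel", "tumor_id"], kind="stable").reset_index(drop=True)


def attach_pathology(
    features: pd.DataFrame, pathology: pd.DataFrame, config: RunConfig | None = None
) -> pd.DataFrame:
    """Join per-tumor pathology (index, n_subtypes, group, predominant)."""
    config = config or RunConfig()
    prof_rows = []
    for _, row in pathology.iterrows():
        comp = validate_composition(
            {s: row[s] for s in SUBTYPES if s in row and not pd.isna(row[s])}
        )
        prof = heterogeneity_profile(comp, config.subtype_weights)
        prof_rows.append(
            {
                "tumor_id": row["tumor_id"],
                "index": prof.index,
                "n_subtypes": prof.n_subtypes,
                "group": prof.group.value,
                "predominant": prof.predominant,
            }
        )
    return features.merge(pd.DataFrame(prof_rows), on="tumor_id", how="inner")


def run_correlation_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per feature per channel: Spearman rho vs the heterogeneity index.

    ``cohort`` is the output of :func:`attach_pathology`.  Features constant
    across tumors get a missing rho (logged), mirroring how degenerate
    columns are reported rather than dropped.
    """
    if cohort["tumor_id"].nunique() < 3:
        raise InsufficientDataError("need at least 3 tumors for correlations")
    rows = []
    for channel in ("non_contrast", "iodine"):
        sub = cohort[cohort["channel"] == channel]
        if sub.empty:
            continue
        for feat in feature_names():
            pair = sub[[feat, "index"]].dropna()
            try:
                res = spearman(pair[feat].to_numpy(), pair["index"].to_numpy())
                rows.append(
                    {
                        "feature": feat,
                        "channel": channel,
                        "rho": res.rho,
                        "p_value": res.p_value,
                        "strength": res.strength,
                        "n": res.n,
                    }
                )
            except (HeteroradError, ValueError) as exc:
                log.warning("correlation undefined for %s/%s: %s", feat, channel, exc)
                rows.append(
                    {
                        "feature": feat,
                        "channel": channel,
                        "rho": float("nan"),
                        "p_value": float("nan"),
                        "strength": "undefined",
                        "n": len(pair),
                    }
                )
    return pd.DataFrame(rows)


GROUP_ORDER = (Group.ONE.value, Group.TWO.value, Group.THREE_OR_FOUR.value)


def run_group_comparison(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per subtype-count group with ANOVA and Tukey HSD p-values."""
    for g in GROUP_ORDER:
        n_g = cohort.loc[cohort["group"] == g, "tumor_id"].nunique()
        if n_g < 2:
            raise GroupDefinitionError(
                f"group {g} has {n_g} tumors; need at least 2"
            )
    rows = []
    for channel in ("non_contrast", "iodine"):
        sub = cohort[cohort["channel"] == channel]
        if sub.empty:
            continue
        for feat in feature_names():
            groups = [
                sub.loc[sub["group"] == g, feat].dropna().to_numpy()
                for g in GROUP_ORDER
            ]
            if any(g.size < 2 for g in groups):
                log.warning("skipping %s/%s: a group is degenerate", feat, channel)
                continue
            cmp = anova_tukey(groups)
            row = {"feature": feat, "channel": channel}
            for g, m, s, n in zip(GROUP_ORDER, cmp.means, cmp.sds, cmp.ns):
                row[f"mean_{g}"] = m
                row[f"sd_{g}"] = s
                row[f"n_{g}"] = n
            row["f_statistic"] = cmp.f_statistic
            row["anova_p"] = cmp.anova_p
            for (a, b), p in cmp.tukey.items():
                row[f"tukey_{GROUP_ORDER[a]}_vs_{GROUP_ORDER[b]}"] = p
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ModelValidationReport:
    selected_features: list[str]
    coefficients: dict[str, float]
    aic: float
    in_fold_r: float
    out_of_fold_r: float
    n: int
    seed: int
    k_folds: int


def run_model_validation(
    cohort: pd.DataFrame, config: RunConfig | None = None
) -> ModelValidationReport:
    """Stepwise-AIC model of the heterogeneity index with 10-fold CV.

    Features from both channels enter as candidates (suffixed _nc / _iod);
    both the in-fold (full-data fitted) and out-of-fold Pearson r against
    the index are reported.
    """
    config = config or RunConfig()
    wide = _pivot_channels(cohort)
    complete = wide.dropna()
    if len(complete) < 30:
        raise InsufficientDataError(
            f"model validation needs >= 30 complete tumors, got {len(complete)}"
        )
    y = complete.pop("index")
    fit = cross_validated_prediction(
        complete, y.to_numpy(), k=config.cv_folds, seed=config.seed
    )
    return ModelValidationReport(
        selected_features=fit.selected_features,
        coefficients=fit.coefficients,
        aic=fit.aic,
        in_fold_r=fit.in_fold_r,
        out_of_fold_r=fit.out_of_fold_r,
        n=fit.n,
        seed=config.seed,
        k_folds=config.cv_folds,
    )


def _pivot_channels(cohort: pd.DataFrame) -> pd.DataFrame:
    suffix = {"non_contrast": "_nc", "iodine": "_iod"}
    parts = []
    for channel, suf in suffix.items():
        sub = cohort[cohort["channel"] == channel]
        if sub.empty:
            continue
        cols = sub.set_index("tumor_id")[list(feature_names())].add_suffix(suf)
        parts.append(cols)
    wide = pd.concat(parts, axis=1)
    idx = cohort.drop_duplicates("tumor_id").set_index("tumor_id")["index"]
    wide["index"] = idx
    return wide


def run_stability(
    pairs, config: RunConfig | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-feature Lin CCC across two readers' masks, with a summary line.

    ``pairs`` is an iterable of (volume, mask_a, mask_b).  Returns the
    per-feature table and a summary dict (min, max, mean, sd over features).
    """
    config = config or RunConfig()
    rows_a, rows_b = [], []
    for volume, mask_a, mask_b in pairs:
        try:
            rows_a.append(extract_features(volume, mask_a, config))
            rows_b.append(extract_features(volume, mask_b, config))
        except HeteroradError as exc:
            log.warning("stability pair skipped: %s", exc)
    if not rows_a:
        raise RunError("no usable mask pairs")
    a = pd.DataFrame(rows_a)
    b = pd.DataFrame(rows_b)
    recs = []
    for feat in feature_names():
        xa = a[feat].to_numpy()
        xb = b[feat].to_numpy()
        ok = ~(np.isnan(xa) | np.isnan(xb))
        if ok.sum() < 2:
            recs.append({"feature": feat, "ccc": float("nan"), "n": int(ok.sum())})
            continue
        recs.append(
            {"feature": feat, "ccc": lin_ccc(xa[ok], xb[ok]), "n": int(ok.sum())}
        )
    table = pd.DataFrame(recs)
    cccs = table["ccc"].dropna()
    summary = {
        "min": float(cccs.min()),
        "max": float(cccs.max()),
        "mean": float(cccs.mean()),
        "sd": float(cccs.std(ddof=1)),
        "n_features": int(cccs.size),
    }
    return table, summary


EXCLUSION_FLAGS = ("benign", "mucinous", "insufficient_slides")


def summarize_cohort(pathology) -> dict:
    """Cohort summary: exclusion filtering, predominant subtype, group counts.

    ``pathology`` is a DataFrame or CSV path with per-tumor subtype
    percentages and optional exclusion-flag columns.  Percentages are
    rounded to one decimal.
    """
    if isinstance(pathology, str):
        try:
            df = pd.read_csv(pathology, comment="#")
        except Exception as exc:  # surface the line if pandas reports one
            raise RunError(f"malformed pathology CSV {pathology}: {exc}") from exc
    else:
        df = pathology.copy()
    n_total = len(df)
    keep = pd.Series(True, index=df.index)
    for flag in EXCLUSION_FLAGS:
        if flag in df.columns:
            keep &= df[flag].fillna(0).astype(int) == 0
    survivors = df[keep]
    predominant: dict[str, int] = {}
    groups = {g: 0 for g in GROUP_ORDER}
    for _, row in survivors.iterrows():
        comp = validate_composition(
            {s: row[s] for s in SUBTYPES if s in row and not pd.isna(row[s])}
        )
        prof = heterogeneity_profile(comp)
        predominant[prof.predominant] = predominant.get(prof.predominant, 0) + 1
        groups[prof.group.value] += 1
    n = len(survivors)
    return {
        "n_total": n_total,
        "n_excluded": n_total - n,
        "n_survivors": n,
        "predominant_counts": predominant,
        "predominant_percent": {
            k: round(100.0 * v / n, 1) for k, v in predominant.items()
        },
        "group_counts": groups,
        "group_percent": {k: round(100.0 * v / n, 1) for k, v in groups.items()},
    }


def write_report(df: pd.DataFrame, path: str, config: RunConfig) -> None:
    """CSV with the serialized RunConfig embedded as comment header lines."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# heterorad-config: {config.to_json()}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.10g")
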