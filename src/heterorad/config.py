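"""Run configuration: quantization profiles, subtype weights, phantom defaults.

Two quantization profiles are used downstream.  Texture matrices (GLCM,
GLSZM zones) use a coarse 16-level binning over a fixed Hounsfield window
[-1000, 400] HU, so that a level always means the same attenuation band
regardless of the individual tumor's dynamic range.  Histogram-style
statistics (regional uniformity/entropy) use a fine 256-bin profile over the
same window.  Both are configurable.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import yaml

#: IASLC/ATS/ERS invasive-adenocarcinoma growth patterns, fixed order.
SUBTYPES = ("lepidic", "acinar", "papillary", "micropapillary", "solid")

#: Ranking used to break predominance ties: most aggressive pattern wins.
AGGRESSIVENESS_ORDER = ("solid", "micropapillary", "papillary", "acinar", "lepidic")

#: Hazard-ratio-derived weights for the pathologic heterogeneity index.
#: These defaults encode only the established ordering of subtype
#: aggressiveness (lepidic best prognosis ... solid/micropapillary worst);
#: any published hazard-ratio set can be substituted.
DEFAULT_SUBTYPE_WEIGHTS = {
    "lepidic": 0.0,
    "acinar": 1.0,
    "papillary": 1.0,
    "micropapillary": 2.0,
    "solid": 2.0,
}

#: Fixed HU window covering lung parenchyma through enhancing soft tissue.
DEFAULT_HU_WINDOW = (-1000.0, 400.0)


@dataclass(frozen=True)
class QuantizationProfile:
    """Equal-width intensity binning: level count plus optional fixed range.

    ``hu_range=None`` means the observed ROI min/max is used at quantization
    time (then a constant ROI is an error the caller must resolve).
    """

    n_levels: int
    hu_range: tuple[float, float] | None = None


TEXTURE_PROFILE = QuantizationProfile(16, DEFAULT_HU_WINDOW)
HISTOGRAM_PROFILE = QuantizationProfile(256, DEFAULT_HU_WINDOW)

# Non-contrast HU distributions per growth pattern, ordered along the
# radiologic ground-glass -> solid spectrum. (mean HU, SD).
DEFAULT_SUBTYPE_HU = {
    "lepidic": (-650.0, 80.0),
    "acinar": (-300.0, 90.0),
    "papillary": (-150.0, 90.0),
    "micropapillary": (-50.0, 80.0),
    "solid": (30.0, 60.0),
}

# Iodine-map values (HU enhancement) ordered by expected vascularity.
DEFAULT_SUBTYPE_IODINE = {
    "lepidic": (5.0, 15.0),
    "acinar": (20.0, 15.0),
    "papillary": (30.0, 15.0),
    "micropapillary": (40.0, 15.0),
    "solid": (45.0, 15.0),
}


@dataclass
class RunConfig:
    """Everything a pipeline command needs to be reproducible byte-for-byte."""

    texture_levels: int = TEXTURE_PROFILE.n_levels
    texture_range: tuple[float, float] | None = TEXTURE_PROFILE.hu_range
    histogram_bins: int = HISTOGRAM_PROFILE.n_levels
    histogram_range: tuple[float, float] = DEFAULT_HU_WINDOW
    zone_connectivity: int = 26  # 26 or 6
    size_3d: bool = False  # False: max axial in-plane diameter
    subtype_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_WEIGHTS)
    )
    subtype_hu: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_HU)
    )
    subtype_iodine: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_IODINE)
    )
    noise_sd: float = 20.0
    cv_folds: int = 10
    seed: int = 0

    @property
    def texture_profile(self) -> QuantizationProfile:
        rng = tuple(self.texture_range) if self.texture_range is not None else None
        return QuantizationProfile(self.texture_levels, rng)

    @property
    def histogram_profile(self) -> QuantizationProfile:
        return QuantizationProfile(self.histogram_bins, tuple(self.histogram_range))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.texture_range is not None:
            cfg.texture_range = tuple(cfg.texture_range)
        cfg.histogram_range = tuple(cfg.histogram_range)
        cfg.subtype_hu = {k: tuple(v) for k, v in cfg.subtype_hu.items()}
        cfg.subtype_iodine = {k: tuple(v) for k, v in cfg.subtype_iodine.items()}
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
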