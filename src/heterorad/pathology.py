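"""Histologic subtype compositions and the pathologic heterogeneity index.

A tumor's comprehensive histologic subtyping assigns each IASLC/ATS/ERS
growth pattern (lepidic, acinar, papillary, micropapillary, solid) a
percentage quantized to the nearest 5%, summing to 100%.  Central fibrosis
may be recorded alongside but is excluded from the subtype simplex.

The pathologic heterogeneity index summarizes a mixture's prognostic weight
as the weighted mean of subtype proportions, with per-subtype weights
derived from disease-free-survival hazard ratios.  The shipped default
weights encode only the established aggressiveness ordering (lepidic 0,
acinar/papillary 1, micropapillary/solid 2); substitute any published
hazard-ratio set through configuration.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .config import AGGRESSIVENESS_ORDER, DEFAULT_SUBTYPE_WEIGHTS, SUBTYPES
from .errors import ConfigurationError, InvalidCompositionError


class Group(str, enum.Enum):
    """Subtype-count groups used for the three-way comparison."""

    ONE = "ONE"
    TWO = "TWO"
    THREE_OR_FOUR = "THREE_OR_FOUR"


@dataclass(frozen=True)
class SubtypeComposition:
    percent: dict[str, int]  # all five subtypes, multiples of 5, sum 100
    fibrosis_percent: int | None = None


@dataclass(frozen=True)
class HeterogeneityProfile:
    index: float
    n_subtypes: int
    group: Group
    predominant: str


def _round5(x: float) -> int:
    return int(math.floor(x / 5.0 + 0.5)) * 5


def _largest_remainder_units(shares: dict[str, float], total_units: int) -> dict[str, int]:
    """Apportion ``total_units`` integer units proportionally to ``shares``."""
    s = sum(shares.values())
    exact = {k: total_units * v / s for k, v in shares.items()}
    units = {k: int(math.floor(e)) for k, e in exact.items()}
    short = total_units - sum(units.values())
    order = sorted(
        shares,
        key=lambda k: (-(exact[k] - units[k]), SUBTYPES.index(k)),
    )
    for k in order[:short]:
        units[k] += 1
    return units


def validate_composition(raw: dict[str, float]) -> SubtypeComposition:
    """Round to nearest 5%, repair the sum to 100 by largest remainder.

    Keys must be subtypes (plus optional ``fibrosis``).  All-zero or negative
    input is rejected.
    """
    raw = dict(raw)
    fibrosis = raw.pop("fibrosis", None)
    unknown = set(raw) - set(SUBTYPES)
    if unknown:
        raise InvalidCompositionError(f"unknown subtypes: {sorted(unknown)}")
    for k, v in raw.items():
        if v < 0 or v > 100:
            raise InvalidCompositionError(f"{k}: percentage {v} outside [0, 100]")
    if sum(raw.values()) == 0:
        raise InvalidCompositionError("subtype percentages sum to zero")
    rounded = {k: _round5(float(v)) for k, v in raw.items()}
    total = sum(rounded.values())
    if total != 100:
        # renormalize; if nearest-5 rounding wiped out a tiny composition,
        # apportion from the raw shares instead
        positive = {k: v for k, v in rounded.items() if v > 0}
        if not positive:
            positive = {k: v for k, v in raw.items() if v > 0}
        units = _largest_remainder_units(positive, 20)
        rounded = {k: units.get(k, 0) * 5 for k in rounded}
    percent = {s: int(rounded.get(s, 0)) for s in SUBTYPES}
    fib = None
    if fibrosis is not None:
        if fibrosis < 0:
            raise InvalidCompositionError(f"fibrosis percentage {fibrosis} negative")
        fib = _round5(float(fibrosis))
    return SubtypeComposition(percent=percent, fibrosis_percent=fib)


def heterogeneity_index(
    comp: SubtypeComposition, weights: dict[str, float] | None = None
) -> float:
    """Hazard-ratio-weighted mean of the subtype proportions."""
    w = DEFAULT_SUBTYPE_WEIGHTS if weights is None else weights
    index = 0.0
    for s, pct in comp.percent.items():
        if pct == 0:
            continue
        if s not in w or not math.isfinite(w[s]) or w[s] < 0:
            raise ConfigurationError(f"missing or invalid weight for subtype {s!r}")
        index += w[s] * pct / 100.0
    return index


def subtype_count_and_group(comp: SubtypeComposition) -> tuple[int, Group]:
    n = sum(1 for v in comp.percent.values() if v > 0)
    group = Group.ONE if n == 1 else Group.TWO if n == 2 else Group.THREE_OR_FOUR
    return n, group


def predominant_subtype(comp: SubtypeComposition) -> str:
    """Largest-percentage pattern; ties go to the more aggressive pattern."""
    return max(
        comp.percent,
        key=lambda s: (comp.percent[s], -AGGRESSIVENESS_ORDER.index(s)),
    )


def heterogeneity_profile(
    comp: SubtypeComposition, weights: dict[str, float] | None = None
) -> HeterogeneityProfile:
    n, group = subtype_count_and_group(comp)
    return HeterogeneityProfile(
        index=heterogeneity_index(comp, weights),
        n_subtypes=n,
        group=group,
        predominant=predominant_subtype(comp),
    )
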