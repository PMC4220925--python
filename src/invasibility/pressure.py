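"""Human-pressure scoring, reference classification and quality classes.

Each site carries ten ordinal disturbance scores (1 = minimum disturbance,
5 = maximum) covering land use, urban influence, riparian state, longitudinal
connectivity, sediment load, hydrological regime, channel morphology,
artificial lentic water bodies, toxicity/acidification and nutrient/organic
loads. The sum of the ten scores is the total human pressure (range 10-50).

A site counts as reference (undisturbed or least disturbed) when every score
is 1 or 2 with at most a single 3; any score of 4 or 5 disqualifies it. The
total-pressure gradient is further binned into the five Water Framework
Directive quality classes High/Good/Moderate/Poor/Bad.

Water-chemistry measurements (BOD5, COD, TSS, SRP, NO2, NO3, NH4, total
inorganic N, all mg/L) complement the evaluation and travel with the profile
as GLM covariates; they never enter the total-pressure sum.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

#: The ten pressure criteria, in canonical order.
CRITERIA: tuple[str, ...] = (
    "land_use",
    "urban_area",
    "riparian_vegetation",
    "connectivity",
    "sediment_load",
    "hydrological_regime",
    "morphological_condition",
    "artificial_lentic_water_bodies",
    "toxic_acid_levels",
    "nutrient_organic_loads",
)

#: Chemistry covariates carried alongside the ordinal scores (mg/L).
CHEMISTRY_VARS: tuple[str, ...] = (
    "BOD5", "COD", "TSS", "SRP", "NO2", "NO3", "NH4", "N",
)


class QualityClass(enum.IntEnum):
    """Five WFD quality classes ordered by increasing disturbance."""

    HIGH = 0
    GOOD = 1
    MODERATE = 2
    POOR = 3
    BAD = 4

    def __str__(self) -> str:  # "High", "Good", ...
        return self.name.capitalize()


#: Default class boundaries: equal-width bins over the total-pressure range
#: [10, 50]. A total t maps to High for t in [10, 18), Good [18, 26),
#: Moderate [26, 34), Poor [34, 42), Bad [42, 50].
DEFAULT_CLASS_BOUNDS: tuple[int, int, int, int] = (18, 26, 34, 42)


@dataclass(frozen=True)
class PressureProfile:
    """Ten ordinal pressure scores plus optional chemistry for one site."""

    scores: Mapping[str, int]
    chemistry: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(CRITERIA) - set(self.scores)
        if missing:
            raise ValueError(f"missing pressure criteria: {sorted(missing)}")
        extra = set(self.scores) - set(CRITERIA)
        if extra:
            raise ValueError(f"unknown pressure criteria: {sorted(extra)}")
        for name, score in self.scores.items():
            if score not in (1, 2, 3, 4, 5):
                raise ValueError(
                    f"score for {name!r} must be an integer in 1..5, got {score!r}")
        for name, value in self.chemistry.items():
            if value < 0:
                raise ValueError(f"chemistry {name!r} must be >= 0, got {value}")


def total_pressure(profile: PressureProfile) -> int:
    """Total human pressure: the sum of the ten ordinal scores (10-50)."""
    return int(sum(profile.scores[c] for c in CRITERIA))


def classify_reference(profile: PressureProfile) -> bool:
    """True when the site qualifies as reference (undisturbed/least disturbed).

    The rule: all ten scores are 1 or 2, except that a single score of 3 is
    tolerated. Any score of 4 or 5, or a second 3, disqualifies the site.
    """
    values = [profile.scores[c] for c in CRITERIA]
    if max(values) > 3:
        return False
    return sum(v == 3 for v in values) <= 1


def assign_quality_class(
    total: int,
    bounds: Sequence[int] = DEFAULT_CLASS_BOUNDS,
) -> QualityClass:
    """Map a total human pressure onto one of the five quality classes.

    ``bounds`` gives the four lower edges of Good/Moderate/Poor/Bad; the
    default bins the range [10, 50] into five equal-width classes. The
    mapping is monotone: a larger total never yields a better class.
    """
    if not 10 <= total <= 50:
        raise ValueError(f"total pressure must lie in [10, 50], got {total}")
    if list(bounds) != sorted(bounds) or len(bounds) != 4:
        raise ValueError("bounds must be four non-decreasing cut points")
    rank = sum(total >= b for b in bounds)
    return QualityClass(rank)


def profile_from_row(row: Mapping[str, object], prefix: str = "pressure_") -> PressureProfile:
    """Build a profile from a site-table row with ``pressure_*`` columns."""
    scores = {c: int(row[prefix + c]) for c in CRITERIA if prefix + c in row}
    chemistry = {v: float(row[v]) for v in CHEMISTRY_VARS
                 if v in row and pd.notna(row[v])}
    return PressureProfile(scores=scores, chemistry=chemistry)


def classification_report(
    sites: pd.DataFrame,
    bounds: Sequence[int] = DEFAULT_CLASS_BOUNDS,
    prefix: str = "pressure_",
) -> pd.DataFrame:
    """Per-site pressure report: total, reference flag and quality class.

    ``sites`` is a site table with one ``pressure_<criterion>`` column per
    criterion; the result is indexed like ``sites`` with columns
    ``total_pressure``, ``reference`` and ``quality_class``.
    """
    records = []
    for _, row in sites.iterrows():
        profile = profile_from_row(row, prefix=prefix)
        total = total_pressure(profile)
        records.append({
            "total_pressure": total,
            "reference": classify_reference(profile),
            "quality_class": str(assign_quality_class(total, bounds)),
        })
    report = pd.DataFrame(records, index=sites.index)
    if "site_id" in sites.columns:
        report.insert(0, "site_id", sites["site_id"].to_numpy())
    return report
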