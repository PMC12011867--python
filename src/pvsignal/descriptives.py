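"""Descriptive stratification of a report cohort.

Produces the standard pharmacovigilance summary tables: reporting year,
reporter country and occupation, age and weight buckets, time to onset, and
clinical outcome.  Buckets are left-closed/right-open except the last, and
every missing or unparseable value lands in an explicit unknown category so
percentages always total 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .cohort import CaseReport, CohortSpec
from .faers_io import ParseWarnings

# unit conversion factors to years / kilograms
_AGE_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}
_WEIGHT_TO_KG = {"KG": 1.0, "LBS": 0.453592, "GMS": 0.001}

# outcome severity precedence: a report with several outcome codes
# contributes only its most severe one
OUTCOME_PRECEDENCE = ("DE", "LT", "DS", "HO", "OT")
OUTCOME_LABELS = {
    "DE": "death",
    "LT": "life-threatening",
    "DS": "disability",
    "HO": "hospitalization",
    "OT": "other",
}
UNKNOWN = "unknown"


@dataclass(frozen=True)
class BucketScheme:
    """Ordered buckets over a real line segment.

    ``edges`` are the interior boundaries; bucket i covers
    [edges[i-1], edges[i]) with open ends below the first and at/above the
    last edge.  ``labels`` has len(edges)+1 entries.
    """

    name: str
    edges: tuple[float, ...]
    labels: tuple[str, ...]
    unknown_label: str = UNKNOWN

    def __post_init__(self) -> None:
        if list(self.edges) != sorted(set(self.edges)):
            raise ValueError("edges must be strictly increasing")
        if len(self.labels) != len(self.edges) + 1:
            raise ValueError("need len(edges)+1 labels")

    def bucket(self, value: Optional[float]) -> str:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return self.unknown_label
        for edge, label in zip(self.edges, self.labels):
            if value < edge:
                return label
        return self.labels[-1]


# age buckets follow the published strata; 45–65 and 66–75 are rendered as
# left-closed [45, 66) and [66, 76) so integer ages read as labelled
AGE_SCHEME = BucketScheme(
    name="age_years",
    edges=(18.0, 45.0, 66.0, 76.0),
    labels=("<18", "18-44", "45-65", "66-75", ">75"),
)
WEIGHT_SCHEME = BucketScheme(
    name="weight_kg",
    edges=(73.0, 88.0, 105.0),
    labels=("<73", "73-87", "88-104", ">104"),
)
# onset buckets use a 30-day month, so 3–6 months = [90, 180) days
ONSET_SCHEME = BucketScheme(
    name="onset_days",
    edges=(30.0, 90.0, 180.0, 360.0),
    labels=("<1 month", "1-3 months", "3-6 months", "6-12 months", ">12 months"),
)
DEFAULT_SCHEMES = {"age": AGE_SCHEME, "weight": WEIGHT_SCHEME,
                   "onset": ONSET_SCHEME}


def normalize_age(value: Optional[float], unit: Optional[str],
                  warnings: Optional[ParseWarnings] = None) -> Optional[float]:
    """Convert an age to years; unknown units or negatives become missing."""
    if value is None:
        return None
    if value < 0:
        if warnings is not None:
            warnings.add("negative_age")
        return None
    factor = _AGE_TO_YEARS.get((unit or "YR").upper())
    if factor is None:
        if warnings is not None:
            warnings.add("unknown_age_unit")
        return None
    return value * factor


def normalize_weight(value: Optional[float], unit: Optional[str],
                     warnings: Optional[ParseWarnings] = None) -> Optional[float]:
    """Convert a body weight to kilograms; non-positive becomes missing."""
    if value is None:
        return None
    if value <= 0:
        if warnings is not None:
            warnings.add("nonpositive_weight")
        return None
    factor = _WEIGHT_TO_KG.get((unit or "KG").upper())
    if factor is None:
        if warnings is not None:
            warnings.add("unknown_weight_unit")
        return None
    return value * factor


@dataclass(frozen=True)
class OnsetRecord:
    primaryid: int
    onset_days: int
    bucket: str


def onset_days(report: CaseReport, spec: CohortSpec,
               scheme: BucketScheme = ONSET_SCHEME,
               warnings: Optional[ParseWarnings] = None) -> Optional[OnsetRecord]:
    """Days from the earliest matching suspect-drug start to the event date.

    Requires full-precision dates on both ends (partial dates would fabricate
    precision); negative spans count a warning and return missing.
    """
    event = report.demographics.event_dt
    if not event.is_full:
        return None
    starts = [
        report.therapy_starts[d.drug_seq]
        for d in report.drugs
        if d.role_cod in spec.role_codes and spec.drug_matches(d.drugname)
        and d.drug_seq in report.therapy_starts
    ]
    starts = [s for s in starts if s.is_full]
    if not starts:
        return None
    start = min(s.value for s in starts)
    days = (event.value - start).days
    if days < 0:
        if warnings is not None:
            warnings.add("negative_onset")
        return None
    return OnsetRecord(report.primaryid, days, scheme.bucket(float(days)))


def _freq_table(labels: Sequence[str], denominator: int,
                order: Optional[Sequence[str]] = None) -> pd.DataFrame:
    counts = pd.Series(list(labels), dtype="object").value_counts()
    if order is not None:
        counts = counts.reindex([o for o in order if o in counts.index])
    frame = counts.rename("n").to_frame()
    frame["percent"] = (
        (frame["n"] / denominator * 100).round(2) if denominator else 0.0
    )
    frame["denominator"] = denominator
    frame.index.name = "category"
    return frame.reset_index()


def worst_outcome(report: CaseReport) -> str:
    for code in OUTCOME_PRECEDENCE:
        if code in report.outcomes:
            return OUTCOME_LABELS[code]
    return UNKNOWN


def summarize(cohort: Sequence[CaseReport], spec: CohortSpec,
              schemes: Optional[dict[str, BucketScheme]] = None,
              warnings: Optional[ParseWarnings] = None) -> dict[str, pd.DataFrame]:
    """Frequency/percentage tables for the seven standard strata.

    Percentages are over the cohort size except the onset table, whose
    denominator is the number of reports with a computable onset; every
    table states its denominator.
    """
    schemes = {**DEFAULT_SCHEMES, **(schemes or {})}
    n = len(cohort)

    years = [str(r.demographics.fda_dt.value.year) if r.demographics.fda_dt.is_full
             else UNKNOWN for r in cohort]
    countries = [r.demographics.country or UNKNOWN for r in cohort]
    occupations = [r.demographics.occupation or UNKNOWN for r in cohort]
    ages = [schemes["age"].bucket(
        normalize_age(r.demographics.age_value, r.demographics.age_unit, warnings))
        for r in cohort]
    weights = [schemes["weight"].bucket(
        normalize_weight(r.demographics.weight_value, r.demographics.weight_unit,
                         warnings))
        for r in cohort]
    onsets = [rec for r in cohort
              if (rec := onset_days(r, spec, schemes["onset"], warnings))]
    outcomes = [worst_outcome(r) for r in cohort]

    return {
        "year": _freq_table(sorted(years), n),
        "country": _freq_table(countries, n),
        "occupation": _freq_table(occupations, n),
        "age": _freq_table(ages, n,
                           order=list(schemes["age"].labels) + [UNKNOWN]),
        "weight": _freq_table(weights, n,
                              order=list(schemes["weight"].labels) + [UNKNOWN]),
        "onset": _freq_table([rec.bucket for rec in onsets], len(onsets),
                             order=list(schemes["onset"].labels)),
        "outcome": _freq_table(outcomes, n,
                               order=[*OUTCOME_LABELS.values(), UNKNOWN]),
    }
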