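"""EHR-style triglyceride phenotyping with medication adjustment.

Each participant's longitudinal TG measurements (mg/dl) are corrected for
lipid-lowering medication exposure — every measurement taken while exposed
is multiplied by the drug class's correction factor (the largest factor if
several classes overlap) — and summarized as the median.  The adjusted
median then places each non-excluded participant into one of three
non-overlapping primary categories:

* SEVERE          adjusted median TG > 885 mg/dl (10 mmol/L)
* MILD_MODERATE   300 mg/dl <= TG <= 885 mg/dl
* NORMAL          TG within the cohort's 25th–75th percentiles AND not on
                  lipid-lowering medication
* OTHER           everyone else (including 25th–75th percentile patients on
                  medication, who might be well-treated HTG)

Two sensitivity labels are assigned alongside: AHA_SEVERE (TG > 500 mg/dl)
and TOP1PCT (TG >= the cohort's 99th percentile, ties included).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MGDL_PER_MMOL",
    "ParticipantRecord",
    "TGCategory",
    "AdjustmentTable",
    "adjust_tg",
    "on_lipid_lowering",
    "assign_categories",
    "phenotype_cohort",
    "load_exclusion_config",
    "match_exclusions",
    "mgdl_to_mmol",
]

MGDL_PER_MMOL = 1 / 0.01129

EXCLUSION_FLAGS = ("metastatic_cancer", "hospice", "feeding_tube", "severe_malnutrition")

Date = _dt.date
Interval = tuple[Date, Optional[Date]]  # stop None = ongoing


def mgdl_to_mmol(tg_mg_dl: float) -> float:
    return tg_mg_dl * 0.01129


@dataclass
class ParticipantRecord:
    """Demographics, longitudinal TG measurements and medication exposures."""

    participant_id: str
    sex: str
    age_years: float
    bmi: float
    measurements: list[tuple[Date, float]] = field(default_factory=list)
    med_exposures: list[tuple[str, Interval]] = field(default_factory=list)
    excluded_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for _, tg in self.measurements:
            if not tg > 0:
                raise ValueError(f"TG measurements must be strictly positive, got {tg}")

    @property
    def excluded(self) -> bool:
        return any(self.excluded_flags.values())


@dataclass(frozen=True)
class TGCategory:
    """Primary category label plus sensitivity-definition flags."""

    label: str  # "SEVERE" | "MILD_MODERATE" | "NORMAL" | "OTHER"
    aha_severe: bool = False
    top1pct: bool = False


@dataclass(frozen=True)
class AdjustmentTable:
    """Drug class -> multiplicative correction factor (>= 1) for exposed measurements.

    A factor of 1.0 means no adjustment.  The default table inverts assumed
    fractional TG reductions (statin 15%, fibrate 30%, omega-3 25%, niacin
    20%), i.e. factor = 1 / (1 - reduction); the factors are configuration,
    not constants of the method.
    """

    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        for cls, f in self.factors.items():
            if f < 1.0:
                raise ValueError(f"adjustment factor for {cls!r} must be >= 1, got {f}")

    @classmethod
    def default(cls) -> "AdjustmentTable":
        reductions = {"statin": 0.15, "fibrate": 0.30, "omega3": 0.25, "niacin": 0.20}
        return cls({k: 1.0 / (1.0 - r) for k, r in reductions.items()})

    def factor(self, drug_class: str) -> float:
        return float(self.factors.get(drug_class, 1.0))


def _in_interval(day: Date, interval: Interval) -> bool:
    start, stop = interval
    return start <= day and (stop is None or day <= stop)


def adjust_tg(record: ParticipantRecord, table: AdjustmentTable) -> float:
    """Medication-adjusted median TG (mg/dl) for one participant.

    Each measurement overlapping an exposure interval is multiplied by its
    class factor (the largest factor when several classes overlap); the
    median of the adjusted values is returned (even-length lists: mean of
    the central pair).
    """
    if not record.measurements:
        raise ValueError(f"participant {record.participant_id}: no TG measurements")
    adjusted = []
    for day, tg in record.measurements:
        factor = 1.0
        for cls, interval in record.med_exposures:
            if _in_interval(day, interval):
                factor = max(factor, table.factor(cls))
        adjusted.append(tg * factor)
    return float(np.median(adjusted))


def on_lipid_lowering(record: ParticipantRecord) -> bool:
    """True if any exposure interval overlaps any TG measurement date."""
    return any(
        _in_interval(day, interval)
        for day, _ in record.measurements
        for _, interval in record.med_exposures
    )


def assign_categories(
    adjusted_tgs: Mapping[str, float],
    on_meds: Mapping[str, bool],
    excluded: Mapping[str, bool],
    severe_threshold: float = 885.0,
    mild_lower: float = 300.0,
    aha_threshold: float = 500.0,
    normal_band: tuple[float, float] = (0.25, 0.75),
    top_percent: float = 0.01,
) -> dict[str, TGCategory]:
    """Assign every non-excluded participant to exactly one TG category.

    Cohort percentiles (normal band bounds and the top-1% cutoff) are
    computed over all non-excluded participants with linear interpolation.
    Excluded participants receive no category.
    """
    pool = [pid for pid in adjusted_tgs if not excluded.get(pid, False)]
    if not pool:
        raise ValueError("empty cohort after exclusions; percentiles undefined")
    values = np.array([adjusted_tgs[p] for p in pool])
    p_lo, p_hi = np.percentile(values, [100 * normal_band[0], 100 * normal_band[1]])
    p_top = np.percentile(values, 100 * (1 - top_percent))

    out: dict[str, TGCategory] = {}
    for pid in pool:
        tg = adjusted_tgs[pid]
        if tg > severe_threshold:
            label = "SEVERE"
        elif mild_lower <= tg <= severe_threshold:
            label = "MILD_MODERATE"
        elif p_lo <= tg <= p_hi and not on_meds.get(pid, False):
            label = "NORMAL"
        else:
            label = "OTHER"
        out[pid] = TGCategory(
            label=label,
            aha_severe=tg > aha_threshold,
            top1pct=tg >= p_top,
        )
    return out


def phenotype_cohort(
    participants: Sequence[ParticipantRecord],
    table: AdjustmentTable | None = None,
    **category_kwargs,
) -> pd.DataFrame:
    """Phenotype table for a cohort: adjusted median TG plus category labels.

    Participants without any TG measurement do not meet the inclusion
    criterion and are dropped.  Columns: participant_id, adjusted_median_tg,
    on_lipid_lowering, excluded, category, aha_severe, top1pct (category
    columns are NA for excluded participants).
    """
    table = table or AdjustmentTable.default()
    included = [p for p in participants if p.measurements]
    adjusted = {p.participant_id: adjust_tg(p, table) for p in included}
    meds = {p.participant_id: on_lipid_lowering(p) for p in included}
    excl = {p.participant_id: p.excluded for p in included}
    cats = assign_categories(adjusted, meds, excl, **category_kwargs)
    rows = []
    for p in included:
        pid = p.participant_id
        cat = cats.get(pid)
        rows.append(
            {
                "participant_id": pid,
                "adjusted_median_tg": adjusted[pid],
                "on_lipid_lowering": meds[pid],
                "excluded": excl[pid],
                "category": cat.label if cat else pd.NA,
                "aha_severe": cat.aha_severe if cat else pd.NA,
                "top1pct": cat.top1pct if cat else pd.NA,
            }
        )
    return pd.DataFrame(rows)


def load_exclusion_config(path) -> dict[str, set[str]]:
    """Load an exclusion config mapping flag -> list of code strings (YAML or JSON)."""
    text = open(path).read()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        data = yaml.safe_load(text)
    return {flag: set(map(str, codes)) for flag, codes in data.items()}


def match_exclusions(
    participant_codes: Mapping[str, Iterable[str]],
    code_lists: Mapping[str, set[str]],
) -> dict[str, dict[str, bool]]:
    """Exact-string match of per-participant codes against exclusion code lists.

    Returns {participant_id: {flag: bool}} suitable for
    ``ParticipantRecord.excluded_flags``.
    """
    return {
        pid: {flag: bool(set(map(str, codes)) & codeset) for flag, codeset in code_lists.items()}
        for pid, codes in participant_codes.items()
    }
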