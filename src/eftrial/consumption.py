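"""Remote drinking-monitoring aggregation.

Participants report the previous day's drink count daily across three
monitoring phases (a 7-day baseline, then two intervention monitoring
phases).  This module turns the participant-day records into per-phase
summaries, applies the baseline harmful-drinking eligibility rules, and
exports an analysis-ready long-format daily table for external mixed-model
fitting.

Two denominators coexist deliberately: figure-style drinks/day divides total
drinks by *total calendar days* in the phase (missing days count in the
denominator), while the model export marks missing days as missing and
excludes nothing silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "DailyRecord",
    "PhaseSummary",
    "summarize_phase",
    "summarize_all_phases",
    "baseline_eligibility",
    "long_format_export",
]

PHASES = ("baseline", "monitoring1", "monitoring2")

HEAVY_DAY_DRINKS = 4  # >= 4 drinks marks a heavy drinking day


@dataclass
class DailyRecord:
    """One participant-day of remote monitoring."""

    participant: str
    day_index: int
    phase: str
    reported_drinks: int | None  # None = submission missing
    breath_samples: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.reported_drinks is not None and self.reported_drinks < 0:
            raise ValueError("reported_drinks must be >= 0")
        if any(b < 0 for b in self.breath_samples):
            raise ValueError("BrAC values must be >= 0")


@dataclass
class PhaseSummary:
    participant: str
    phase: str
    total_days: int
    reported_days: int
    drinking_days: int
    total_drinks: int
    drinks_per_day: float                    # total-calendar-day denominator
    drinks_per_reported_day: float | None    # reported-day denominator
    drinks_per_drinking_day: float | None    # None when no drinking days


def summarize_phase(records: list[DailyRecord]) -> PhaseSummary:
    """Aggregate one participant-phase.

    Missing reports contribute to total_days only.  drinks_per_day uses the
    total calendar days of the phase as denominator; drinks_per_drinking_day
    is None (undefined, never zero-filled) when there are no drinking days.
    """
    if not records:
        raise ValueError("empty record list")
    phases = {r.phase for r in records}
    participants = {r.participant for r in records}
    if len(phases) != 1 or len(participants) != 1:
        raise ValueError("records must be a single participant-phase")
    reported = [r.reported_drinks for r in records if r.reported_drinks is not None]
    total_drinks = int(sum(reported))
    drinking_days = sum(1 for d in reported if d >= 1)
    total_days = len(records)
    return PhaseSummary(
        participant=next(iter(participants)),
        phase=next(iter(phases)),
        total_days=total_days,
        reported_days=len(reported),
        drinking_days=drinking_days,
        total_drinks=total_drinks,
        drinks_per_day=total_drinks / total_days,
        drinks_per_reported_day=(total_drinks / len(reported)
                                 if reported else None),
        drinks_per_drinking_day=(total_drinks / drinking_days
                                 if drinking_days >= 1 else None),
    )


def summarize_all_phases(daily: pd.DataFrame) -> pd.DataFrame:
    """Per participant x phase summaries from a long daily table.

    ``daily`` needs columns participant, day_index, phase, reported_drinks
    (NaN = missing).  Returns one row per participant-phase.
    """
    rows = []
    for (pid, phase), g in daily.groupby(["participant", "phase"], sort=True):
        recs = [
            DailyRecord(str(pid), int(r.day_index), str(phase),
                        None if pd.isna(r.reported_drinks) else int(r.reported_drinks))
            for r in g.itertuples()
        ]
        s = summarize_phase(recs)
        rows.append({
            "participant": s.participant, "phase": s.phase,
            "total_days": s.total_days, "reported_days": s.reported_days,
            "drinking_days": s.drinking_days, "total_drinks": s.total_drinks,
            "drinks_per_day": s.drinks_per_day,
            "drinks_per_reported_day": (np.nan if s.drinks_per_reported_day is None
                                        else s.drinks_per_reported_day),
            "drinks_per_drinking_day": (np.nan if s.drinks_per_drinking_day is None
                                        else s.drinks_per_drinking_day),
        })
    return pd.DataFrame(rows)


def baseline_eligibility(records: list[DailyRecord]) -> tuple[bool, list[str]]:
    """Apply the 7-day baseline continuation rules.

    Eligible iff the participant reported on >= 5 of the 7 days, drank on
    >= 4 days, and showed harmful drinking: >= 4 days of >= 4 drinks, or an
    average of more than 4 drinks per drinking day.  Returns the flag and
    the list of every failed clause.
    """
    if len(records) != 7:
        raise ValueError("baseline eligibility requires exactly 7 days of records")
    s = summarize_phase(records)
    reasons: list[str] = []
    if s.reported_days < 5:
        reasons.append(f"reported on {s.reported_days}/7 days (< 5 required)")
    if s.drinking_days < 4:
        reasons.append(f"{s.drinking_days} drinking days (< 4 required)")
    heavy_days = sum(1 for r in records
                     if r.reported_drinks is not None
                     and r.reported_drinks >= HEAVY_DAY_DRINKS)
    mean_ok = (s.drinks_per_drinking_day is not None
               and s.drinks_per_drinking_day > 4.0)
    if heavy_days < 4 and not mean_ok:
        reasons.append(
            f"{heavy_days} days of >=4 drinks (< 4) and "
            "drinks/drinking day not > 4")
    return (not reasons), reasons


def long_format_export(daily: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """One row per participant-day with outcome, phase, group and covariates.

    Missing drink counts stay as missing values (NaN) — they are marked,
    not dropped nor zero-filled — so the frame is directly usable for
    mixed-model fitting outside the package.
    """
    dup = daily.duplicated(["participant", "day_index"])
    if dup.any():
        bad = daily.loc[dup, ["participant", "day_index"]].iloc[0]
        raise ValueError(
            f"duplicate participant-day row: {bad.participant} day {bad.day_index}")
    covars = ["participant", "group", "age", "sex", "ethnicity", "race",
              "education", "income", "audit_score"]
    covars = [c for c in covars if c in profiles.columns]
    base = daily[["participant", "day_index", "phase", "reported_drinks"]]
    out = base.merge(profiles[covars], on="participant", how="left",
                     validate="many_to_one")
    cols = ["participant", "day_index", "phase", "reported_drinks"] + \
        [c for c in covars if c != "participant"]
    return out[cols].sort_values(["participant", "day_index"]).reset_index(drop=True)
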