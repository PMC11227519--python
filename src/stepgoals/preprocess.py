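"""Cleaning, filtering and aggregation of raw 30-minute step blocks.

Raw inputs are block records (participant, date, block index 0-47, steps)
and self-reported profiles (sex, age, height, weight, pledge flag).  The
rules implemented here:

* blocks with index outside 0-47, non-integer index, or negative steps are
  removed (and counted by reason);
* a participant-day with at least one positive block yields a 24-hour
  vector, with absent blocks imputed as zero (hour h = block 2h + 2h+1);
  days with no positive block are dropped;
* profiles are kept only with complete data, age >= 17, weight in
  [30, 300] kg, height in [101, 220] cm and pledge = False;
* age and BMI groups use half-open, lower-inclusive boundaries;
* the analysis window is 2018-01-08 .. 2018-03-31 and weekend days are
  Saturday and Sunday.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .twopart import age_group_of, bmi_group_of

__all__ = [
    "HOUR_COLS",
    "STUDY_START",
    "STUDY_END",
    "CleaningLog",
    "clean_blocks",
    "impute_and_aggregate",
    "filter_profiles",
    "derive_groups",
    "restrict_window_and_daytype",
    "cumulative_matrix",
]

HOUR_COLS = [f"h{h:02d}" for h in range(24)]
STUDY_START = dt.date(2018, 1, 8)
STUDY_END = dt.date(2018, 3, 31)


@dataclass
class CleaningLog:
    """Per-rule removal counts; removals sum to input minus output."""

    n_input: int = 0
    n_output: int = 0
    n_bad_block_index: int = 0
    n_non_integer_index: int = 0
    n_negative_steps: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def clean_blocks(records: pd.DataFrame) -> tuple[pd.DataFrame, CleaningLog]:
    """Drop implausible block records.

    Removes non-integer block indices, indices outside 0-47, and negative
    step counts, logging each reason.  Idempotent.
    """
    df = records.copy()
    log = CleaningLog(n_input=len(df))

    idx = pd.to_numeric(df["block_index"], errors="coerce")
    non_integer = idx.isna() | (idx != np.floor(idx))
    log.n_non_integer_index = int(non_integer.sum())
    df = df[~non_integer]
    idx = idx[~non_integer].astype(int)

    bad_range = (idx < 0) | (idx > 47)
    log.n_bad_block_index = int(bad_range.sum())
    df = df[~bad_range.to_numpy()]

    steps = pd.to_numeric(df["steps"], errors="coerce")
    negative = steps.isna() | (steps < 0)
    log.n_negative_steps = int(negative.sum())
    df = df[~negative.to_numpy()]

    df = df.assign(
        block_index=df["block_index"].astype(int), steps=df["steps"].astype(int)
    ).reset_index(drop=True)
    log.n_output = len(df)
    return df, log


def impute_and_aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate cleaned blocks to hourly participant-days.

    A day is emitted only if some block that day is positive; missing
    blocks count as zero.  Duplicate (participant, date, block) records
    are summed with a warning.
    """
    cols = ["participant_id", "date", "block_index", "steps"]
    df = records[cols].copy()
    if df.empty:
        return pd.DataFrame(
            columns=["participant_id", "date", *HOUR_COLS, "daily_total"]
        )
    n_dup = int(df.duplicated(subset=cols[:3]).sum())
    if n_dup:
        warnings.warn(f"summed {n_dup} duplicate (participant, date, block) records")
    df = df.groupby(cols[:3], as_index=False)["steps"].sum()

    any_positive = df.groupby(["participant_id", "date"])["steps"].transform("max") > 0
    df = df[any_positive]
    if df.empty:
        return pd.DataFrame(
            columns=["participant_id", "date", *HOUR_COLS, "daily_total"]
        )

    df["hour"] = df["block_index"] // 2
    wide = (
        df.groupby(["participant_id", "date", "hour"])["steps"]
        .sum()
        .unstack("hour", fill_value=0)
        .reindex(columns=range(24), fill_value=0)
    )
    wide.columns = HOUR_COLS
    wide = wide.reset_index()
    wide["daily_total"] = wide[HOUR_COLS].sum(axis=1)
    return wide


def filter_profiles(profiles: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Keep plausible non-pledge profiles; tally exclusions by first rule hit.

    Reasons (checked in order): missing, age, weight, height, pledge.
    """
    df = profiles.copy()
    reasons = {"missing": 0, "age": 0, "weight": 0, "height": 0, "pledge": 0}
    age = pd.to_numeric(df.get("age"), errors="coerce")
    height = pd.to_numeric(df.get("height_cm"), errors="coerce")
    weight = pd.to_numeric(df.get("weight_kg"), errors="coerce")
    sex = df.get("sex")

    missing = age.isna() | height.isna() | weight.isna() | sex.isna()
    bad_age = ~missing & (age < 17)
    bad_weight = ~missing & ~bad_age & ((weight < 30) | (weight > 300))
    bad_height = ~missing & ~bad_age & ~bad_weight & ((height < 101) | (height > 220))
    pledge = df["pledge"].astype(bool) if "pledge" in df else pd.Series(False, index=df.index)
    bad_pledge = ~missing & ~bad_age & ~bad_weight & ~bad_height & pledge

    reasons["missing"] = int(missing.sum())
    reasons["age"] = int(bad_age.sum())
    reasons["weight"] = int(bad_weight.sum())
    reasons["height"] = int(bad_height.sum())
    reasons["pledge"] = int(bad_pledge.sum())

    keep = ~(missing | bad_age | bad_weight | bad_height | bad_pledge)
    return df[keep].reset_index(drop=True), reasons


def derive_groups(profiles: pd.DataFrame) -> pd.DataFrame:
    """Attach age_group, bmi and bmi_group columns.

    BMI = weight / (height/100)^2; group boundaries are lower-inclusive.
    """
    df = profiles.copy()
    df["bmi"] = df["weight_kg"] / (df["height_cm"] / 100.0) ** 2
    df["age_group"] = [age_group_of(a) for a in df["age"]]
    df["bmi_group"] = [bmi_group_of(b) for b in df["bmi"]]
    return df


def restrict_window_and_daytype(
    days: pd.DataFrame,
    start: dt.date = STUDY_START,
    end: dt.date = STUDY_END,
) -> tuple[pd.DataFrame, dict]:
    """Keep dates inside [start, end] and label weekday/weekend.

    Unparseable dates are rejected and counted in the returned log.
    """
    df = days.copy()
    parsed = pd.to_datetime(df["date"], errors="coerce")
    n_unparseable = int(parsed.isna().sum())
    in_window = (
        parsed.notna()
        & (parsed >= pd.Timestamp(start))
        & (parsed <= pd.Timestamp(end))
    )
    log = {
        "n_input": len(df),
        "n_unparseable_date": n_unparseable,
        "n_outside_window": int((~in_window).sum()) - n_unparseable,
        "n_output": int(in_window.sum()),
    }
    df = df[in_window].copy()
    parsed = parsed[in_window]
    df["date"] = parsed.dt.date
    df["day_type"] = np.where(parsed.dt.dayofweek >= 5, "weekend", "weekday")
    return df.reset_index(drop=True), log


def cumulative_matrix(days: pd.DataFrame) -> np.ndarray:
    """Running totals over the 24 hourly columns, shape (n_days, 24)."""
    return days[HOUR_COLS].to_numpy(dtype=float).cumsum(axis=1)
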