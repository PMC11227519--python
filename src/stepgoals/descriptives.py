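"""Descriptive layer: incentive accounting, summaries and the group test.

Includes the reward-schedule arithmetic (10/25/40 points at daily totals of
5000/7500/10,000 steps, first tier at 750 points), daily and hourly
summaries, goal-band tabulations, and a cluster-robust joint test for
differences in mean daily steps between demographic groups.

The cluster test regresses daily totals on k-1 group dummies, computes the
CR1 sandwich covariance (small-sample factor G/(G-1) x (N-1)/(N-k)), and
tests that all dummy coefficients are jointly zero with a Wald-type F
statistic referred to F(k-1, G-1).  With singleton clusters the CR1
covariance coincides with the HC1 heteroskedasticity-robust sandwich.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RewardSchedule",
    "DEFAULT_SCHEDULE",
    "healthpoints_for_day",
    "days_to_complete_tier",
    "percent",
    "goal_band_table",
    "DailySummary",
    "daily_summary",
    "hourly_summary",
    "ClusterTestResult",
    "cluster_robust_group_test",
]


@dataclass(frozen=True)
class RewardSchedule:
    """Step thresholds with the points each daily total earns."""

    thresholds: tuple = (5_000, 7_500, 10_000)
    points: tuple = (10, 25, 40)
    first_tier_points: int = 750

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.points):
            raise ValueError("thresholds and points must align")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if any(b < a for a, b in zip(self.points, self.points[1:])):
            raise ValueError("points must be non-decreasing")


DEFAULT_SCHEDULE = RewardSchedule()


def healthpoints_for_day(
    daily_total: float, schedule: RewardSchedule = DEFAULT_SCHEDULE
) -> int:
    """Points earned for one day's total; thresholds are inclusive."""
    if daily_total < 0:
        raise ValueError(f"daily_total must be >= 0, got {daily_total}")
    earned = 0
    for threshold, pts in zip(schedule.thresholds, schedule.points):
        if daily_total >= threshold:
            earned = pts
    return earned


def days_to_complete_tier(tier_points: float, points_per_day: float) -> int:
    """ceiling(tier_points / points_per_day)."""
    if tier_points < 0:
        raise ValueError("tier_points must be >= 0")
    if points_per_day <= 0:
        raise ValueError("points_per_day must be > 0")
    return math.ceil(tier_points / points_per_day)


def percent(count: float, total: float, ndigits: int = 1) -> float:
    """100 * count / total, rounded."""
    if total <= 0:
        raise ValueError("total must be > 0")
    return round(100.0 * count / total, ndigits)


def goal_band_table(
    daily_totals: np.ndarray, schedule: RewardSchedule = DEFAULT_SCHEDULE
) -> pd.DataFrame:
    """Counts and percentages of days per goal band (<T1, [T1,T2), ..., >=Tk)."""
    totals = np.asarray(daily_totals, dtype=float)
    if totals.size == 0:
        raise ValueError("no daily totals")
    edges = list(schedule.thresholds)
    bands = np.searchsorted(edges, totals, side="right")
    labels = [f"<{edges[0]}"]
    labels += [f"{lo}-{hi - 1}" for lo, hi in zip(edges[:-1], edges[1:])]
    labels += [f">={edges[-1]}"]
    counts = np.bincount(bands, minlength=len(labels))
    return pd.DataFrame(
        {
            "band": labels,
            "n_days": counts,
            "percent": [percent(c, totals.size, 1) for c in counts],
        }
    )


@dataclass
class DailySummary:
    grouping: str
    per_level: pd.DataFrame  # level, n_days, mean, sd
    overall: dict  # n_days, mean, sd
    bands: pd.DataFrame
    test: "ClusterTestResult"


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return float(x.mean()), sd


def daily_summary(
    participant_days: pd.DataFrame,
    profiles: pd.DataFrame,
    grouping: str,
    schedule: RewardSchedule = DEFAULT_SCHEDULE,
) -> DailySummary:
    """Mean/SD of daily totals by group, overall, goal bands and joint test.

    Every participant-day must join to a profile carrying the grouping
    column (one of age_group, bmi_group, sex).
    """
    if grouping not in ("age_group", "bmi_group", "sex"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if grouping not in profiles.columns:
        raise ValueError(f"profiles lack a {grouping!r} column; derive groups first")
    merged = participant_days.merge(
        profiles[["participant_id", grouping]], on="participant_id", how="left"
    )
    if merged[grouping].isna().any():
        orphans = merged.loc[merged[grouping].isna(), "participant_id"].unique()
        raise ValueError(f"participant-days without a profile: {list(orphans)[:5]}")

    rows = []
    for level, grp in merged.groupby(grouping, sort=True):
        mean, sd = _mean_sd(grp["daily_total"])
        rows.append({"level": level, "n_days": len(grp), "mean": mean, "sd": sd})
    per_level = pd.DataFrame(rows)
    mean, sd = _mean_sd(merged["daily_total"])
    overall = {"n_days": len(merged), "mean": mean, "sd": sd}
    bands = goal_band_table(merged["daily_total"].to_numpy(), schedule)
    test = cluster_robust_group_test(
        merged["daily_total"].to_numpy(),
        merged[grouping].to_numpy(),
        merged["participant_id"].to_numpy(),
    )
    return DailySummary(grouping, per_level, overall, bands, test)


def hourly_summary(
    participant_days: pd.DataFrame, stratifier: str = "day_type"
) -> pd.DataFrame:
    """Per (hour, stratifier level): mean steps and proportion of zeros."""
    hour_cols = [f"h{h:02d}" for h in range(24)]
    if stratifier not in participant_days.columns:
        raise ValueError(f"no column {stratifier!r} in participant_days")
    long = participant_days.melt(
        id_vars=[stratifier], value_vars=hour_cols, var_name="hour", value_name="steps"
    )
    long["hour"] = long["hour"].str[1:].astype(int)
    out = (
        long.groupby([stratifier, "hour"])["steps"]
        .agg(mean_steps="mean", prop_zero=lambda s: float(np.mean(s == 0)))
        .reset_index()
    )
    return out


@dataclass
class ClusterTestResult:
    statistic: float  # joint F
    p_value: float
    df_num: int
    df_den: int
    n_clusters: int
    coefficients: pd.DataFrame  # term, estimate, se, t
    covariance: np.ndarray = field(repr=False)


def cluster_robust_group_test(
    daily_totals: np.ndarray,
    group_labels: np.ndarray,
    cluster_ids: np.ndarray,
) -> ClusterTestResult:
    """Joint F test of group differences with cluster-sandwich errors.

    Fits OLS of the outcome on an intercept and k-1 dummies (reference =
    first sorted level), computes the CR1 cluster covariance, and tests
    H0: all dummy coefficients are zero against F(k-1, G-1).
    """
    y = np.asarray(daily_totals, dtype=float)
    groups = np.asarray(group_labels)
    clusters = np.asarray(cluster_ids)
    if not (len(y) == len(groups) == len(clusters)):
        raise ValueError("inputs must have equal length")
    levels = sorted(pd.unique(groups))
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 group levels")
    terms = ["intercept"] + [f"group[{lv}]" for lv in levels[1:]]
    X = np.column_stack(
        [np.ones(len(y))] + [(groups == lv).astype(float) for lv in levels[1:]]
    )
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        full = np.linalg.matrix_rank(X)
        for j in range(p):
            rest = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(rest) == full:
                raise ValueError(f"design is rank deficient at column {terms[j]!r}")
        raise ValueError("design is rank deficient")
    uniq = pd.unique(clusters)
    G = len(uniq)
    if G < 2:
        raise ValueError("need at least 2 clusters")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    bread = np.linalg.inv(X.T @ X)
    scores = X * resid[:, None]
    # sum within clusters, then outer products
    score_df = pd.DataFrame(scores).groupby(clusters).sum().to_numpy()
    meat = score_df.T @ score_df
    scale = (G / (G - 1.0)) * ((n - 1.0) / (n - p))
    V = scale * bread @ meat @ bread
    V = (V + V.T) / 2.0

    q = k - 1
    b = beta[1:]
    Vb = V[1:, 1:]
    F = float(b @ np.linalg.solve(Vb, b)) / q
    p_value = float(stats.f.sf(F, q, G - 1))
    se = np.sqrt(np.maximum(np.diag(V), 0.0))  # guard tiny negative round-off
    with np.errstate(divide="ignore"):
        t_stats = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
    coef = pd.DataFrame({"term": terms, "estimate": beta, "se": se, "t": t_stats})
    return ClusterTestResult(F, p_value, q, G - 1, G, coef, V)
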