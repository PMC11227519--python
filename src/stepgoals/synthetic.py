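"""Synthetic tracker data with the structure the analysis assumes.

The real programme data are restricted, so this module generates stand-in
data: participant profiles with configurable demographic marginals, and
intra-day step counts drawn from the same hour x day-type x stratum
two-part model the inference module fits.  Because generation goes through
``compile_truth`` -- which turns the configured diurnal profile, covariate
multipliers and stratum multipliers into exact per-cell coefficient
vectors -- the generating parameters are retrievable for parameter
recovery tests.

The generative process is this artifact's own construction; the source
study describes no generator.  Its shape is chosen to emulate the stylised
facts the analysis needs: tri-modal weekday / bi-modal weekend activity,
a high proportion of zero hours, right-skewed positive counts, demographic
effects, and (via ``goal_boost``) a bunching spike just above the daily
goals.  The goal boost perturbs the pure two-part process, so recovery
experiments should disable it.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .twopart import (
    AGE_GROUPS,
    BMI_GROUPS,
    DAY_TYPES,
    EVENING_STRATA,
    MORNING,
    SEXES,
    STRATUM_EDGES,
    ModelCellKey,
    TwoPartParameters,
    age_group_of,
    bmi_group_of,
    design_matrix,
)

__all__ = [
    "GeneratorConfig",
    "default_marginals",
    "default_diurnal_profile",
    "default_covariate_effects",
    "default_stratum_effects",
    "generate_profiles",
    "compile_truth",
    "generate_hourly_steps",
    "emit_block_records",
]

GOALS = (5_000.0, 7_500.0, 10_000.0)

_AGE_RANGES = {
    "17-29": (17, 29),
    "30-39": (30, 39),
    "40-49": (40, 49),
    "50-59": (50, 59),
    ">=60": (60, 79),
}
_BMI_RANGES = {
    "<18.5": (16.0, 18.5),
    "18.5-22.9": (18.5, 23.0),
    "23-27.4": (23.0, 27.5),
    ">=27.5": (27.5, 35.0),
}


def default_marginals() -> dict:
    """Category -> probability maps approximating the study's demographics."""
    return {
        "sex": {"female": 0.596, "male": 0.404},
        "age_group": {
            "17-29": 0.148,
            "30-39": 0.250,
            "40-49": 0.252,
            "50-59": 0.208,
            ">=60": 0.142,
        },
        "bmi_group": {
            "<18.5": 0.042,
            "18.5-22.9": 0.283,
            "23-27.4": 0.391,
            ">=27.5": 0.284,
        },
    }


# (activity probability, mean positive steps) for the reference participant.
# Weekday: commute (7-9), lunch (12-14) and evening (18-20) peaks.
# Weekend: late-morning (9-11) and early-evening (17-19) peaks.
_WEEKDAY_PROFILE = {
    0: (0.05, 100), 1: (0.03, 80), 2: (0.02, 80), 3: (0.02, 80),
    4: (0.03, 100), 5: (0.15, 200), 6: (0.50, 500), 7: (0.80, 1000),
    8: (0.85, 950), 9: (0.75, 400), 10: (0.70, 350), 11: (0.75, 450),
    12: (0.85, 900), 13: (0.80, 650), 14: (0.70, 350), 15: (0.70, 350),
    16: (0.70, 400), 17: (0.80, 650), 18: (0.85, 1100), 19: (0.80, 1000),
    20: (0.70, 500), 21: (0.60, 350), 22: (0.45, 250), 23: (0.25, 150),
}
_WEEKEND_PROFILE = {
    0: (0.05, 100), 1: (0.03, 80), 2: (0.02, 80), 3: (0.02, 80),
    4: (0.03, 100), 5: (0.08, 150), 6: (0.20, 200), 7: (0.35, 300),
    8: (0.60, 550), 9: (0.80, 1000), 10: (0.80, 950), 11: (0.70, 500),
    12: (0.70, 500), 13: (0.65, 400), 14: (0.60, 350), 15: (0.60, 380),
    16: (0.65, 450), 17: (0.75, 850), 18: (0.75, 900), 19: (0.65, 500),
    20: (0.55, 350), 21: (0.50, 300), 22: (0.40, 200), 23: (0.20, 120),
}


def default_diurnal_profile() -> dict:
    profile = {}
    for h, v in _WEEKDAY_PROFILE.items():
        profile[("weekday", h)] = v
    for h, v in _WEEKEND_PROFILE.items():
        profile[("weekend", h)] = v
    return profile


def default_covariate_effects() -> dict:
    """(category, level) -> (activity odds multiplier, positive-mean multiplier)."""
    return {
        ("age_group", "30-39"): (1.00, 1.00),
        ("age_group", "40-49"): (1.10, 1.05),
        ("age_group", "50-59"): (1.15, 1.08),
        ("age_group", ">=60"): (1.35, 1.10),
        ("bmi_group", "<18.5"): (0.95, 0.95),
        ("bmi_group", "23-27.4"): (1.05, 1.04),
        ("bmi_group", ">=27.5"): (0.85, 0.92),
        ("sex", "male"): (1.00, 1.12),
    }


def default_stratum_effects() -> dict:
    """Multipliers on the evening intercepts by accumulated-step stratum:
    motivation fades once goals are passed."""
    return {
        "S1": (1.00, 1.00),
        "S2": (0.95, 0.95),
        "S3": (0.90, 0.92),
        "S4": (0.65, 0.80),
    }


@dataclass
class GeneratorConfig:
    n_participants: int = 50
    date_start: dt.date = dt.date(2018, 1, 8)
    date_end: dt.date = dt.date(2018, 1, 21)
    demographic_marginals: dict = field(default_factory=default_marginals)
    diurnal_profile: dict = field(default_factory=default_diurnal_profile)
    dispersion: float = 1.5  # gamma shape of positive hourly counts
    covariate_effects: dict = field(default_factory=default_covariate_effects)
    stratum_effects: dict = field(default_factory=default_stratum_effects)
    cum_effect: tuple = (-0.4, -0.3)  # (logit, log-mean) slope on cum/10,000
    goal_boost: tuple = (500.0, 0.35)  # (window_steps, boost probability)
    boost_hours: tuple = tuple(range(18, 24))
    corruption_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if self.date_start > self.date_end:
            raise ValueError("date_start must be <= date_end")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0")
        expected_levels = {
            "sex": SEXES,
            "age_group": AGE_GROUPS,
            "bmi_group": BMI_GROUPS,
        }
        for category, levels in expected_levels.items():
            probs = self.demographic_marginals.get(category)
            if probs is None:
                raise ValueError(f"missing marginals for category {category!r}")
            if set(probs) != set(levels):
                raise ValueError(
                    f"marginals for {category!r} must cover levels {levels}"
                )
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"marginals for category {category!r} sum to {total:.6f}, not 1"
                )
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"negative probability in category {category!r}")
        for key, (p, mean) in self.diurnal_profile.items():
            day_type, hour = key
            if day_type not in DAY_TYPES:
                raise ValueError(f"unknown day_type {day_type!r} in diurnal profile")
            if not (isinstance(hour, (int, np.integer)) and 0 <= hour <= 23):
                raise ValueError(f"hour {hour!r} outside 0-23 in diurnal profile")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"activity probability {p} outside [0,1] at {key}")
            if not mean > 0:
                raise ValueError(f"mean positive steps must be > 0 at {key}")
        for day_type in DAY_TYPES:
            for hour in range(24):
                if (day_type, hour) not in self.diurnal_profile:
                    raise ValueError(f"diurnal profile missing ({day_type!r}, {hour})")
        window, prob = self.goal_boost
        if window < 0 or not 0.0 <= prob <= 1.0:
            raise ValueError("goal_boost must be (window >= 0, probability in [0,1])")
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise ValueError("corruption_rate must be in [0,1]")

    def without_boost(self) -> "GeneratorConfig":
        return replace(self, goal_boost=(self.goal_boost[0], 0.0))


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_profiles(config: GeneratorConfig) -> pd.DataFrame:
    """Draw participant profiles from the configured marginals.

    Age is uniform within its band, BMI uniform within its band, height
    normal by sex, and weight is back-computed from BMI and height.
    Deterministic given the config seed.
    """
    config.validate()
    rng = _rng(config, 11)
    n = config.n_participants
    columns = ["participant_id", "sex", "age", "height_cm", "weight_kg", "pledge"]
    if n == 0:
        return pd.DataFrame(columns=columns)

    marg = config.demographic_marginals
    sex_levels, sex_p = zip(*sorted(marg["sex"].items()))
    age_levels, age_p = zip(*[(g, marg["age_group"][g]) for g in AGE_GROUPS])
    bmi_levels, bmi_p = zip(*[(g, marg["bmi_group"][g]) for g in BMI_GROUPS])

    sex = rng.choice(sex_levels, size=n, p=np.asarray(sex_p) / sum(sex_p))
    age_group = rng.choice(age_levels, size=n, p=np.asarray(age_p) / sum(age_p))
    bmi_group = rng.choice(bmi_levels, size=n, p=np.asarray(bmi_p) / sum(bmi_p))

    lo = np.array([_AGE_RANGES[g][0] for g in age_group])
    hi = np.array([_AGE_RANGES[g][1] for g in age_group])
    age = rng.integers(lo, hi + 1)

    mean_height = np.where(sex == "male", 170.5, 158.5)
    height = np.clip(rng.normal(mean_height, 6.0), 145.0, 195.0).round(1)

    blo = np.array([_BMI_RANGES[g][0] for g in bmi_group])
    bhi = np.array([_BMI_RANGES[g][1] for g in bmi_group])
    bmi = rng.uniform(blo, np.nextafter(bhi, blo))
    weight = np.clip(bmi * (height / 100.0) ** 2, 30.0, 300.0).round(1)

    return pd.DataFrame(
        {
            "participant_id": [f"P{i:05d}" for i in range(n)],
            "sex": sex,
            "age": age.astype(int),
            "height_cm": height,
            "weight_kg": weight,
            "pledge": False,
        }
    )


def compile_truth(config: GeneratorConfig) -> dict[ModelCellKey, TwoPartParameters]:
    """Exact two-part parameters per model cell implied by the config.

    This is the ground-truth record store: the coefficient vectors returned
    here drive ``generate_hourly_steps`` and are what a correct fit should
    recover (goal boost disabled).
    """
    config.validate()
    beta_cov, gamma_cov = [], []
    for category, levels, ref in (
        ("age_group", AGE_GROUPS, AGE_GROUPS[0]),
        ("bmi_group", BMI_GROUPS, BMI_GROUPS[1]),
        ("sex", SEXES, "female"),
    ):
        for level in levels:
            if level == ref:
                continue
            odds_mult, mean_mult = config.covariate_effects.get(
                (category, level), (1.0, 1.0)
            )
            beta_cov.append(np.log(odds_mult))
            gamma_cov.append(np.log(mean_mult))

    truth: dict[ModelCellKey, TwoPartParameters] = {}
    b_cum, g_cum = config.cum_effect
    for day_type in DAY_TYPES:
        for hour in range(24):
            p0, m0 = config.diurnal_profile[(day_type, hour)]
            base_logit = float(logit(np.clip(p0, 1e-6, 1.0 - 1e-6)))
            base_logmean = float(np.log(m0))
            if hour < 12:
                key = ModelCellKey(hour, day_type, MORNING)
                truth[key] = TwoPartParameters(
                    beta=np.array([base_logit, *beta_cov]),
                    gamma=np.array([base_logmean, *gamma_cov]),
                    alpha=config.dispersion,
                )
            else:
                for stratum in EVENING_STRATA:
                    so, sm = config.stratum_effects.get(stratum, (1.0, 1.0))
                    key = ModelCellKey(hour, day_type, stratum)
                    truth[key] = TwoPartParameters(
                        beta=np.array([base_logit + np.log(so), *beta_cov, b_cum]),
                        gamma=np.array([base_logmean + np.log(sm), *gamma_cov, g_cum]),
                        alpha=config.dispersion,
                    )
    return truth


def generate_hourly_steps(
    profiles: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Simulate hourly counts for every profile x calendar day.

    Each hour is drawn from the compiled two-part cell selected by the
    day type and the stratum of the running total.  In boost hours, a
    participant sitting within ``window_steps`` below the nearest unmet
    goal makes a push with the configured probability, landing just above
    the goal; the push switches off once that goal is crossed.
    """
    config.validate()
    columns = ["participant_id", "date", *[f"h{h:02d}" for h in range(24)], "daily_total"]
    if profiles.empty:
        return pd.DataFrame(columns=columns)

    rng = _rng(config, 23)
    truth = compile_truth(config)

    bmi = profiles["weight_kg"] / (profiles["height_cm"] / 100.0) ** 2
    D = design_matrix(
        [age_group_of(a) for a in profiles["age"]],
        [bmi_group_of(b) for b in bmi],
        list(profiles["sex"]),
    )  # (n_participants, 9)

    dates = pd.date_range(config.date_start, config.date_end, freq="D")
    n_p, n_d = len(profiles), len(dates)
    pid_idx = np.repeat(np.arange(n_p), n_d)
    date_idx = np.tile(np.arange(n_d), n_p)
    is_weekend = np.tile(dates.dayofweek.to_numpy() >= 5, n_p)
    n_rows = n_p * n_d

    window, boost_p = config.goal_boost
    goals = np.asarray(GOALS)
    edges = np.asarray(STRATUM_EDGES)

    cum = np.zeros(n_rows)
    hourly = np.zeros((n_rows, 24), dtype=np.int64)
    for h in range(24):
        y = np.zeros(n_rows)
        labels = None if h < 12 else np.searchsorted(edges, cum, side="right")
        for day_type in DAY_TYPES:
            dmask = is_weekend if day_type == "weekend" else ~is_weekend
            strata = (MORNING,) if h < 12 else EVENING_STRATA
            for s_idx, stratum in enumerate(strata):
                mask = dmask if h < 12 else dmask & (labels == s_idx)
                rows = np.flatnonzero(mask)
                if rows.size == 0:
                    continue
                params = truth[ModelCellKey(h, day_type, stratum)]
                Xsel = D[pid_idx[rows]]
                eta_b = Xsel @ params.beta[:9]
                eta_g = Xsel @ params.gamma[:9]
                if h >= 12:
                    sc = cum[rows] / 10_000.0
                    eta_b = eta_b + params.beta[9] * sc
                    eta_g = eta_g + params.gamma[9] * sc
                p = expit(eta_b)
                active = rng.random(rows.size) < p
                if active.any():
                    mu = np.exp(eta_g[active])
                    draws = rng.gamma(config.dispersion, mu / config.dispersion)
                    y[rows[active]] = np.maximum(1.0, np.rint(draws))
        if boost_p > 0 and h in config.boost_hours:
            next_idx = np.searchsorted(goals, cum, side="right")
            has_goal = next_idx < len(goals)
            gap = np.where(has_goal, goals[np.minimum(next_idx, 2)] - cum, np.inf)
            eligible = has_goal & (gap > 0) & (gap <= window)
            push = eligible & (rng.random(n_rows) < boost_p)
            if push.any():
                overshoot = rng.gamma(2.0, 100.0, int(push.sum()))
                y[push] = np.maximum(y[push], np.rint(gap[push] + overshoot))
        cum += y
        hourly[:, h] = y.astype(np.int64)

    out = pd.DataFrame(hourly, columns=[f"h{h:02d}" for h in range(24)])
    out.insert(0, "date", dates.date[date_idx])
    out.insert(0, "participant_id", profiles["participant_id"].to_numpy()[pid_idx])
    out["daily_total"] = hourly.sum(axis=1)
    return out


def emit_block_records(
    participant_days: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Round-trip hourly data to the raw 30-minute block format.

    Each hour's count is split binomially across its two blocks (sums are
    conserved exactly); zero blocks are omitted, matching raw feeds where
    empty blocks are simply absent.  With ``corruption_rate > 0``, invalid
    records (block index >= 48 or negative steps) are appended and listed
    in the returned sidecar table for test assertions.
    """
    rng = _rng(config, 37)
    hour_cols = [f"h{h:02d}" for h in range(24)]
    if participant_days.empty:
        empty = pd.DataFrame(columns=["participant_id", "date", "block_index", "steps"])
        return empty, empty.assign(reason=pd.Series(dtype=object))

    counts = participant_days[hour_cols].to_numpy(dtype=np.int64)
    n_days = counts.shape[0]
    pid = np.repeat(participant_days["participant_id"].to_numpy(), 24)
    date = np.repeat(participant_days["date"].to_numpy(), 24)
    hour = np.tile(np.arange(24), n_days)
    flat = counts.reshape(-1)

    nz = flat > 0
    first = rng.binomial(flat[nz], 0.5)
    second = flat[nz] - first
    blocks = pd.DataFrame(
        {
            "participant_id": np.concatenate([pid[nz], pid[nz]]),
            "date": np.concatenate([date[nz], date[nz]]),
            "block_index": np.concatenate([2 * hour[nz], 2 * hour[nz] + 1]),
            "steps": np.concatenate([first, second]),
        }
    )
    blocks = blocks[blocks["steps"] > 0]
    blocks = blocks.sort_values(
        ["participant_id", "date", "block_index"], kind="mergesort"
    ).reset_index(drop=True)

    n_bad = int(round(config.corruption_rate * len(blocks)))
    if n_bad == 0:
        sidecar = pd.DataFrame(
            columns=["participant_id", "date", "block_index", "steps", "reason"]
        )
        return blocks, sidecar

    src = blocks.iloc[rng.integers(0, len(blocks), n_bad)].reset_index(drop=True)
    bad_index = np.arange(n_bad) % 2 == 0
    bad = src.copy()
    bad.loc[bad_index, "block_index"] = 48 + rng.integers(0, 5, int(bad_index.sum()))
    bad.loc[~bad_index, "steps"] = -rng.integers(1, 200, int((~bad_index).sum()))
    sidecar = bad.assign(
        reason=np.where(bad_index, "block_index_out_of_range", "negative_steps")
    )
    corrupted = pd.concat([blocks, bad], ignore_index=True)
    return corrupted, sidecar
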