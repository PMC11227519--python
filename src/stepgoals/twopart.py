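"""Hour-specific two-part (hurdle) model for intra-day step counts.

The outcome for one participant-hour is either zero (no recorded steps) or
a positive count.  A binary logistic regression gives the probability of
any activity in the hour; conditional on activity, a gamma regression with
a log link gives the size of the positive count.  Hours in the second half
of the day (12:00-23:59) are additionally stratified by the step count
accumulated up to the previous hour, using the four goal-defined intervals
[0, 5000), [5000, 7500), [7500, 10000) and [10000, inf); hours before noon
use a single "morning" specification without the cumulative covariate.

The gamma component is parameterised by (shape ``alpha``, mean
``exp(gamma . x)``), i.e. rate ``alpha / mean``.  Positive counts are
treated as continuous by the likelihood even though generated data are
rounded to integers; the rounding is a documented approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, gammaln

__all__ = [
    "MORNING",
    "EVENING_STRATA",
    "STRATUM_EDGES",
    "DAY_TYPES",
    "AGE_GROUPS",
    "BMI_GROUPS",
    "AGE_REF",
    "BMI_REF",
    "SEXES",
    "ModelCellKey",
    "TwoPartParameters",
    "age_group_of",
    "bmi_group_of",
    "is_morning",
    "stratum_of",
    "scaled_cumulative",
    "design_names",
    "design_vector",
    "design_matrix",
    "activity_probability",
    "positive_mean",
    "twopart_loglik",
    "sample_one_hour",
    "sample_hours",
]

MORNING = "morning"
EVENING_STRATA = ("S1", "S2", "S3", "S4")
#: upper bounds separating the evening strata (S1 < 5000 <= S2 < 7500 <= S3 < 10000 <= S4)
STRATUM_EDGES = (5000.0, 7500.0, 10000.0)
DAY_TYPES = ("weekday", "weekend")

AGE_GROUPS = ("17-29", "30-39", "40-49", "50-59", ">=60")
BMI_GROUPS = ("<18.5", "18.5-22.9", "23-27.4", ">=27.5")
AGE_REF = "17-29"
BMI_REF = "18.5-22.9"
SEXES = ("female", "male")

_AGE_EDGES = (30.0, 40.0, 50.0, 60.0)
_BMI_EDGES = (18.5, 23.0, 27.5)
_BMI_LABELS_ORDERED = ("<18.5", "18.5-22.9", "23-27.4", ">=27.5")


def age_group_of(age: float) -> str:
    """Five age bands; lower-inclusive boundaries (e.g. 60 -> '>=60')."""
    if not np.isfinite(age) or age < 17:
        raise ValueError(f"age must be finite and >= 17, got {age!r}")
    idx = int(np.searchsorted(_AGE_EDGES, age, side="right"))
    return AGE_GROUPS[idx]


def bmi_group_of(bmi: float) -> str:
    """Four BMI bands with lower-inclusive boundaries (27.5 -> '>=27.5')."""
    if not np.isfinite(bmi) or bmi <= 0:
        raise ValueError(f"bmi must be finite and positive, got {bmi!r}")
    idx = int(np.searchsorted(_BMI_EDGES, bmi, side="right"))
    return _BMI_LABELS_ORDERED[idx]


def is_morning(hour: int) -> bool:
    if not 0 <= hour <= 23:
        raise ValueError(f"hour must be in 0..23, got {hour}")
    return hour < 12


def stratum_of(cum_steps: float, hour: int) -> str:
    """Select the model stratum for a given accumulated count and hour.

    Hours before noon always map to the single morning stratum; afternoon
    and evening hours map to the goal interval containing ``cum_steps``.
    """
    if cum_steps < 0:
        raise ValueError(f"cum_steps must be >= 0, got {cum_steps}")
    if is_morning(hour):
        return MORNING
    idx = int(np.searchsorted(STRATUM_EDGES, cum_steps, side="right"))
    return EVENING_STRATA[idx]


def scaled_cumulative(cum_steps: float) -> float:
    """Accumulated steps divided by 10,000 (== 1 at the top daily goal)."""
    if cum_steps < 0:
        raise ValueError(f"cum_steps must be >= 0, got {cum_steps}")
    return cum_steps / 10_000.0


@dataclass(frozen=True)
class ModelCellKey:
    """Identifies one fitted model: hour x day type x stratum."""

    hour: int
    day_type: str
    stratum: str

    def __post_init__(self) -> None:
        if not 0 <= self.hour <= 23:
            raise ValueError(f"hour must be in 0..23, got {self.hour}")
        if self.day_type not in DAY_TYPES:
            raise ValueError(f"unknown day_type {self.day_type!r}")
        morning = self.hour < 12
        if morning and self.stratum != MORNING:
            raise ValueError(f"hour {self.hour} < 12 requires the morning stratum")
        if not morning and self.stratum not in EVENING_STRATA:
            raise ValueError(
                f"hour {self.hour} >= 12 requires a stratum in {EVENING_STRATA}"
            )

    def label(self) -> str:
        return f"{self.day_type}_h{self.hour:02d}_{self.stratum}"


def cell_key(hour: int, day_type: str, cum_steps: float) -> ModelCellKey:
    return ModelCellKey(hour, day_type, stratum_of(cum_steps, hour))


# --------------------------------------------------------------------------
# design vectors
#
# column order: intercept, 4 age dummies (ref 17-29), 3 BMI dummies
# (ref 18.5-22.9), male dummy, and -- for afternoon/evening cells only --
# the accumulated count divided by 10,000.

_N_BASE = 9  # columns shared by morning and evening designs


def design_names(morning: bool) -> list[str]:
    names = ["intercept"]
    names += [f"age_{g}" for g in AGE_GROUPS if g != AGE_REF]
    names += [f"bmi_{g}" for g in BMI_GROUPS if g != BMI_REF]
    names += ["male"]
    if not morning:
        names += ["scaled_cum"]
    return names


def design_matrix(
    age_group: Sequence[str],
    bmi_group: Sequence[str],
    sex: Sequence[str],
    cum_steps: Sequence[float] | None = None,
) -> np.ndarray:
    """Stack design rows for many participant-hours.

    ``cum_steps=None`` builds the morning design (9 columns); otherwise the
    scaled cumulative column is appended (10 columns).
    """
    age_group = np.asarray(age_group, dtype=object)
    bmi_group = np.asarray(bmi_group, dtype=object)
    sex = np.asarray(sex, dtype=object)
    n = len(age_group)
    if len(bmi_group) != n or len(sex) != n:
        raise ValueError("age_group, bmi_group and sex must have equal length")
    for arr, allowed, what in (
        (age_group, AGE_GROUPS, "age_group"),
        (bmi_group, BMI_GROUPS, "bmi_group"),
        (sex, SEXES, "sex"),
    ):
        bad = set(arr) - set(allowed)
        if bad:
            raise ValueError(f"unknown {what} value(s): {sorted(map(str, bad))}")
    cols = [np.ones(n)]
    cols += [(age_group == g).astype(float) for g in AGE_GROUPS if g != AGE_REF]
    cols += [(bmi_group == g).astype(float) for g in BMI_GROUPS if g != BMI_REF]
    cols += [(sex == "male").astype(float)]
    if cum_steps is not None:
        cum = np.asarray(cum_steps, dtype=float)
        if len(cum) != n:
            raise ValueError("cum_steps length mismatch")
        if np.any(cum < 0):
            raise ValueError("cum_steps must be >= 0")
        cols.append(cum / 10_000.0)
    return np.column_stack(cols)


def design_vector(
    age_group: str, bmi_group: str, sex: str, cum_steps: float | None = None
) -> np.ndarray:
    cum = None if cum_steps is None else [cum_steps]
    return design_matrix([age_group], [bmi_group], [sex], cum)[0]


# --------------------------------------------------------------------------
# parameters and likelihood


@dataclass(frozen=True)
class TwoPartParameters:
    """Coefficients of one model cell.

    beta drives the logistic (any-activity) part, gamma the log-link mean
    of the positive part, alpha is the gamma shape shared within the cell.
    """

    beta: np.ndarray
    gamma: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=float))
        if self.beta.ndim != 1 or self.gamma.ndim != 1:
            raise ValueError("beta and gamma must be 1-D coefficient vectors")
        if self.beta.shape != self.gamma.shape:
            raise ValueError(
                f"beta and gamma must have matching length, got "
                f"{self.beta.shape[0]} vs {self.gamma.shape[0]}"
            )
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be finite and > 0, got {self.alpha}")

    @property
    def n_covariates(self) -> int:
        return self.beta.shape[0]


def _check_design(params: TwoPartParameters, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.n_covariates:
        raise ValueError(
            f"design has {X.shape[1]} columns but parameters expect "
            f"{params.n_covariates}"
        )
    return X


def activity_probability(params: TwoPartParameters, X: np.ndarray) -> np.ndarray:
    """P(any positive steps) per design row."""
    X = _check_design(params, X)
    return expit(X @ params.beta)


def positive_mean(params: TwoPartParameters, X: np.ndarray) -> np.ndarray:
    """Conditional mean of the positive part, exp(gamma . x)."""
    X = _check_design(params, X)
    return np.exp(X @ params.gamma)


def twopart_loglik(
    params: TwoPartParameters, X: np.ndarray, y: np.ndarray
) -> float:
    """Exact log-likelihood of the hurdle model for aligned rows/counts.

    Zero counts contribute log(1 - p); positive counts contribute
    log(p) plus the gamma log-density with shape alpha and mean
    exp(gamma . x).
    """
    if not (np.all(np.isfinite(params.beta)) and np.all(np.isfinite(params.gamma))):
        raise ValueError("non-finite parameter vector")
    X = _check_design(params, X)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.shape[0] != X.shape[0]:
        raise ValueError("y must be 1-D and aligned with the design rows")
    if np.any(y < 0):
        raise ValueError("counts must be >= 0")
    pos = y > 0
    eta = X @ params.beta
    # z*eta - log(1 + exp(eta)) == log p  (z=1)  or  log(1-p)  (z=0)
    binary = float(np.sum(np.where(pos, eta, 0.0) - np.logaddexp(0.0, eta)))
    if not pos.any():
        return binary
    a = params.alpha
    mu = np.exp(X[pos] @ params.gamma)
    yv = y[pos]
    dens = np.sum(
        a * np.log(a / mu) + (a - 1.0) * np.log(yv) - a * yv / mu - gammaln(a)
    )
    return binary + float(dens)


def sample_hours(
    params: TwoPartParameters, X: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one hurdle outcome per design row.

    Zero with probability 1-p, otherwise a rounded gamma draw floored at 1
    so the activity indicator and positivity always agree.
    """
    X = _check_design(params, X)
    p = expit(X @ params.beta)
    active = rng.random(X.shape[0]) < p
    out = np.zeros(X.shape[0], dtype=np.int64)
    if active.any():
        mu = np.exp(X[active] @ params.gamma)
        draws = rng.gamma(params.alpha, mu / params.alpha)
        out[active] = np.maximum(1, np.rint(draws)).astype(np.int64)
    return out


def sample_one_hour(
    params: TwoPartParameters, x: np.ndarray, rng: np.random.Generator
) -> int:
    return int(sample_hours(params, np.atleast_2d(x), rng)[0])


def cell_to_dict(key: ModelCellKey, params: TwoPartParameters) -> dict:
    """JSON-ready representation of one fitted/true model cell."""
    return {
        "hour": key.hour,
        "day_type": key.day_type,
        "stratum": key.stratum,
        "beta": params.beta.tolist(),
        "gamma": params.gamma.tolist(),
        "alpha": params.alpha,
    }


def cell_from_dict(payload: dict) -> tuple[ModelCellKey, TwoPartParameters]:
    key = ModelCellKey(payload["hour"], payload["day_type"], payload["stratum"])
    params = TwoPartParameters(payload["beta"], payload["gamma"], payload["alpha"])
    return key, params
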