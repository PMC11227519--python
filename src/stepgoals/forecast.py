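"""Forward simulation of the rest of the day and goal recommendations.

Given fitted hourly model cells, a path starts from the accumulated count
at the query hour, samples that hour from the cell selected by the current
stratum, updates the running total, re-selects the stratum, and repeats
through hour 23.  Estimation uncertainty is propagated by attaching a
posterior parameter draw to each path.

Recommendation thresholds follow a mean-crossing rule by default: the
smallest 500-step grid value of accumulated counts for which the predicted
mean end-of-day total reaches the daily goal.  The attainment probability
at the threshold is reported alongside.  A probability-based criterion
(P(total >= goal) >= p0) is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .inference import PosteriorDraws
from .twopart import (
    AGE_REF,
    BMI_REF,
    DAY_TYPES,
    EVENING_STRATA,
    MORNING,
    STRATUM_EDGES,
    ModelCellKey,
    TwoPartParameters,
    design_vector,
)

__all__ = [
    "ForecastQuery",
    "CellSet",
    "Recommendation",
    "DEFAULT_GRID",
    "forward_simulate_remainder",
    "goal_probability",
    "predict_mean_and_ci",
    "recommend_thresholds",
    "recommendation_table",
]

#: accumulated-count grid used for tabled recommendations (steps)
DEFAULT_GRID = tuple(range(0, 12_501, 500))
DEFAULT_GOALS = (5_000, 7_500, 10_000)


@dataclass(frozen=True)
class ForecastQuery:
    """State of one participant-day at the start of an hour."""

    hour: int
    cum_steps: float
    day_type: str
    age_group: str = AGE_REF
    bmi_group: str = BMI_REF
    sex: str = "female"

    def __post_init__(self) -> None:
        if not 0 <= self.hour <= 24:
            raise ValueError(f"hour must be in 0..24, got {self.hour}")
        if self.cum_steps < 0:
            raise ValueError("cum_steps must be >= 0")
        if self.day_type not in DAY_TYPES:
            raise ValueError(f"unknown day_type {self.day_type!r}")


class CellSet:
    """Parameter draws for every available model cell.

    Each cell maps to an array of shape (n_draws, 2*d + 1) holding
    [beta..., gamma..., log_alpha]; a point parameter set is a single-row
    cell.  Lookup of a missing cell raises ``KeyError`` naming the hour,
    day type and stratum.
    """

    def __init__(self, cells: Mapping[ModelCellKey, np.ndarray]):
        self._cells: dict[ModelCellKey, np.ndarray] = {}
        for key, arr in cells.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            if arr.shape[1] % 2 != 1:
                raise ValueError(f"cell {key.label()} has invalid parameter width")
            self._cells[key] = arr

    @classmethod
    def from_posteriors(cls, fits: Mapping[ModelCellKey, PosteriorDraws]) -> "CellSet":
        return cls({key: pd_.merged() for key, pd_ in fits.items()})

    @classmethod
    def from_true_params(
        cls, params: Mapping[ModelCellKey, TwoPartParameters]
    ) -> "CellSet":
        cells = {}
        for key, p in params.items():
            row = np.concatenate([p.beta, p.gamma, [np.log(p.alpha)]])
            cells[key] = row[None, :]
        return cls(cells)

    def draws(self, key: ModelCellKey) -> np.ndarray:
        try:
            return self._cells[key]
        except KeyError:
            raise KeyError(
                f"no fitted cell for hour={key.hour}, day_type={key.day_type!r}, "
                f"stratum={key.stratum!r}"
            ) from None

    def keys(self) -> Iterable[ModelCellKey]:
        return self._cells.keys()

    def __contains__(self, key: ModelCellKey) -> bool:
        return key in self._cells

    def __len__(self) -> int:
        return len(self._cells)


def _strata_for_hour(hour: int) -> tuple[str, ...]:
    return (MORNING,) if hour < 12 else EVENING_STRATA


def forward_simulate_remainder(
    query: ForecastQuery,
    cells: CellSet,
    n_paths: int,
    rng: np.random.Generator | None = None,
    param_index: int | None = None,
    return_trajectories: bool = False,
    max_hourly: float = 100_000.0,
):
    """Simulate end-of-day totals from the query state.

    Every path re-selects its model cell each hour from the stratum of its
    own running total.  By default each path carries an independent
    posterior parameter draw (``param_index=None``); passing an integer
    pins every path to that draw (modulo each cell's sample size), which is
    used for per-draw mean forecasts.

    Returns the array of end-of-day totals, or ``(totals, trajectories)``
    with trajectories of shape (n_remaining_hours, n_paths) holding the
    running total after each simulated hour.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    cum = np.full(n_paths, float(query.cum_steps))
    traj: list[np.ndarray] = []
    if query.hour >= 24:
        totals = cum
        return (totals, np.empty((0, n_paths))) if return_trajectories else totals

    # one uniform per path selects the same posterior quantile in every cell
    u = rng.random(n_paths)
    x9 = design_vector(query.age_group, query.bmi_group, query.sex)

    edges = np.asarray(STRATUM_EDGES)
    for h in range(query.hour, 24):
        strata = _strata_for_hour(h)
        if h < 12:
            labels = np.zeros(n_paths, dtype=int)
        else:
            labels = np.searchsorted(edges, cum, side="right")
        y = np.zeros(n_paths)
        for s_idx, stratum in enumerate(strata):
            mask = labels == s_idx
            m = int(mask.sum())
            if m == 0:
                continue
            P = cells.draws(ModelCellKey(h, query.day_type, stratum))
            if param_index is None:
                rows = P[(u[mask] * len(P)).astype(int)]
            else:
                rows = np.broadcast_to(P[param_index % len(P)], (m, P.shape[1]))
            d = (P.shape[1] - 1) // 2
            eta_b = rows[:, :9] @ x9
            eta_g = rows[:, d : d + 9] @ x9
            if d == 10:
                sc = cum[mask] / 10_000.0
                eta_b = eta_b + rows[:, 9] * sc
                eta_g = eta_g + rows[:, d + 9] * sc
            p = expit(eta_b)
            active = rng.random(m) < p
            if active.any():
                a = np.exp(rows[active, -1])
                # cap the linear predictor: draws from data-poor cells whose
                # posterior is essentially the wide prior would otherwise
                # overflow; max_hourly bounds any single simulated hour
                mu = np.exp(np.minimum(eta_g[active], 25.0))
                draws = rng.gamma(a, mu / a)
                vals = np.zeros(m)
                vals[active] = np.minimum(
                    np.maximum(1.0, np.rint(draws)), max_hourly
                )
                y[mask] = vals
        cum = cum + y
        if return_trajectories:
            traj.append(cum.copy())
    if return_trajectories:
        return cum, np.asarray(traj)
    return cum


def goal_probability(
    query: ForecastQuery,
    goal: float,
    cells: CellSet,
    n_paths: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, tuple[float, float]]:
    """P(end-of-day total >= goal) with a binomial standard-error band.

    Returns ``(probability, (lower, upper))`` where the band is the
    estimate +/- 1.96 Monte-Carlo standard errors, clipped to [0, 1].
    Short-circuits to exactly 1 when the goal is already met.
    """
    if goal < 0:
        raise ValueError("goal must be >= 0")
    if query.cum_steps >= goal:
        return 1.0, (1.0, 1.0)
    if n_paths < 100:
        warnings.warn(f"n_paths={n_paths} < 100; goal probability will be noisy")
    totals = forward_simulate_remainder(query, cells, n_paths, rng)
    phat = float(np.mean(totals >= goal))
    se = np.sqrt(phat * (1.0 - phat) / n_paths)
    return phat, (max(0.0, phat - 1.96 * se), min(1.0, phat + 1.96 * se))


def predict_mean_and_ci(
    query: ForecastQuery,
    cells: CellSet,
    n_draws: int = 200,
    n_paths_per_draw: int = 50,
    rng: np.random.Generator | None = None,
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Mean end-of-day total with a 95% interval on the mean.

    For each of ``n_draws`` posterior parameter draws, the model-implied
    mean total is estimated by forward simulation holding that draw fixed;
    the point estimate averages over draws and the interval is the
    2.5/97.5 percentile of the per-draw means (an interval on the mean,
    not on individual totals).  Returns ``(mean, (lo, hi), per_draw_means)``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    max_draws = max((len(cells.draws(k)) for k in cells.keys()), default=1)
    n_draws = min(n_draws, max_draws)
    indices = rng.integers(0, 2**31 - 1, size=n_draws) if max_draws > 1 else [0]
    means = np.array(
        [
            float(
                np.mean(
                    forward_simulate_remainder(
                        query, cells, n_paths_per_draw, rng, param_index=int(j)
                    )
                )
            )
            for j in indices
        ]
    )
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(means.mean()), (float(lo), float(hi)), means


@dataclass(frozen=True)
class Recommendation:
    hour: int
    goal: float
    day_type: str
    threshold: float | None  # smallest qualifying grid value, None if unattainable
    probability: float | None  # attainment probability at the threshold
    criterion: str


def recommend_thresholds(
    hour: int,
    goal: float,
    cells: CellSet,
    day_type: str,
    age_group: str = AGE_REF,
    bmi_group: str = BMI_REF,
    sex: str = "female",
    grid: Iterable[float] = DEFAULT_GRID,
    criterion: str = "mean",
    min_probability: float = 0.9,
    n_draws: int = 100,
    n_paths_per_draw: int = 25,
    n_prob_paths: int = 4_000,
    rng: np.random.Generator | None = None,
) -> Recommendation:
    """Smallest grid value of accumulated steps meeting the goal criterion.

    ``criterion='mean'`` (default) requires the predicted mean end-of-day
    total to reach the goal; ``criterion='probability'`` requires the
    attainment probability to reach ``min_probability``.
    """
    if criterion not in ("mean", "probability"):
        raise ValueError(f"unknown criterion {criterion!r}")
    rng = rng if rng is not None else np.random.default_rng()
    threshold = None
    for c in sorted(grid):
        query = ForecastQuery(hour, float(c), day_type, age_group, bmi_group, sex)
        if c >= goal:
            threshold = float(c)
            break
        if criterion == "mean":
            mean, _, _ = predict_mean_and_ci(
                query, cells, n_draws, n_paths_per_draw, rng
            )
            ok = mean >= goal
        else:
            prob, _ = goal_probability(query, goal, cells, n_prob_paths, rng)
            ok = prob >= min_probability
        if ok:
            threshold = float(c)
            break
    if threshold is None:
        return Recommendation(hour, goal, day_type, None, None, criterion)
    query = ForecastQuery(hour, threshold, day_type, age_group, bmi_group, sex)
    prob, _ = goal_probability(query, goal, cells, n_prob_paths, rng)
    return Recommendation(hour, goal, day_type, threshold, prob, criterion)


def recommendation_table(
    cells: CellSet,
    hours: Iterable[int],
    goals: Iterable[float] = DEFAULT_GOALS,
    day_types: Iterable[str] = DAY_TYPES,
    subgroups: Mapping[str, dict] | None = None,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Tidy grid of recommendations over hours x goals x subgroups.

    ``subgroups`` maps a label to demographic keyword overrides (defaults
    to a single reference-participant row labelled 'overall').
    """
    rng = rng if rng is not None else np.random.default_rng()
    subgroups = subgroups or {"overall": {}}
    records = []
    for day_type in day_types:
        for goal in goals:
            for hour in hours:
                for label, demo in subgroups.items():
                    rec = recommend_thresholds(
                        hour, goal, cells, day_type, rng=rng, **demo, **kwargs
                    )
                    records.append(
                        {
                            "day_type": day_type,
                            "goal": goal,
                            "hour": hour,
                            "subgroup": label,
                            "threshold": rec.threshold,
                            "probability": rec.probability,
                            "criterion": rec.criterion,
                        }
                    )
    return pd.DataFrame.from_records(records)
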