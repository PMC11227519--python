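import itertools

import numpy as np
import pytest

from stepgoals.forecast import (
    CellSet,
    ForecastQuery,
    Recommendation,
    forward_simulate_remainder,
    goal_probability,
    predict_mean_and_ci,
    recommend_thresholds,
)
from stepgoals.twopart import (
    EVENING_STRATA,
    MORNING,
    ModelCellKey,
    TwoPartParameters,
)

POINT_MASS_SHAPE = 1e8  # gamma sd = mean/1e4, so rounding returns the mean exactly


def point_cell(p, step, cum_slope=0.0, morning=False):
    """Parameters yielding: 0 w.p. 1-p, otherwise exactly `step` counts."""
    d = 9 if morning else 10
    beta = np.zeros(d)
    gamma = np.zeros(d)
    with np.errstate(divide="ignore"):
        beta[0] = np.log(p / (1 - p)) if 0 < p < 1 else (60.0 if p >= 1 else -60.0)
    gamma[0] = np.log(step)
    if not morning:
        beta[9] = 0.0
        gamma[9] = cum_slope
    return TwoPartParameters(beta, gamma, POINT_MASS_SHAPE)


def toy_cells(hours, p=0.5, step=1000, day_type="weekday"):
    cells = {}
    for h in hours:
        for stratum in EVENING_STRATA if h >= 12 else (MORNING,):
            cells[ModelCellKey(h, day_type, stratum)] = point_cell(
                p, step, morning=h < 12
            )
    return CellSet.from_true_params(cells)


def enumeration_oracle(start, hours_p_step, goal):
    """Exact P(total >= goal) for independent point-mass hourly outcomes."""
    prob = 0.0
    options = [((1 - p, 0), (p, s)) for p, s in hours_p_step]
    for combo in itertools.product(*options):
        weight = np.prod([w for w, _ in combo])
        total = start + sum(s for _, s in combo)
        if total >= goal:
            prob += weight
    return prob


class TestForwardSimulate:
    def test_no_hours_left_returns_start(self, rng):
        cells = toy_cells(range(22, 24))
        query = ForecastQuery(24, 4321, "weekday")
        totals = forward_simulate_remainder(query, cells, 50, rng)
        assert (totals == 4321).all()

    def test_degenerate_hurdle_stays_at_start(self, rng):
        cells = toy_cells(range(20, 24), p=0.0)
        query = ForecastQuery(20, 777, "weekday")
        totals = forward_simulate_remainder(query, cells, 200, rng)
        assert (totals == 777).all()

    def test_two_hour_point_mass_enumeration(self, rng):
        cells = toy_cells(range(22, 24), p=0.5, step=1000)
        query = ForecastQuery(22, 0, "weekday")
        totals = forward_simulate_remainder(query, cells, 10_000, rng)
        # outcomes: 0/1000/2000 with probs .25/.5/.25
        assert set(np.unique(totals)) <= {0.0, 1000.0, 2000.0}
        p2 = np.mean(totals == 2000)
        se = np.sqrt(0.25 * 0.75 / 10_000)
        assert abs(p2 - 0.25) < 3 * se

    def test_missing_cell_named(self, rng):
        cells = toy_cells(range(23, 24))
        query = ForecastQuery(22, 0, "weekday")
        with pytest.raises(KeyError, match="hour=22.*stratum='S1'"):
            forward_simulate_remainder(query, cells, 10, rng)

    def test_trajectories_non_decreasing(self, rng):
        cells = toy_cells(range(18, 24), p=0.7, step=800)
        query = ForecastQuery(18, 2500, "weekday")
        totals, traj = forward_simulate_remainder(
            query, cells, 300, rng, return_trajectories=True
        )
        assert traj.shape == (6, 300)
        assert (np.diff(traj, axis=0) >= 0).all()
        assert (traj[0] >= 2500).all()
        np.testing.assert_array_equal(traj[-1], totals)

    def test_stratum_reselected_each_hour(self, rng):
        # paths crossing 5000 switch from the S1 cell to the S2 cell
        cells_dict = {}
        for stratum in EVENING_STRATA:
            step = 6000 if stratum == "S1" else 100  # S1 jumps over the boundary
            cells_dict[ModelCellKey(22, "weekday", stratum)] = point_cell(1.0, step)
            cells_dict[ModelCellKey(23, "weekday", stratum)] = point_cell(1.0, step)
        cells = CellSet.from_true_params(cells_dict)
        totals = forward_simulate_remainder(
            ForecastQuery(22, 0, "weekday"), cells, 100, rng
        )
        # 6000 in hour 22, then the S2 cell's 100 (point mass wobbles +/-1)
        assert np.all(np.abs(totals - 6100) <= 2)


class TestGoalProbability:
    def test_already_achieved(self, rng):
        cells = toy_cells(range(22, 24))
        prob, band = goal_probability(
            ForecastQuery(22, 10_000, "weekday"), 10_000, cells, 500, rng
        )
        assert prob == 1.0 and band == (1.0, 1.0)

    def test_goal_zero(self, rng):
        cells = toy_cells(range(22, 24))
        prob, _ = goal_probability(ForecastQuery(22, 0, "weekday"), 0, cells, 500, rng)
        assert prob == 1.0

    def test_matches_enumeration_oracle(self, rng):
        p, step = 0.6, 900
        cells = toy_cells(range(21, 24), p=p, step=step)
        exact = enumeration_oracle(500, [(p, step)] * 3, 2_000)
        est, _ = goal_probability(
            ForecastQuery(21, 500, "weekday"), 2_000, cells, 10_000, rng
        )
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(est - exact) < 3 * se

    def test_small_path_count_warns(self, rng):
        cells = toy_cells(range(23, 24))
        with pytest.warns(UserWarning, match="n_paths"):
            goal_probability(ForecastQuery(23, 0, "weekday"), 5_000, cells, 50, rng)

    def test_monotone_in_accumulated_steps(self, rng):
        cells = toy_cells(range(20, 24), p=0.5, step=700)
        probs = []
        for c in range(0, 10_001, 2_000):
            prob, _ = goal_probability(
                ForecastQuery(20, c, "weekday"), 10_000, cells, 6_000,
                np.random.default_rng(99),
            )
            probs.append(prob)
        assert all(b >= a - 0.02 for a, b in zip(probs, probs[1:]))

    def test_monotone_in_goal(self, rng):
        cells = toy_cells(range(20, 24), p=0.5, step=700)
        query = ForecastQuery(20, 4_000, "weekday")
        p5, _ = goal_probability(query, 5_000, cells, 6_000, np.random.default_rng(1))
        p75, _ = goal_probability(query, 7_500, cells, 6_000, np.random.default_rng(1))
        p10, _ = goal_probability(query, 10_000, cells, 6_000, np.random.default_rng(1))
        assert p5 >= p75 >= p10


class TestPredictMean:
    def test_always_zero_future_zero_width(self, rng):
        cells = toy_cells(range(21, 24), p=0.0)
        mean, (lo, hi), _ = predict_mean_and_ci(
            ForecastQuery(21, 3_333, "weekday"), cells, rng=rng
        )
        assert mean == lo == hi == 3_333

    def test_one_step_closed_form(self, rng):
        p, mu = 0.6, 800.0
        cells_dict = {
            ModelCellKey(23, "weekday", s): TwoPartParameters(
                np.r_[np.log(p / (1 - p)), np.zeros(9)],
                np.r_[np.log(mu), np.zeros(9)],
                2.0,
            )
            for s in EVENING_STRATA
        }
        cells = CellSet.from_true_params(cells_dict)
        c = 1_000
        mean, _, _ = predict_mean_and_ci(
            ForecastQuery(23, c, "weekday"), cells, n_draws=1,
            n_paths_per_draw=40_000, rng=rng,
        )
        expected = c + p * mu
        mc_sd = np.sqrt(p * (mu**2 / 2.0) + p * (1 - p) * mu**2) / np.sqrt(40_000)
        assert abs(mean - expected) < 3 * mc_sd + 1.0

    def test_mean_non_decreasing_in_accumulated(self, rng):
        cells = toy_cells(range(21, 24), p=0.5, step=600)
        means = [
            predict_mean_and_ci(
                ForecastQuery(21, c, "weekday"), cells, n_draws=1,
                n_paths_per_draw=4_000, rng=np.random.default_rng(5),
            )[0]
            for c in range(0, 12_001, 3_000)
        ]
        assert all(b >= a - 30 for a, b in zip(means, means[1:]))


class TestRecommend:
    def test_goal_zero_threshold_zero(self, rng):
        cells = toy_cells(range(22, 24))
        rec = recommend_thresholds(22, 0, cells, "weekday", rng=rng)
        assert rec.threshold == 0.0 and rec.probability == 1.0

    def test_always_zero_future_needs_goal_on_grid(self, rng):
        cells = toy_cells(range(20, 24), p=0.0)
        rec = recommend_thresholds(20, 10_000, cells, "weekday", rng=rng)
        assert rec.threshold == 10_000.0
        assert rec.probability == 1.0

    def test_matches_brute_force_grid_search(self, rng):
        p, step = 0.8, 900
        cells = toy_cells(range(20, 24), p=p, step=step)
        rec = recommend_thresholds(
            20, 7_500, cells, "weekday", n_draws=1, n_paths_per_draw=8_000, rng=rng
        )
        # exact mean from c: c + 4*p*step; smallest grid c with mean >= 7500
        brute = next(
            c for c in range(0, 12_501, 500) if c + 4 * p * step >= 7_500
        )
        assert rec.threshold == brute

    def test_consistency_threshold_vs_one_grid_step_below(self, rng):
        p, step = 0.6, 800
        cells = toy_cells(range(20, 24), p=p, step=step)
        rec = recommend_thresholds(
            20, 10_000, cells, "weekday", n_draws=1, n_paths_per_draw=4_000, rng=rng
        )
        assert rec.threshold is not None and rec.threshold >= 500
        above, _ = goal_probability(
            ForecastQuery(20, rec.threshold, "weekday"), 10_000, cells, 8_000,
            np.random.default_rng(2),
        )
        below, _ = goal_probability(
            ForecastQuery(20, rec.threshold - 500, "weekday"), 10_000, cells, 8_000,
            np.random.default_rng(2),
        )
        assert above >= below - 0.02

    def test_threshold_not_above_goal_grid_point(self, rng):
        cells = toy_cells(range(20, 24), p=0.1, step=100)
        for goal in (5_000, 7_500, 10_000):
            rec = recommend_thresholds(
                20, goal, cells, "weekday", n_draws=1, n_paths_per_draw=500, rng=rng
            )
            assert rec.threshold is not None
            assert rec.threshold <= int(np.ceil(goal / 500.0)) * 500

    def test_probability_criterion(self, rng):
        cells = toy_cells(range(22, 24), p=0.5, step=1000)
        rec = recommend_thresholds(
            22, 2_000, cells, "weekday", criterion="probability",
            min_probability=0.7, n_prob_paths=4_000, rng=rng,
        )
        # P(reach 2000 | c) : c=0 -> .25, c=500 -> .25, c=1000 -> .75
        assert rec.threshold == 1_000.0

    def test_unknown_criterion_rejected(self, rng):
        cells = toy_cells(range(22, 24))
        with pytest.raises(ValueError, match="criterion"):
            recommend_thresholds(22, 5_000, cells, "weekday", criterion="vibes")


class TestQueryValidation:
    def test_invalid_hour(self):
        with pytest.raises(ValueError):
            ForecastQuery(25, 0, "weekday")

    def test_invalid_day_type(self):
        with pytest.raises(ValueError):
            ForecastQuery(18, 0, "midweek")

    def test_negative_cum(self):
        with pytest.raises(ValueError):
            ForecastQuery(18, -5, "weekday")
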