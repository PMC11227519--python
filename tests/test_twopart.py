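import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats
from scipy.integrate import quad
from scipy.special import expit

from stepgoals.twopart import (
    AGE_GROUPS,
    BMI_GROUPS,
    EVENING_STRATA,
    MORNING,
    ModelCellKey,
    TwoPartParameters,
    age_group_of,
    bmi_group_of,
    design_matrix,
    design_names,
    design_vector,
    sample_hours,
    sample_one_hour,
    scaled_cumulative,
    stratum_of,
    twopart_loglik,
)


class TestStratum:
    def test_boundary_4999_is_s1(self):
        assert stratum_of(4999, 15) == "S1"

    def test_boundary_5000_is_s2(self):
        assert stratum_of(5000, 15) == "S2"

    def test_morning_hour_ignores_cum(self):
        assert stratum_of(3000, 9) == MORNING
        assert stratum_of(11000, 9) == MORNING

    @pytest.mark.parametrize(
        "cum,expected",
        [(0, "S1"), (7499, "S2"), (7500, "S3"), (9999, "S3"), (10000, "S4"), (50000, "S4")],
    )
    def test_interval_assignment(self, cum, expected):
        assert stratum_of(cum, 18) == expected

    def test_invalid_hour_rejected(self):
        with pytest.raises(ValueError):
            stratum_of(100, 24)
        with pytest.raises(ValueError):
            stratum_of(100, -1)

    def test_negative_cum_rejected(self):
        with pytest.raises(ValueError):
            stratum_of(-1, 15)

    @given(st.integers(min_value=0, max_value=100_000))
    @settings(max_examples=50, deadline=None)
    def test_strata_exhaustive_and_disjoint(self, cum):
        s = stratum_of(cum, 18)
        bounds = {"S1": (0, 5000), "S2": (5000, 7500), "S3": (7500, 10000), "S4": (10000, float("inf"))}
        lo, hi = bounds[s]
        assert lo <= cum < hi


class TestScaledCumulative:
    def test_goal_completion_scales_to_one(self):
        assert scaled_cumulative(10_000) == 1.0

    def test_zero(self):
        assert scaled_cumulative(0) == 0.0

    def test_linearity(self):
        assert scaled_cumulative(12_500) == 1.25


class TestCellKey:
    def test_morning_stratum_enforced(self):
        with pytest.raises(ValueError):
            ModelCellKey(9, "weekday", "S1")
        with pytest.raises(ValueError):
            ModelCellKey(15, "weekday", MORNING)

    def test_label_roundtrip(self):
        key = ModelCellKey(18, "weekend", "S3")
        assert key.label() == "weekend_h18_S3"


class TestGroups:
    @pytest.mark.parametrize(
        "age,group", [(17, "17-29"), (29, "17-29"), (30, "30-39"), (59, "50-59"), (60, ">=60"), (85, ">=60")]
    )
    def test_age_groups(self, age, group):
        assert age_group_of(age) == group

    @pytest.mark.parametrize(
        "bmi,group",
        [(18.49, "<18.5"), (18.5, "18.5-22.9"), (24.2, "23-27.4"), (27.5, ">=27.5")],
    )
    def test_bmi_groups(self, bmi, group):
        assert bmi_group_of(bmi) == group


class TestDesign:
    def test_reference_participant_is_intercept_only(self):
        x = design_vector("17-29", "18.5-22.9", "female")
        assert x.tolist() == [1.0] + [0.0] * 8

    def test_evening_design_appends_scaled_cum(self):
        x = design_vector(">=60", ">=27.5", "male", cum_steps=7500)
        assert len(x) == 10
        assert x[-1] == 0.75
        names = design_names(morning=False)
        assert names[-1] == "scaled_cum"
        assert x[names.index("age_>=60")] == 1.0
        assert x[names.index("male")] == 1.0

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="age_group"):
            design_matrix(["child"], ["18.5-22.9"], ["female"])


def _random_params(rng, d=9, alpha=1.7):
    return TwoPartParameters(
        beta=rng.normal(0, 0.5, d), gamma=rng.normal(0, 0.3, d) + np.eye(1, d, 0)[0] * 6,
        alpha=alpha,
    )


class TestLoglik:
    def test_zero_count_at_symmetric_logit(self):
        params = TwoPartParameters(beta=[0.0], gamma=[5.0], alpha=2.0)
        ll = twopart_loglik(params, np.ones((1, 1)), np.array([0.0]))
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_exponential_density_at_its_mean(self):
        # alpha=1: gamma is exponential; density at the mean is (1/mean) e^-1
        gamma0 = 5.3
        params = TwoPartParameters(beta=[0.4], gamma=[gamma0], alpha=1.0)
        mean = np.exp(gamma0)
        ll = twopart_loglik(params, np.ones((1, 1)), np.array([mean]))
        expected = np.log(expit(0.4)) + np.log(1.0 / mean) - 1.0
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_matches_independent_density_oracle(self, rng):
        # oracle: scipy bernoulli/gamma densities assembled term by term
        params = _random_params(rng)
        X = np.column_stack([np.ones(40), rng.integers(0, 2, (40, 8))]).astype(float)
        y = sample_hours(params, X, rng).astype(float)
        assert (y == 0).any() and (y > 0).any()

        p = expit(X @ params.beta)
        mu = np.exp(X @ params.gamma)
        oracle = 0.0
        for yi, pi, mi in zip(y, p, mu):
            if yi == 0:
                oracle += np.log(1 - pi)
            else:
                oracle += np.log(pi) + stats.gamma.logpdf(
                    yi, a=params.alpha, scale=mi / params.alpha
                )
        assert twopart_loglik(params, X, y) == pytest.approx(oracle, abs=1e-8)

    def test_nonfinite_parameters_rejected(self):
        params = TwoPartParameters(beta=[0.0], gamma=[5.0], alpha=1.0)
        bad = TwoPartParameters.__new__(TwoPartParameters)
        object.__setattr__(bad, "beta", np.array([np.nan]))
        object.__setattr__(bad, "gamma", np.array([5.0]))
        object.__setattr__(bad, "alpha", 1.0)
        with pytest.raises(ValueError):
            twopart_loglik(bad, np.ones((1, 1)), np.array([1.0]))
        del params

    def test_density_normalises(self):
        # P(0) + P(+) * integral of gamma density == 1
        params = TwoPartParameters(beta=[0.7], gamma=[4.0], alpha=2.5)
        p = expit(0.7)
        mu = np.exp(4.0)
        integral, _ = quad(
            lambda v: stats.gamma.pdf(v, a=params.alpha, scale=mu / params.alpha),
            0,
            np.inf,
        )
        assert (1 - p) + p * integral == pytest.approx(1.0, abs=1e-8)

    def test_factorisation_joint_optimum_equals_componentwise(self, rng):
        # maximising the joint likelihood decouples into the two sub-problems
        params = _random_params(rng, d=2)
        X = np.column_stack([np.ones(200), rng.integers(0, 2, 200)]).astype(float)
        y = sample_hours(params, X, rng).astype(float)
        pos = y > 0

        def joint_neg(theta):
            p = TwoPartParameters(theta[:2], theta[2:4], np.exp(theta[4]))
            return -twopart_loglik(p, X, y)

        def logistic_neg(b):
            eta = X @ b
            return -np.sum(np.where(pos, eta, 0) - np.logaddexp(0, eta))

        def gamma_neg(t):
            g, la = t[:2], t[2]
            a = np.exp(la)
            mu = np.exp(X[pos] @ g)
            return -np.sum(stats.gamma.logpdf(y[pos], a=a, scale=mu / a))

        x0 = np.array([0.0, 0.0, np.log(y[pos].mean()), 0.0, 0.0])
        joint = optimize.minimize(joint_neg, x0, method="Nelder-Mead",
                                  options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        blog = optimize.minimize(logistic_neg, np.zeros(2), method="BFGS")
        bgam = optimize.minimize(
            gamma_neg, np.array([np.log(y[pos].mean()), 0.0, 0.0]), method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        np.testing.assert_allclose(joint.x[:2], blog.x, atol=2e-3)
        np.testing.assert_allclose(joint.x[2:4], bgam.x[:2], atol=2e-3)


class TestSampling:
    def test_probability_zero_always_zero(self, rng):
        params = TwoPartParameters(beta=[-60.0], gamma=[5.0], alpha=2.0)
        draws = sample_hours(params, np.ones((500, 1)), rng)
        assert (draws == 0).all()

    def test_large_shape_concentrates_at_mean(self, rng):
        gamma0 = np.log(800.0)
        params = TwoPartParameters(beta=[60.0], gamma=[gamma0], alpha=1e6)
        draws = sample_hours(params, np.ones((200, 1)), rng)
        assert np.all(np.abs(draws - 800) <= 5)

    def test_zero_fraction_matches_hurdle(self, rng):
        beta0 = 0.8
        params = TwoPartParameters(beta=[beta0], gamma=[5.0], alpha=2.0)
        n = 100_000
        draws = sample_hours(params, np.ones((n, 1)), rng)
        p = expit(beta0)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(np.mean(draws == 0) - (1 - p)) < 3 * se

    def test_positive_draws_floored_at_one(self, rng):
        params = TwoPartParameters(beta=[60.0], gamma=[np.log(0.01)], alpha=1.0)
        draws = sample_hours(params, np.ones((200, 1)), rng)
        assert (draws >= 1).all()

    def test_mean_identity_monte_carlo(self, rng):
        # E[count] ~= p * exp(gamma . x) up to rounding
        beta0, gamma0, alpha = 0.3, np.log(600.0), 2.0
        params = TwoPartParameters(beta=[beta0], gamma=[gamma0], alpha=alpha)
        n = 200_000
        draws = sample_hours(params, np.ones((n, 1)), rng)
        p = expit(beta0)
        mu = np.exp(gamma0)
        expected = p * mu
        var = p * (mu**2 / alpha) + p * (1 - p) * mu**2
        se = np.sqrt(var / n)
        assert abs(draws.mean() - expected) < 3 * se + 1.0  # +1 for rounding/floor

    def test_scalar_wrapper(self, rng):
        params = TwoPartParameters(beta=[60.0], gamma=[6.0], alpha=2.0)
        value = sample_one_hour(params, np.ones(1), rng)
        assert isinstance(value, int) and value >= 1


class TestSerialisation:
    def test_json_roundtrip(self, rng):
        import json

        from stepgoals.twopart import cell_from_dict, cell_to_dict

        key = ModelCellKey(19, "weekend", "S3")
        params = _random_params(rng, d=10)
        payload = json.loads(json.dumps(cell_to_dict(key, params)))
        key2, params2 = cell_from_dict(payload)
        assert key2 == key
        np.testing.assert_allclose(params2.beta, params.beta)
        np.testing.assert_allclose(params2.gamma, params.gamma)
        assert params2.alpha == params.alpha
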