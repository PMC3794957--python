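"""Zero-inflated GPD supply process: quantiles, sampling, fitting, scaling."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from rescuesim import (
    DEFAULT_CATEGORY_PARAMS,
    DonationEvent,
    GpdSupplyParams,
    draw_daily_donation,
    estimate_rate,
    fit_gpd_mle,
    fit_size_scaling,
    gpd_conditional_mean,
    gpd_quantile,
    predict_mean_supply,
    rescale_to_mean,
)
from rescuesim.supply_model import InsufficientDataError, donations_from_uniforms


def _bisect_gpd_quantile(u: float, scale: float, shape: float) -> float:
    """Independent numerical inversion of the GPD CDF by bisection."""

    def cdf(x: float) -> float:
        return 1.0 - (1.0 + shape * x / scale) ** (-1.0 / shape)

    lo, hi = 0.0, 1e9
    for _ in range(200):
        mid = (lo + hi) / 2
        if cdf(mid) < u:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestGpdQuantile:
    def test_lower_endpoint_is_threshold(self, grocers):
        assert gpd_quantile(1e-12, grocers) == pytest.approx(0.0, abs=1e-6)

    def test_exponential_special_case(self):
        p = GpdSupplyParams("x", 0.0, 1.0, 100.0, 0.0)
        assert gpd_quantile(1 - math.exp(-1), p) == pytest.approx(100.0)

    def test_median_matches_numerical_cdf_inversion(self, grocers):
        expected = _bisect_gpd_quantile(0.5, 293.139, 0.205)
        assert gpd_quantile(0.5, grocers) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("u", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_u_outside_open_interval(self, grocers, u):
        with pytest.raises(ValueError):
            gpd_quantile(u, grocers)

    @given(
        u1=st.floats(0.001, 0.998),
        du=st.floats(1e-4, 1e-3),
        shape=st.floats(-0.5, 0.9),
    )
    @settings(derandomize=True, max_examples=100)
    def test_strictly_increasing_in_u(self, u1, du, shape):
        p = GpdSupplyParams("x", 0.0, 1.0, 100.0, shape)
        assert gpd_quantile(u1 + du, p) > gpd_quantile(u1, p)

    @given(u=st.floats(0.01, 0.99))
    @settings(derandomize=True, max_examples=50)
    def test_continuous_in_shape_at_zero(self, u):
        exp = GpdSupplyParams("x", 0.0, 1.0, 100.0, 0.0)
        for eps in (1e-8, -1e-8):
            near = GpdSupplyParams("x", 0.0, 1.0, 100.0, eps)
            assert gpd_quantile(u, near) == pytest.approx(
                gpd_quantile(u, exp), rel=1e-4
            )


class TestConditionalMean:
    @pytest.mark.parametrize(
        "category,printed_mean",
        [
            ("all", 491.884),
            ("grocers", 368.728),
            ("manufacturers", 629.954),
            ("individuals", 1492.042),
            ("farms", 6908.353),
        ],
    )
    def test_printed_category_means(self, category, printed_mean):
        p = DEFAULT_CATEGORY_PARAMS[category]
        assert gpd_conditional_mean(p) == pytest.approx(printed_mean, rel=5e-3)

    def test_exponential_mean_equals_scale(self):
        p = GpdSupplyParams("x", 0.0, 1.0, 100.0, 0.0)
        assert gpd_conditional_mean(p) == pytest.approx(100.0)

    def test_infinite_mean_rejected(self):
        p = GpdSupplyParams("x", 0.0, 1.0, 100.0, 1.1)
        with pytest.raises(ValueError, match="infinite"):
            gpd_conditional_mean(p)


class TestDailyDraws:
    def test_zero_rate_never_donates(self, rng):
        p = GpdSupplyParams("x", 0.0, 0.0, 100.0, 0.1)
        assert all(draw_daily_donation(p, rng) == 0.0 for _ in range(200))

    def test_draws_nonnegative_and_rate_matches(self, grocers, rng):
        u = rng.random((100_000, 2))
        draws = donations_from_uniforms(u[:, 0], u[:, 1], grocers)
        assert np.all(draws >= 0)
        frac = np.mean(draws > 0)
        se = math.sqrt(0.302 * 0.698 / 100_000)
        assert frac == pytest.approx(0.302, abs=3 * se)

    def test_nonzero_draw_mean_matches_analytic(self, grocers, rng):
        u = rng.random((200_000, 2))
        draws = donations_from_uniforms(u[:, 0], u[:, 1], grocers)
        positive = draws[draws > 0]
        analytic = gpd_conditional_mean(grocers)
        # heavy tail (shape 0.205): allow 4 empirical SEs
        se = positive.std() / math.sqrt(positive.size)
        assert positive.mean() == pytest.approx(analytic, abs=4 * se)


class TestGpdMle:
    def test_recovers_generating_parameters(self, grocers, rng):
        u = rng.random(10_000)
        samples = gpd_quantile(u, grocers)
        fit = fit_gpd_mle(samples)
        assert abs(fit.scale - 293.139) < 3 * fit.scale_se
        assert abs(fit.shape - 0.205) < 3 * fit.shape_se

    def test_exponential_shape_recovered_near_zero(self, rng):
        samples = rng.exponential(100.0, size=10_000)
        fit = fit_gpd_mle(samples)
        assert abs(fit.shape) < 3 * fit.shape_se

    def test_agrees_with_scipy_genpareto(self, grocers, rng):
        u = rng.random(5_000)
        samples = gpd_quantile(u, grocers)
        fit = fit_gpd_mle(samples)
        c, loc, scale = scipy.stats.genpareto.fit(samples, floc=0)
        assert fit.scale == pytest.approx(scale, rel=1e-3)
        assert fit.shape == pytest.approx(c, abs=2e-3)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_gpd_mle([10.0, 20.0, 30.0, 40.0, 50.0])

    def test_nonpositive_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_gpd_mle([1.0] * 29 + [-5.0, 3.0])


class TestEstimateRate:
    def test_no_events_gives_zero(self):
        assert estimate_rate([], 100) == 0.0

    def test_every_day_gives_one(self):
        events = [DonationEvent("a", d, 10.0) for d in range(50)]
        assert estimate_rate(events, 50) == 1.0

    def test_zero_days_rejected(self):
        with pytest.raises(ValueError):
            estimate_rate([], 0)

    def test_pooled_simulated_log_matches_rate(self, grocers, rng):
        n_donors, n_days = 100, 365
        u = rng.random((n_donors * n_days, 2))
        draws = donations_from_uniforms(u[:, 0], u[:, 1], grocers)
        events = [
            DonationEvent(f"d{i % n_donors}", i // n_donors, float(v))
            for i, v in enumerate(draws)
            if v > 0
        ]
        rate = estimate_rate(events, n_donors * n_days)
        assert rate == pytest.approx(0.302, abs=0.01)


class TestSizeScaling:
    def test_two_point_line_has_unit_slope(self):
        model = fit_size_scaling(
            [(1e3, "grocers", 10.0), (1e5, "grocers", 1000.0), (1e4, "grocers", 100.0)]
        )
        assert model.slope == pytest.approx(1.0)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_recovers_slope_and_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 200
        log_sqft = rng.uniform(3, 5.5, n)
        cats = rng.choice(["grocers", "bakeries"], n)
        offs = np.where(cats == "grocers", 0.0, -0.4)
        log_mean = 0.3 + 0.8 * log_sqft + offs + rng.normal(0, 0.1, n)
        records = list(zip(10.0**log_sqft, cats, 10.0**log_mean))
        model = fit_size_scaling(records)

        X = sm.add_constant(
            np.column_stack([log_sqft, (cats == "bakeries").astype(float)])
        )
        ref = sm.OLS(log_mean, X).fit()
        assert model.slope == pytest.approx(ref.params[1], abs=1e-9)
        assert model.intercept == pytest.approx(ref.params[0], abs=1e-9)
        assert abs(model.slope - 0.8) < 3 * ref.bse[1]

    def test_identical_sizes_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_size_scaling([(1e4, "g", 10.0), (1e4, "g", 20.0), (1e4, "g", 30.0)])

    def test_prediction_properties(self):
        from rescuesim import SizeScalingModel

        model = SizeScalingModel(0.0, 1.0, {"grocers": 0.0}, 0.0)
        assert predict_mean_supply(100.0, "grocers", model) == pytest.approx(100.0)
        m2 = SizeScalingModel(0.1, 0.7, {"grocers": 0.0}, 0.0)
        ratio = predict_mean_supply(2000.0, "grocers", m2) / predict_mean_supply(
            1000.0, "grocers", m2
        )
        assert ratio == pytest.approx(2**0.7)
        with pytest.raises(KeyError):
            predict_mean_supply(100.0, "farms", model)


class TestRescaleToMean:
    def test_inverts_conditional_mean_exactly(self, grocers):
        out = rescale_to_mean(grocers, 368.728)
        assert out.scale == pytest.approx(293.139, rel=5e-3)
        assert gpd_conditional_mean(out) == pytest.approx(368.728, rel=1e-12)

    def test_fixed_point_and_idempotence(self, grocers):
        target = gpd_conditional_mean(grocers)
        once = rescale_to_mean(grocers, target)
        twice = rescale_to_mean(once, target)
        assert once.scale == pytest.approx(grocers.scale, rel=1e-12)
        assert twice.scale == pytest.approx(once.scale, rel=1e-12)

    def test_direct_arithmetic(self):
        p = GpdSupplyParams("x", 0.0, 1.0, 10.0, 0.5)
        assert rescale_to_mean(p, 100.0).scale == pytest.approx(50.0)

    def test_infinite_mean_rejected(self):
        p = GpdSupplyParams("x", 0.0, 1.0, 10.0, 1.2)
        with pytest.raises(ValueError):
            rescale_to_mean(p, 100.0)
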