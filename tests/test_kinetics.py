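"""Preprocessing, order inference, and apparent-rate fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nitrokin as nk
from nitrokin.errors import FitError


def make_series(times, x, temperature=303.15, w=94.0, c_io0=0.5, m=4.4):
    cond = nk.Condition(
        temperature=temperature, w_h2so4=w, c_io0=c_io0, c_hno3_0=m * c_io0
    )
    return nk.ConversionSeries(times=np.asarray(times, float),
                               conversions=np.asarray(x, float), condition=cond)


class TestPreprocessing:
    @pytest.mark.parametrize(
        "c_io,c_nio,expected",
        [(0.0, 5.0, 1.0), (3.0, 3.0, 0.5), (5.0, 0.0, 0.0)],
    )
    def test_hplc_conversion(self, c_io, c_nio, expected):
        assert nk.conversion_from_hplc(c_io, c_nio) == pytest.approx(expected)

    def test_hplc_no_analyte_raises(self):
        with pytest.raises(ValueError, match="analyte"):
            nk.conversion_from_hplc(0.0, 0.0)

    def test_residence_time_halves_with_doubled_flow(self):
        assert nk.residence_time(4.0, 1.0, 1.0) == pytest.approx(120.0)
        assert nk.residence_time(4.0, 2.0, 2.0) == pytest.approx(60.0)

    def test_residence_time_zero_flow_raises(self):
        with pytest.raises(ValueError):
            nk.residence_time(4.0, 0.0, 0.0)


class TestTransformExcess:
    def test_zero_at_origin(self):
        assert nk.transform_excess(0.0, 4.4) == 0.0

    def test_ln2_closed_form(self):
        # (4.4 - x)/(4.4 (1 - x)) = 2 at x = 2.2/3.9
        x = 2.2 / 3.9
        assert nk.transform_excess(x, 4.4) == pytest.approx(np.log(2.0), rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        x=st.floats(0, 0.999, allow_nan=False),
        m=st.floats(1.01, 50, allow_nan=False),
    )
    def test_strictly_increasing_in_x(self, x, m):
        eps = 1e-6
        if x + eps < 1:
            assert nk.transform_excess(x + eps, m) > nk.transform_excess(x, m)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nk.transform_excess(1.0, 4.4)
        with pytest.raises(ValueError):
            nk.transform_excess(0.5, 1.0)


class TestRSquared:
    def test_perfect_and_null_fits(self):
        obs = np.array([1.0, 2.0, 3.0, 5.0])
        assert nk.r_squared(obs, obs) == pytest.approx(1.0)
        assert nk.r_squared(obs, np.full(4, obs.mean())) == pytest.approx(0.0)

    def test_hand_case_matches_brute_force(self):
        obs = np.array([1.0, 2.0, 4.0, 8.0])
        fit = np.array([1.5, 2.5, 3.5, 7.5])
        ss_res = sum((o - f) ** 2 for o, f in zip(obs, fit))
        ss_tot = sum((o - obs.mean()) ** 2 for o in obs)
        assert nk.r_squared(obs, fit) == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)

    def test_constant_observed_raises(self):
        with pytest.raises(ValueError):
            nk.r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


def pseudo_series(alpha, k_pseudo=0.004, c_io0=1.0, ratio=15.0):
    t = np.arange(30.0, 330.0, 30.0)
    if alpha == 1:
        x = 1.0 - np.exp(-k_pseudo * t)
    else:
        x = c_io0 * k_pseudo * t / (1.0 + c_io0 * k_pseudo * t)
    return make_series(t, x, c_io0=c_io0, m=ratio)


def mixed_series(beta, k=0.004, c_io0=0.5, m=4.4):
    t = np.arange(30.0, 330.0, 30.0)
    if beta == 0:
        x = 1.0 - np.exp(-k * t)
    else:
        x = nk.predict_conversion(k, m, c_io0, t)
    return make_series(t, x, c_io0=c_io0, m=m)


class TestInferOrders:
    @pytest.mark.parametrize("alpha", [1, 2])
    @pytest.mark.parametrize("beta", [0, 1])
    def test_recovers_generating_orders(self, alpha, beta):
        result = nk.infer_orders(pseudo_series(alpha), mixed_series(beta))
        assert result.alpha == alpha
        assert result.beta == beta
        # the two substrate-order candidates are well separated; the
        # nitric-acid candidates differ only subtly at M = 4.4, so only
        # the alpha margin is required to clear the ambiguity threshold
        assert not result.ambiguous_alpha

    def test_first_order_r2_dominates_on_first_order_data(self):
        result = nk.infer_orders(pseudo_series(1), mixed_series(1))
        assert result.r2_by_candidate["alpha=1"] == pytest.approx(1.0, abs=1e-10)
        assert (
            result.r2_by_candidate["alpha=1"] > result.r2_by_candidate["alpha=2"]
        )

    def test_pseudo_ratio_precondition(self):
        with pytest.raises(ValueError, match="4.40"):
            nk.infer_orders(mixed_series(1), mixed_series(1))

    def test_short_series_rejected(self):
        s = pseudo_series(1)
        short = make_series(s.times[:3], s.conversions[:3], m=15.0, c_io0=1.0)
        with pytest.raises(FitError):
            nk.infer_orders(short, mixed_series(1))


class TestFitApparentK:
    def test_noise_free_inversion(self):
        # k = 0.05 over 30-300 s drives conversion to within 1e-11 of
        # complete, where double rounding of x limits the transform
        # round trip; the fit still inverts to ~3e-7 relative
        k, m, c_io0 = 0.05, 4.4, 0.5
        t = np.arange(30.0, 330.0, 30.0)
        s = make_series(t, nk.predict_conversion(k, m, c_io0, t), c_io0=c_io0, m=m)
        fit = nk.fit_apparent_k(s)
        assert fit.k == pytest.approx(k, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-4)

    def test_noise_free_inversion_moderate_conversion(self):
        # away from saturation the inversion is exact to 1e-10
        k, m, c_io0 = 0.002, 4.4, 0.5
        t = np.arange(30.0, 330.0, 30.0)
        s = make_series(t, nk.predict_conversion(k, m, c_io0, t), c_io0=c_io0, m=m)
        fit = nk.fit_apparent_k(s)
        assert fit.k == pytest.approx(k, rel=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_random_tuples_recovered(self):
        rng = np.random.default_rng(11)
        frac = np.linspace(0.1, 1.0, 10)
        for _ in range(50):
            k = 10 ** rng.uniform(-4, -1)
            m = rng.uniform(1.5, 20.0)
            c_io0 = rng.uniform(0.1, 2.0)
            # scale the grid so the largest transform value stays O(1):
            # informative conversions, no saturation
            z_max = rng.uniform(0.5, 4.0)
            t = z_max * frac / ((m - 1.0) * c_io0 * k)
            s = make_series(t, nk.predict_conversion(k, m, c_io0, t),
                            c_io0=c_io0, m=m)
            assert nk.fit_apparent_k(s).k == pytest.approx(k, rel=1e-10)

    def test_flat_series_is_nonphysical(self):
        s = make_series([30.0, 60.0, 90.0, 120.0], [0.0, 0.0, 0.0, 0.0])
        with pytest.raises(FitError, match="non-physical"):
            nk.fit_apparent_k(s)

    def test_noisy_recovery_within_ten_percent(self):
        k_true, m, c_io0 = 0.001, 4.4, 0.5
        t = np.arange(60.0, 300.0, 40.0)
        s = nk.generate_series(k_true, m, c_io0, t, noise_sd=0.01, seed=3)
        assert nk.fit_apparent_k(s).k == pytest.approx(k_true, rel=0.10)

    def test_time_unit_consistency(self):
        # minutes in, k out identical when inputs are converted together
        k, m, c_io0 = 0.002, 4.4, 0.5
        t_s = np.arange(60.0, 360.0, 60.0)
        x = nk.predict_conversion(k, m, c_io0, t_s)
        k_seconds = nk.fit_apparent_k(make_series(t_s, x, c_io0=c_io0, m=m)).k
        k_minutes = nk.fit_apparent_k(make_series(t_s / 60.0, x, c_io0=c_io0, m=m)).k
        assert k_minutes / 60.0 == pytest.approx(k_seconds, rel=1e-9)

    def test_large_intercept_warns(self):
        t = np.arange(30.0, 330.0, 30.0)
        x = nk.predict_conversion(0.002, 4.4, 0.5, t + 100.0)  # offset start
        s = make_series(t, x)
        with pytest.warns(UserWarning, match="intercept"):
            nk.fit_apparent_k(s)


class TestSeriesValidation:
    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            make_series([30.0, 30.0, 60.0, 90.0], [0.1, 0.2, 0.3, 0.4])

    def test_conversion_bounds_enforced(self):
        with pytest.raises(ValueError):
            make_series([30.0, 60.0], [0.5, 1.0])
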