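"""Forward prediction, envelope policy, validation, optimization."""

import numpy as np
import pytest

import nitrokin as nk
from nitrokin.errors import EnvelopeError
from nitrokin.predict import INTERIOR, REJECTED, SOFT, response_surface


class TestPredictConversion:
    def test_zero_time_zero_conversion(self):
        assert nk.predict_conversion(0.01, 4.4, 0.5, 0.0) == 0.0

    def test_closed_form_at_z_ln2(self):
        # z = ln 2, M = 4.4 -> x = 4.4/7.8
        m, c_io0, k = 4.4, 0.5, 0.01
        t = np.log(2.0) / ((m - 1) * c_io0 * k)
        assert nk.predict_conversion(k, m, c_io0, t) == pytest.approx(
            4.4 / 7.8, rel=1e-12
        )

    @pytest.mark.parametrize("z", [50.0, 800.0, 5000.0])
    def test_saturation_without_overflow(self, z):
        m, c_io0 = 4.4, 0.5
        t = z / ((m - 1) * c_io0 * 1.0)
        x = nk.predict_conversion(1.0, m, c_io0, t)
        assert 0.0 <= x < 1.0
        assert x == pytest.approx(1.0, abs=1e-9)

    def test_mutual_inverse_with_transform(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            x = rng.uniform(0.0, 0.999)
            m = rng.uniform(1.01, 30.0)
            z = nk.transform_excess(x, m)
            c_io0, k = 0.5, 0.01
            t = z / ((m - 1) * c_io0 * k)
            assert nk.predict_conversion(k, m, c_io0, t) == pytest.approx(
                x, rel=1e-10, abs=1e-12
            )

    def test_monotone_in_every_driver(self):
        base = nk.predict_conversion(0.001, 4.4, 0.5, 120.0)
        assert nk.predict_conversion(0.002, 4.4, 0.5, 120.0) > base
        assert nk.predict_conversion(0.001, 4.4, 0.5, 240.0) > base
        assert nk.predict_conversion(0.001, 4.4, 1.0, 120.0) > base
        assert nk.predict_conversion(0.001, 8.0, 0.5, 120.0) > base

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            nk.predict_conversion(0.01, 1.0, 0.5, 60.0)


class TestEnvelope:
    def test_three_state_classification(self):
        env = nk.CalibrationEnvelope()
        assert env.classify(308.15, 94.0, 120.0) == INTERIOR
        assert env.classify(316.15, 94.0, 600.0) == SOFT  # 43 C, 10 min
        assert env.classify(330.15, 94.0, 120.0) == REJECTED  # 57 C

    def test_soft_must_nest_in_hard(self):
        with pytest.raises(ValueError):
            nk.CalibrationEnvelope(
                soft={"t_min": 270.0, "t_max": 400.0, "w_min": 88.0,
                      "w_max": 98.0, "time_max": 300.0}
            )

    def test_hard_violation_raises_in_prediction(
        self, fitted_params, nitronium_model
    ):
        req = nk.PredictionRequest(
            temperature=330.15, w_h2so4=94.0, c_io0=0.5, m_ratio=4.4,
            residence_time=120.0,
        )
        with pytest.raises(EnvelopeError):
            nk.predict_request(req, fitted_params, nitronium_model)

    def test_soft_extrapolation_flagged_not_fatal(
        self, fitted_params, nitronium_model
    ):
        # the published-style stress test: long residence, 40 C
        req = nk.PredictionRequest(
            temperature=313.15, w_h2so4=94.0, c_io0=0.5, m_ratio=4.4,
            residence_time=12.36 * 60.0,
        )
        pred = nk.predict_request(req, fitted_params, nitronium_model)
        assert pred.status == SOFT
        assert 0.0 < pred.x < 1.0
        with pytest.raises(EnvelopeError):
            nk.predict_request(req, fitted_params, nitronium_model, strict=True)


class TestPredictK:
    def test_arithmetic_composition(self, fitted_params, nitronium_model):
        kp = nk.predict_k(94.0, 308.15, fitted_params, nitronium_model)
        assert kp.lg_k == pytest.approx(
            kp.lg_ratio + kp.n * kp.mc + kp.lg_k0, rel=1e-12
        )
        assert kp.k == pytest.approx(10.0**kp.lg_k, rel=1e-12)

    def test_round_trip_against_truth(self, truth, fitted_params, nitronium_model):
        # k values produced by the fitted pipeline match the generator
        for w in (88.0, 92.0, 96.0):
            for t in (303.15, 313.15):
                kp = nk.predict_k(w, t, fitted_params, nitronium_model)
                assert kp.k == pytest.approx(truth.k(w, t), rel=1e-6)


class TestResponseSurface:
    def test_single_cell_equals_direct_prediction(
        self, fitted_params, nitronium_model
    ):
        res = response_surface(
            fitted_params, nitronium_model, 4.4, 0.5,
            times=np.array([120.0]), w_values=np.array([94.0]),
            fixed_temperature=308.15,
        )
        kp = nk.predict_k(94.0, 308.15, fitted_params, nitronium_model)
        want = nk.predict_conversion(kp.k, 4.4, 0.5, 120.0)
        assert res.x[0, 0] == pytest.approx(want, rel=1e-12)

    def test_monotone_along_time(self, fitted_params, nitronium_model):
        res = response_surface(
            fitted_params, nitronium_model, 4.4, 0.5,
            times=np.linspace(30.0, 280.0, 12),
            temperatures=np.array([303.15, 313.15]), fixed_w=94.0,
        )
        assert np.all(np.diff(res.x, axis=0) > 0)

    def test_hard_violation_lists_cells(self, fitted_params, nitronium_model):
        with pytest.raises(EnvelopeError, match="cell"):
            response_surface(
                fitted_params, nitronium_model, 4.4, 0.5,
                times=np.array([60.0, 16.0 * 60.0 * 60.0]),
                temperatures=np.array([308.15]), fixed_w=94.0,
            )


class TestValidate:
    def test_perfect_agreement(self):
        rep = nk.validate([0.5, 0.7], [0.5, 0.7])
        assert rep.mean == 0.0 and rep.max == 0.0

    def test_percentage_point_semantics(self):
        # a 0.08 conversion miss reads as 8 percentage points
        rep = nk.validate([0.90, 0.50], [0.82, 0.50])
        assert rep.max == pytest.approx(8.0)
        assert rep.worst_index == 0

    def test_pairing_is_positional(self):
        a = nk.validate([0.9, 0.5], [0.5, 0.9])
        b = nk.validate([0.9, 0.5], [0.9, 0.5])
        assert a.mean != b.mean

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            nk.validate([0.5], [0.5, 0.6])


class TestOptimizeConditions:
    def test_monotone_objective_hits_time_cap(self, fitted_params, nitronium_model):
        res = nk.optimize_conditions(
            fitted_params, nitronium_model, 4.4, 0.5, t_step=60.0,
        )
        assert res.request.residence_time == pytest.approx(4.5 * 60.0, abs=31.0)
        assert res.on_boundary
        assert "residence_time" in res.boundary_axes

    def test_grid_matches_fine_grid_oracle(self, fitted_params, nitronium_model):
        coarse = nk.optimize_conditions(
            fitted_params, nitronium_model, 4.4, 0.5,
            t_step=30.0, temp_step=2.5, w_step=1.0,
        )
        fine = nk.optimize_conditions(
            fitted_params, nitronium_model, 4.4, 0.5,
            t_step=10.0, temp_step=0.5, w_step=0.25,
        )
        assert fine.predicted_x >= coarse.predicted_x - 1e-12
        # coarse optimum within one coarse step of the fine one per axis
        assert abs(fine.request.w_h2so4 - coarse.request.w_h2so4) <= 1.0 + 1e-9
        assert abs(fine.request.temperature - coarse.request.temperature) <= 2.5 + 1e-9

    def test_target_objective_prefers_short_time(self, fitted_params, nitronium_model):
        res = nk.optimize_conditions(
            fitted_params, nitronium_model, 4.4, 0.5, objective=0.2,
        )
        assert res.predicted_x == pytest.approx(0.2, abs=0.05)

    def test_published_operating_point_evaluates(
        self, fitted_params, nitronium_model
    ):
        # 94 wt %, 40 C, M 4.4, 12.36 min: accepted, soft-flagged
        req = nk.PredictionRequest(
            temperature=313.15, w_h2so4=94.0, c_io0=0.5, m_ratio=4.4,
            residence_time=12.36 * 60.0,
        )
        pred = nk.predict_request(req, fitted_params, nitronium_model)
        assert pred.status == SOFT
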