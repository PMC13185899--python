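"""Tanh neuron: prediction, fitting, scaling, regularization, bands."""

import numpy as np
import pytest

from nutrireq import (
    AffineScaler,
    FitConfig,
    TanhParams,
    curve_band,
    fit_rmse,
    fit_tanh_neuron,
)
from nutrireq.exceptions import DegenerateDesignError, SampleSizeError
from nutrireq.neuron import original_to_scaled, scaled_to_original


class TestPredict:
    def test_hand_computed_values(self):
        p = TanhParams(A=2.0, b=-1.0, c=0.5, B=1.0)
        np.testing.assert_allclose(
            p.predict([0.0, 2.0, 4.0]),
            [2 * np.tanh(-1) + 1, 1.0, 2 * np.tanh(1) + 1],
            rtol=1e-12,
        )

    def test_limit_is_asymptote_and_midpoint_is_offset(self):
        p = TanhParams(A=2.0, b=-1.0, c=0.5, B=1.0)
        assert p.predict(1e9) == pytest.approx(p.A + p.B, abs=1e-12)
        assert p.predict(-p.b / p.c) == pytest.approx(p.B, abs=1e-12)

    def test_mirror_parameters_predict_identically(self):
        p = TanhParams(A=2.0, b=-1.0, c=0.5, B=1.0)
        m = TanhParams(A=-2.0, b=1.0, c=-0.5, B=1.0)
        x = np.linspace(-5, 5, 11)
        np.testing.assert_allclose(p.predict(x), m.predict(x), rtol=1e-12)
        assert m.canonical() == p


class TestScaler:
    def test_round_trip_is_identity(self, rng):
        x = rng.uniform(300, 500, 40)
        y = rng.uniform(1, 5, 40)
        sc = AffineScaler.from_data(x, y)
        np.testing.assert_allclose(sc.inverse_x(sc.forward_x(x)), x, atol=1e-12)
        np.testing.assert_allclose(sc.inverse_y(sc.forward_y(y)), y, atol=1e-12)
        assert sc.forward_x(x).min() == pytest.approx(-1)
        assert sc.forward_x(x).max() == pytest.approx(1)

    def test_parameter_transform_round_trip(self, rng):
        sc = AffineScaler(300.0, 500.0, 1.0, 5.0)
        p = TanhParams(A=0.8, b=0.3, c=1.7, B=-0.2)
        back = original_to_scaled(scaled_to_original(p, sc), sc)
        np.testing.assert_allclose(back.as_array(), p.as_array(), rtol=1e-12)

    def test_back_transformed_params_reproduce_scaled_predictions(self, rng):
        x = rng.uniform(300, 500, 50)
        y = rng.uniform(1, 5, 50)
        sc = AffineScaler.from_data(x, y)
        scaled = TanhParams(A=0.9, b=-0.4, c=1.2, B=0.1)
        orig = scaled_to_original(scaled, sc)
        via_scaler = sc.inverse_y(scaled.predict(sc.forward_x(x)))
        np.testing.assert_allclose(orig.predict(x), via_scaler, atol=1e-9)


class TestFit:
    def test_noiseless_recovery_across_the_bend(self):
        truth = TanhParams(A=1.0, b=-3.0, c=0.01, B=1.0)
        x = np.linspace(100, 500, 200)
        y = truth.predict(x)
        fit = fit_tanh_neuron(x, y, FitConfig(seed=0))
        rmse_vs_truth = np.sqrt(np.mean((fit.predict(x) - y) ** 2))
        assert rmse_vs_truth < 1e-6
        assert fit.params.A > 0

    def test_fitted_amplitude_always_canonical(self, tanh_dataset):
        x, y, _ = tanh_dataset
        for seed in (0, 1, 2):
            fit = fit_tanh_neuron(x, y, FitConfig(seed=seed))
            assert fit.params.A > 0

    def test_deterministic_given_seed(self, tanh_dataset):
        x, y, _ = tanh_dataset
        a = fit_tanh_neuron(x, y, FitConfig(seed=5))
        b = fit_tanh_neuron(x, y, FitConfig(seed=5))
        assert a.params == b.params
        assert a.objective_trace == b.objective_trace

    def test_order_invariance(self, tanh_dataset, rng):
        x, y, _ = tanh_dataset
        perm = rng.permutation(x.size)
        a = fit_tanh_neuron(x, y, FitConfig(seed=5))
        b = fit_tanh_neuron(x[perm], y[perm], FitConfig(seed=5))
        np.testing.assert_allclose(a.params.as_array(), b.params.as_array(),
                                   rtol=1e-6)

    def test_unit_equivariance_kcal_vs_mcal(self, tanh_dataset):
        x, y, _ = tanh_dataset
        a = fit_tanh_neuron(x, y, FitConfig(seed=5))
        b = fit_tanh_neuron(x / 1000.0, y, FitConfig(seed=5))
        assert b.params.c == pytest.approx(a.params.c * 1000.0, rel=1e-9)
        assert b.params.A == pytest.approx(a.params.A, rel=1e-9)

    def test_regularization_vanishes_without_noise(self):
        truth = TanhParams(A=1.5, b=-12.0, c=0.028, B=3.0)
        x = np.linspace(330, 530, 400)
        fit = fit_tanh_neuron(x, truth.predict(x), FitConfig(seed=1))
        assert fit.gamma == pytest.approx(4.0, abs=0.01)
        assert fit.alpha / fit.beta < 1e-9

    def test_constant_response_shrinks_amplitude_to_zero(self):
        x = np.linspace(0, 10, 60)
        fit = fit_tanh_neuron(x, np.full(60, 3.0), FitConfig(seed=1))
        assert abs(fit.params.A) < 1e-3

    def test_degenerate_inputs_error(self):
        with pytest.raises(DegenerateDesignError):
            fit_tanh_neuron(np.ones(30), np.arange(30.0), FitConfig(seed=0))
        with pytest.raises(SampleSizeError):
            fit_tanh_neuron(np.arange(4.0), np.arange(4.0), FitConfig(seed=0))


class TestRmse:
    def test_noiseless_rmse_zero(self):
        truth = TanhParams(A=1.0, b=-3.0, c=0.01, B=1.0)
        x = np.linspace(100, 500, 200)
        fit = fit_tanh_neuron(x, truth.predict(x), FitConfig(seed=0))
        assert fit.rmse < 1e-7

    def test_matches_direct_residual_computation(self, tanh_dataset):
        x, y, _ = tanh_dataset
        fit = fit_tanh_neuron(x, y, FitConfig(seed=3))
        direct = np.sqrt(np.mean((y - fit.predict(x)) ** 2))
        assert fit_rmse(fit, x, y) == pytest.approx(direct, abs=1e-12)
        assert fit.rmse == pytest.approx(direct, abs=1e-12)

    def test_rmse_estimates_noise_sd_at_large_n(self, rng):
        truth = TanhParams(A=1.8, b=-13.0, c=0.03, B=3.6)
        x = rng.uniform(300, 560, 1500)
        y = truth.predict(x) + rng.normal(0, 0.2, 1500)
        fit = fit_tanh_neuron(x, y, FitConfig(seed=9))
        assert fit.rmse == pytest.approx(0.2, rel=0.10)


class TestCurveBand:
    def test_noiseless_band_collapses(self):
        truth = TanhParams(A=1.5, b=-12.0, c=0.028, B=3.0)
        x = np.linspace(330, 530, 150)
        grid = np.linspace(340, 520, 15)
        mean, lo, hi = curve_band(x, truth.predict(x), grid,
                                  FitConfig(seed=2), n_boot=20, seed=2)
        assert np.max(hi - lo) <= 1e-6

    def test_band_contains_point_estimate_and_is_deterministic(self, tanh_dataset):
        x, y, _ = tanh_dataset
        grid = np.linspace(320, 540, 12)
        mean, lo, hi = curve_band(x, y, grid, FitConfig(seed=4), n_boot=30, seed=4)
        assert np.all(lo <= mean + 1e-9) and np.all(mean <= hi + 1e-9)
        mean2, lo2, hi2 = curve_band(x, y, grid, FitConfig(seed=4), n_boot=30, seed=4)
        np.testing.assert_array_equal(lo, lo2)
        np.testing.assert_array_equal(hi, hi2)
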