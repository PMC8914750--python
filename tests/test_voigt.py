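"""Voigt grip-force model: derivative, prediction, least-squares fitting."""

import numpy as np
import pytest

import fmgrip as fg
from fmgrip.voigt import VoigtModel, VoigtParams, estimate_derivative


def _random_params(rng, angle=0):
    return VoigtParams(a=rng.normal(size=12), b=rng.normal(size=12),
                       c=float(rng.normal()), angle=angle)


class TestEstimateDerivative:
    def test_constant_channel_gives_zero(self):
        X = np.full((50, 12), 3.0)
        np.testing.assert_array_equal(estimate_derivative(X, 0.01), 0.0)

    def test_exact_on_linear_ramp(self):
        t = np.arange(100) * 0.01
        X = np.outer(t, np.full(12, 2.5))  # slope 2.5 per channel
        d = estimate_derivative(X, 0.01)
        np.testing.assert_allclose(d, 2.5, atol=1e-12)

    def test_sine_matches_analytic_derivative(self):
        t = np.arange(1000) / 1000.0
        x = np.sin(2 * np.pi * t)
        d = estimate_derivative(x[:, None], 0.001)[:, 0]
        truth = 2 * np.pi * np.cos(2 * np.pi * t)
        assert np.abs(d[1:-1] - truth[1:-1]).max() < 1e-3

    def test_rejects_bad_dt_and_short_series(self):
        with pytest.raises(ValueError):
            estimate_derivative(np.zeros((10, 12)), 0.0)
        with pytest.raises(ValueError):
            estimate_derivative(np.zeros((2, 12)), 0.01)


class TestPredictForce:
    def test_rest_state_returns_offset(self, rng):
        p = _random_params(rng)
        assert fg.predict_force(p, np.zeros(12), np.zeros(12)) == pytest.approx(p.c)

    def test_single_channel_term(self):
        a = np.zeros(12)
        a[2] = 1.0
        p = VoigtParams(a=a, b=np.zeros(12), c=0.0, angle=0)
        X = np.zeros(12)
        X[2] = 2.0
        assert fg.predict_force(p, X, np.zeros(12)) == pytest.approx(2.0)

    def test_affine_combination_of_states(self, rng):
        p = _random_params(rng)
        p = VoigtParams(a=p.a, b=p.b, c=0.0, angle=0)
        s1, s2 = rng.normal(size=(2, 24))
        for alpha in (0.0, 0.3, 1.0):
            mix = alpha * s1 + (1 - alpha) * s2
            f = fg.predict_force(p, mix[:12], mix[12:])
            f1 = fg.predict_force(p, s1[:12], s1[12:])
            f2 = fg.predict_force(p, s2[:12], s2[12:])
            assert f == pytest.approx(alpha * f1 + (1 - alpha) * f2)

    def test_rejects_non_finite_state(self, rng):
        p = _random_params(rng)
        X = np.zeros(12)
        X[0] = np.nan
        with pytest.raises(ValueError):
            fg.predict_force(p, X, np.zeros(12))


class TestFitParams:
    def test_zero_noise_recovery_matches_pinv_oracle(self, zero_noise_cfg):
        trial = fg.generate_grip_trial(-90, zero_noise_cfg, rng_seed=4)
        dt = 1.0 / zero_noise_cfg.sampling_rate
        Xdot = estimate_derivative(trial.volts_clean, dt)
        rep = fg.fit_params(trial.volts_clean, Xdot, trial.force_true, -90)
        p = zero_noise_cfg.true_params[-90]
        assert np.abs(rep.params.a - p.a).max() < 1e-6
        assert np.abs(rep.params.b - p.b).max() < 1e-6
        assert abs(rep.params.c - p.c) < 1e-6
        assert rep.Q < 1e-12
        # independent oracle: normal equations via pseudo-inverse
        A = np.hstack([trial.volts_clean, Xdot, np.ones((len(trial.t), 1))])
        coef = np.linalg.pinv(A) @ trial.force_true
        np.testing.assert_allclose(
            np.concatenate([rep.params.a, rep.params.b, [rep.params.c]]),
            coef, atol=1e-8)

    def test_constant_design_absorbed_by_intercept(self):
        n = 30
        X = np.full((n, 12), 2.0)
        Xdot = np.zeros((n, 12))
        rep = fg.fit_params(X, Xdot, np.full(n, 7.0), 0)
        model_pred = X @ rep.params.a + Xdot @ rep.params.b + rep.params.c
        np.testing.assert_allclose(model_pred, 7.0, atol=1e-9)
        assert rep.Q < 1e-12
        assert rep.condition_warning  # rank-deficient design

    def test_row_duplication_leaves_fit_unchanged(self, zero_noise_cfg):
        trial = fg.generate_grip_trial(0, zero_noise_cfg, rng_seed=6)
        dt = 1.0 / zero_noise_cfg.sampling_rate
        Xdot = estimate_derivative(trial.volts_clean, dt)
        r1 = fg.fit_params(trial.volts_clean, Xdot, trial.force_true, 0)
        r2 = fg.fit_params(np.vstack([trial.volts_clean] * 2),
                           np.vstack([Xdot] * 2),
                           np.concatenate([trial.force_true] * 2), 0)
        np.testing.assert_allclose(r1.params.a, r2.params.a, atol=1e-8)
        np.testing.assert_allclose(r1.params.b, r2.params.b, atol=1e-8)

    def test_underdetermined_fit_rejected(self, rng):
        with pytest.raises(ValueError):
            fg.fit_params(rng.normal(size=(20, 12)), rng.normal(size=(20, 12)),
                          rng.normal(size=20), 0)

    def test_fitted_q_never_exceeds_true_param_q(self, default_cfg):
        trial = fg.generate_grip_trial(0, default_cfg, rng_seed=8)
        dt = 1.0 / default_cfg.sampling_rate
        Xdot = estimate_derivative(trial.volts_meas, dt)
        rep = fg.fit_params(trial.volts_meas, Xdot, trial.force_meas, 0)
        p = default_cfg.true_params[0]
        resid_true = trial.force_meas - (
            trial.volts_meas @ p.a + Xdot @ p.b + p.c)
        assert rep.Q <= resid_true @ resid_true + 1e-9

    def test_refit_on_predictions_is_idempotent(self, zero_noise_cfg):
        trial = fg.generate_grip_trial(90, zero_noise_cfg, rng_seed=10)
        dt = 1.0 / zero_noise_cfg.sampling_rate
        Xdot = estimate_derivative(trial.volts_clean, dt)
        r1 = fg.fit_params(trial.volts_clean, Xdot, trial.force_true, 90)
        pred = (trial.volts_clean @ r1.params.a + Xdot @ r1.params.b
                + r1.params.c)
        r2 = fg.fit_params(trial.volts_clean, Xdot, pred, 90)
        np.testing.assert_allclose(r1.params.a, r2.params.a, atol=1e-8)

    def test_recovery_error_shrinks_with_noise(self):
        """Mean |a - a_true| is monotone over force-noise levels 0/0.5/1.0 N."""
        errors = []
        for sd in (0.0, 0.5, 1.0):
            cfg = fg.SynthConfig(noise=fg.NoiseConfig(photo_sd=0.0,
                                                      hall_sd=0.0,
                                                      force_sd=sd))
            errs = []
            for seed in range(20):
                trial = fg.generate_grip_trial(0, cfg, rng_seed=seed)
                dt = 1.0 / cfg.sampling_rate
                Xdot = estimate_derivative(trial.volts_clean, dt)
                rep = fg.fit_params(trial.volts_clean, Xdot,
                                    trial.force_meas, 0)
                p = cfg.true_params[0]
                errs.append(np.mean(np.abs(
                    np.concatenate([rep.params.a - p.a, rep.params.b - p.b]))))
            errors.append(np.mean(errs))
        assert errors[0] < errors[1] < errors[2]


class TestVoigtModelEstimator:
    def test_sklearn_params_roundtrip(self):
        model = VoigtModel(angle=90, ridge=0.1)
        assert VoigtModel(**model.get_params()).angle == 90

    def test_fit_predict_on_stacked_design(self, rng):
        truth = np.concatenate([rng.normal(size=24), [1.5]])
        X = rng.normal(size=(200, 24))
        y = X @ truth[:24] + truth[24]
        model = VoigtModel().fit(X, y)
        np.testing.assert_allclose(model.coef_, truth, atol=1e-8)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-8)

    def test_params_bank_json_roundtrip(self, tmp_path, default_cfg):
        from fmgrip.voigt import load_params_bank, save_params_bank

        path = tmp_path / "bank.json"
        save_params_bank(default_cfg.true_params, path)
        back = load_params_bank(path)
        assert set(back) == {-90, 0, 90}
        np.testing.assert_allclose(back[0].a, default_cfg.true_params[0].a)
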