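"""Sensor-physics generator: response curves, ADC, Hall field, grip trials."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fmgrip as fg
from fmgrip import synth
from fmgrip.voigt import estimate_derivative


class TestPhotoresistorResponse:
    def test_zero_deformation_gives_dark_voltage(self, default_cfg):
        curve = default_cfg.photo_curve
        assert fg.photoresistor_response(0.0, curve) == curve.v_dark

    def test_saturates_at_deep_compression(self, default_cfg):
        curve = default_cfg.photo_curve
        assert fg.photoresistor_response(1e6, curve) == pytest.approx(
            curve.v_sat, abs=1e-9)

    def test_strictly_monotone_over_characterized_range(self, default_cfg):
        # full 0..15 mm table at 1 mm steps, as in the bench characterization
        v = fg.photoresistor_response(np.arange(16.0), default_cfg.photo_curve)
        assert np.all(np.diff(v) > 0)

    @pytest.mark.parametrize("bad", [-0.5, np.nan, np.inf])
    def test_rejects_invalid_deformation(self, bad, default_cfg):
        with pytest.raises(ValueError):
            fg.photoresistor_response(bad, default_cfg.photo_curve)


class TestQuantizeAdc:
    def test_lsb_is_4_88_mv(self):
        assert round(fg.AdcConfig().lsb * 1000, 2) == 4.88

    def test_zero_maps_to_zero(self):
        assert fg.quantize_adc(0.0) == 0.0

    def test_overrange_clamps_to_full_scale(self):
        assert fg.quantize_adc(6.0) == 5.0

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=0.0, max_value=5.0))
    def test_quantization_error_within_half_lsb(self, v):
        adc = fg.AdcConfig()
        assert abs(fg.quantize_adc(v, adc) - v) <= adc.lsb / 2 + 1e-12


class TestHallResponse:
    def test_peak_at_sensor_phase(self, default_cfg):
        geom = default_cfg.hall_geometry
        for i in (1, 2, 3):
            peak = fg.hall_response(geom.phases_deg[i - 1], i, geom)
            assert peak == pytest.approx(geom.baseline + geom.amplitudes[i - 1])

    def test_even_symmetry_at_zero_phase(self):
        geom = fg.HallGeometry(phases_deg=(0.0, 0.0, 0.0))
        for th in (10.0, 45.0, 90.0):
            assert fg.hall_response(th, 1, geom) == pytest.approx(
                fg.hall_response(-th, 1, geom))

    def test_three_angle_signatures_pairwise_distinct(self, default_cfg):
        vecs = {a: np.array([fg.hall_response(a, i, default_cfg.hall_geometry)
                             for i in (1, 2, 3)]) for a in (-90, 0, 90)}
        for a in (-90, 0, 90):
            for b in (-90, 0, 90):
                if a < b:
                    assert np.linalg.norm(vecs[a] - vecs[b]) > 0.1

    def test_rejects_bad_sensor_index(self):
        with pytest.raises(ValueError):
            fg.hall_response(0.0, 4)


class TestGripTrial:
    def test_zero_noise_trial_recovers_true_params(self, zero_noise_cfg):
        # independent pseudo-inverse oracle on the emitted design matrix
        trial = fg.generate_grip_trial(0, zero_noise_cfg, rng_seed=11)
        dt = 1.0 / zero_noise_cfg.sampling_rate
        A = np.hstack([trial.volts_clean,
                       estimate_derivative(trial.volts_clean, dt),
                       np.ones((len(trial.t), 1))])
        coef = np.linalg.pinv(A) @ trial.force_true
        p = zero_noise_cfg.true_params[0]
        truth = np.concatenate([p.a, p.b, [p.c]])
        assert np.allclose(coef, truth, atol=1e-6)

    def test_zero_noise_model_closure_before_adc(self, zero_noise_cfg):
        trial = fg.generate_grip_trial(90, zero_noise_cfg, rng_seed=3)
        dt = 1.0 / zero_noise_cfg.sampling_rate
        p = zero_noise_cfg.true_params[90]
        f = (trial.volts_clean @ p.a
             + estimate_derivative(trial.volts_clean, dt) @ p.b + p.c)
        assert np.abs(trial.force_true - f).max() < 1e-9

    @pytest.mark.parametrize("angle", [-90, 0, 90])
    def test_forces_stay_within_meter_range(self, angle, default_cfg):
        trial = fg.generate_grip_trial(angle, default_cfg, rng_seed=5)
        for f in (trial.force_true, trial.force_meas):
            assert f.min() >= 0.0 and f.max() <= 35.0

    def test_force_tracks_mean_deformation(self, default_cfg):
        from fmgrip.evaluate import pearson_correlation

        trial = fg.generate_grip_trial(0, default_cfg, rng_seed=9)
        r = pearson_correlation(trial.force_meas, trial.volts_meas.mean(axis=1))
        assert r >= 0.96

    def test_quantized_voltages_within_adc_range(self, default_cfg):
        trial = fg.generate_grip_trial(0, default_cfg, rng_seed=5)
        assert trial.volts_meas.min() >= 0.0
        assert trial.volts_meas.max() <= default_cfg.adc.v_ref

    def test_unknown_angle_rejected(self, default_cfg):
        with pytest.raises(ValueError):
            fg.generate_grip_trial(45, default_cfg)

    def test_identical_seed_gives_byte_identical_csv(self, default_cfg):
        outs = []
        for _ in range(2):
            trial = fg.generate_grip_trial(0, default_cfg, rng_seed=21)
            buf = io.StringIO()
            synth.write_stream_csv(trial.to_frame(), buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]


class TestCorruption:
    def test_dropout_changes_exactly_100_samples(self):
        from fmgrip.preprocess import HallWindow

        vals = np.linspace(0.1, 0.9, 600)  # strictly positive everywhere
        w = HallWindow(values=vals, label=0, t_start=0.0)
        out = fg.corrupt_window(w, "dropout", rng_seed=2)
        diff = np.flatnonzero(out.values != vals)
        assert len(out) == len(w)
        assert len(diff) == 100
        assert np.all(out.values[diff] == 0.0)
        assert diff.max() - diff.min() == 99  # contiguous run

    def test_zero_spikes_is_identity(self, small_windows):
        w = small_windows[1]
        out = fg.corrupt_window(w, "spikes", rng_seed=2, n_spikes=0)
        assert np.array_equal(out.values, w.values)

    def test_label_never_altered(self, small_windows):
        for mode in ("spikes", "dropout"):
            out = fg.corrupt_window(small_windows[2], mode, rng_seed=3)
            assert out.label == small_windows[2].label

    def test_dropout_rejected_on_short_window(self):
        from fmgrip.preprocess import HallWindow

        w = HallWindow(values=np.zeros(60), label=0, t_start=0.0)
        with pytest.raises(ValueError):
            fg.corrupt_window(w, "dropout")


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path, default_cfg):
        path = tmp_path / "cfg.yaml"
        default_cfg.to_yaml(path)
        back = fg.SynthConfig.from_yaml(path)
        assert back.sampling_rate == default_cfg.sampling_rate
        assert set(back.true_params) == {-90, 0, 90}
        np.testing.assert_allclose(back.true_params[0].a,
                                   default_cfg.true_params[0].a)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            fg.SynthConfig(sampling_rate=0)
        with pytest.raises(ValueError):
            fg.SynthConfig(noise=fg.NoiseConfig(photo_sd=-1))
        bank = fg.default_params_bank()
        del bank[0]
        with pytest.raises(ValueError):
            fg.SynthConfig(true_params=bank)
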