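"""Phantom generator: determinism, ground-truth consistency and regime
realism."""

import numpy as np
import pytest
from scipy.integrate import quad

from thermoflow.metrics import intercorrelation
from thermoflow.synth import (
    PROFILE_CYCLE_MEAN,
    GroundTruth,
    PhantomConfig,
    generate_series,
    preset_config,
    respiratory_profile,
)
from thermoflow.flow import warp_image


def _still_config(**kw):
    base = dict(
        grid=(1, 48, 48), n_frames=24, mode="gated",
        displacement_amplitude=0.0, gating_jitter=0.0, noise_sd=0.0,
        drift_rate=0.0, peak_delta_t=0.0, max_signal_drop=0.0,
        heating_window=(18, 23), seed=11,
    )
    base.update(kw)
    return PhantomConfig(**base)


class TestConfigValidation:
    def test_heating_window_outside_series_rejected(self):
        with pytest.raises(ValueError, match="heating_window"):
            PhantomConfig(n_frames=30, heating_window=(10, 40))

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="n_frames"):
            PhantomConfig(n_frames=10)

    def test_signal_drop_bounds(self):
        with pytest.raises(ValueError, match="max_signal_drop"):
            PhantomConfig(max_signal_drop=1.5)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = PhantomConfig(grid=(1, 32, 32), n_frames=22, seed=3,
                            heating_window=(18, 21))
        s1, t1 = generate_series(cfg)
        s2, t2 = generate_series(cfg)
        assert np.array_equal(s1.magnitude, s2.magnitude)
        assert np.array_equal(s1.phase, s2.phase)
        assert np.array_equal(t1.true_delta_t, t2.true_delta_t)

    def test_different_seed_differs(self):
        kw = dict(grid=(1, 32, 32), n_frames=22, heating_window=(18, 21))
        s1, _ = generate_series(PhantomConfig(seed=3, **kw))
        s2, _ = generate_series(PhantomConfig(seed=4, **kw))
        assert not np.array_equal(s1.magnitude, s2.magnitude)


class TestStillPhantom:
    def test_all_frames_identical_without_motion_noise_heat(self):
        series, _ = generate_series(_still_config())
        assert np.allclose(series.magnitude, series.magnitude[0], atol=1e-12)
        assert np.allclose(series.phase, series.phase[0], atol=1e-12)

    def test_phase_subtraction_recovers_true_temperature(self):
        """With no dropout/drift/motion, standard phase subtraction at
        the true reference inverts the PRF forward model exactly."""
        cfg = _still_config(peak_delta_t=30.0)
        series, truth = generate_series(cfg)
        dphi = np.angle(np.exp(1j * (series.phase - series.phase[0])))
        rec = dphi / cfg.thermometry.rad_per_degree
        assert np.max(np.abs(rec - truth.true_delta_t)) < 1e-9

    def test_noise_tolerance_of_recovery(self):
        cfg = _still_config(peak_delta_t=30.0, noise_sd=0.02, seed=12)
        series, truth = generate_series(cfg)
        dphi = np.angle(np.exp(1j * (series.phase - series.phase[0])))
        rec = dphi / cfg.thermometry.rad_per_degree
        body = series.magnitude[0, 0] > 0.3
        err = (rec - truth.true_delta_t)[:, 0][:, body]
        # phase noise ~ noise_sd/SNR rad maps to a few tenths of a °C
        assert np.sqrt(np.mean(err**2)) < 2.0


class TestGroundTruth:
    def test_no_heat_before_window(self):
        cfg = _still_config(peak_delta_t=40.0, heating_window=(18, 23))
        _, truth = generate_series(cfg)
        assert np.all(truth.true_delta_t[:18] == 0)
        assert truth.true_delta_t[22].max() > 30.0

    def test_true_flow_registers_moving_frame(self):
        """Warping a moving frame by the stored true flow must land on
        the undisplaced template frame (amplitude zero at end-exhale)."""
        cfg = PhantomConfig(
            grid=(1, 64, 64), n_frames=24, mode="fixed_frequency",
            displacement_amplitude=4.0, noise_sd=0.0, drift_rate=0.0,
            peak_delta_t=0.0, max_signal_drop=0.0, heating_window=(20, 23),
            seed=13,
        )
        series, truth = generate_series(cfg)
        t = int(np.argmax(truth.amplitudes))
        assert truth.amplitudes[t] > 3.0
        warped, valid = warp_image(series.magnitude[t], truth.true_flow[t])
        still = int(np.argmin(truth.amplitudes))
        ref = series.magnitude[still]
        inner = valid & (series.magnitude[still] > 0.2)
        inner[:, :6] = inner[:, -6:] = False
        err = np.abs(warped - ref)[inner]
        assert np.sqrt(np.mean(err**2)) < 0.03 * np.ptp(ref)

    def test_mean_displacement_matches_analytic_profile(self):
        """Cycle-averaged amplitude equals displacement_amplitude times
        the analytic mean of the breathing profile."""
        cfg = PhantomConfig(
            grid=(1, 32, 32), n_frames=470, mode="fixed_frequency",
            frame_interval=0.1, respiratory_period=4.7,
            displacement_amplitude=4.0, heating_window=(400, 469), seed=1,
        )
        _, truth = generate_series(cfg)
        analytic, _ = quad(lambda x: respiratory_profile(x), 0, 2 * np.pi)
        analytic /= 2 * np.pi
        assert analytic == pytest.approx(PROFILE_CYCLE_MEAN, rel=1e-9)
        assert truth.amplitudes.mean() == pytest.approx(
            4.0 * PROFILE_CYCLE_MEAN, rel=0.01
        )


class TestRegimeRealism:
    def test_gated_intercorrelation_above_0p95(self):
        cfg = PhantomConfig(grid=(1, 96, 96), n_frames=20, mode="gated",
                            displacement_amplitude=4.5, gating_jitter=0.3,
                            peak_delta_t=0.0, max_signal_drop=0.0,
                            heating_window=(16, 19), seed=5)
        series, _ = generate_series(cfg)
        ref = series.magnitude[0]
        scores = [intercorrelation(series.magnitude[t], ref)
                  for t in range(1, 16)]
        assert min(scores) > 0.95

    def test_fixed_frequency_intercorrelation_above_0p9(self):
        cfg = PhantomConfig(grid=(1, 128, 128), n_frames=30,
                            mode="fixed_frequency",
                            displacement_amplitude=4.5, peak_delta_t=0.0,
                            max_signal_drop=0.0, heating_window=(25, 29),
                            seed=5)
        series, _ = generate_series(cfg)
        ref = series.magnitude[0]
        scores = [intercorrelation(series.magnitude[t], ref)
                  for t in range(1, 30)]
        assert min(scores) > 0.9
        assert min(scores) < 0.95  # genuinely lower than the gated regime


class TestPresets:
    def test_fixed_frequency_preset_fields(self):
        cfg = preset_config("fixed_frequency_paper")
        assert cfg.frame_interval == 2.0
        assert cfg.peak_delta_t == pytest.approx(50.0)
        assert cfg.max_signal_drop == pytest.approx(0.5)
        assert cfg.grid[0] == 13
        assert cfg.voxel_spacing == (2.5, 2.5, 3.0)

    def test_gated_preset_fields(self):
        cfg = preset_config("gated_paper")
        assert cfg.mode == "gated"
        assert 3.5 <= cfg.frame_interval <= 5.0
        assert cfg.grid[0] == 13

    def test_gated_preset_near_still_sampling(self):
        cfg = preset_config("gated_paper", grid=(1, 32, 32), n_frames=20,
                            heating_window=(16, 19))
        _, truth = generate_series(cfg)
        # residual inter-frame motion is a small fraction of the breathing
        # amplitude: that is what gating is for
        assert np.abs(truth.amplitudes).max() < 0.3 * cfg.displacement_amplitude

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValueError, match="gated_paper"):
            preset_config("nope")
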