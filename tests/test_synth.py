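"""Simulator: trajectory shape, sensor fixtures, coupling and determinism."""

import numpy as np
import pytest

from mwicp.core import InvalidConfigError
from mwicp.preprocess import refine_minimum
from mwicp.synth import (
    CouplingModel,
    SimulationConfig,
    make_pressure_trajectory,
    make_sensor_profile,
    simulate_trial,
)


def _linear_cfg(**kw):
    base = dict(duration_s=120.0, ramp_curvature=0.0, lead_jitter_s=0.0,
                ref_rate_hz=1000.0, seed=3)
    base.update(kw)
    return SimulationConfig(**base)


class TestPressureTrajectory:
    def test_default_ramp_terminates_at_60_mmhg(self):
        traj = make_pressure_trajectory(_linear_cfg())
        assert traj.ramp_mmhg[-1] == pytest.approx(60.0)
        assert traj.p_mmhg.max() >= 60.0

    def test_ramp_component_is_nondecreasing_with_flat_lead(self):
        traj = make_pressure_trajectory(SimulationConfig(
            duration_s=60.0, ref_rate_hz=1000.0, seed=11))
        assert np.all(np.diff(traj.ramp_mmhg) >= 0)
        lead = traj.times_s < traj.lead_s
        assert np.all(traj.p_mmhg[lead] == 0.0)

    def test_zero_pulse_amplitude_gives_monotone_trajectory(self):
        traj = make_pressure_trajectory(_linear_cfg(
            pulse_amplitude_mmhg=0.0))
        assert np.all(np.diff(traj.p_mmhg) >= 0)

    def test_beat_mean_recovers_linear_ramp_at_beat_center(self):
        """Zero-mean pulsation: averaging each full beat leaves the ramp."""
        cfg = _linear_cfg(pulse_amplitude_mmhg=2.0, pulse_rate_bpm=60.0,
                          ref_rate_hz=5000.0, lead_s=5.0)
        traj = make_pressure_trajectory(cfg)
        rate = cfg.ref_rate_hz
        beat = int(rate)  # 1 s beats at 60 bpm
        start = int(cfg.lead_s * rate)
        for b in range(3, 100, 17):
            a = start + b * beat
            # independent oracle: trapezoidal mean over one full beat
            mean = np.trapezoid(traj.p_mmhg[a:a + beat + 1],
                                traj.times_s[a:a + beat + 1])
            center = traj.times_s[a] + 0.5
            slope = cfg.p_max_mmhg / (cfg.duration_s - cfg.lead_s)
            expected = (center - cfg.lead_s) * slope
            assert mean == pytest.approx(expected, rel=1e-6)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(duration_s=0.0)
        with pytest.raises(InvalidConfigError):
            SimulationConfig(pulse_rate_bpm=-1.0)


class TestSensorProfiles:
    def test_sensor_a_reflection_dip_location_and_depth(self, default_grid):
        profile = make_sensor_profile("A")
        curve = profile.sxx_mag_db(default_grid.frequencies_ghz)
        loc, val = refine_minimum(curve, default_grid.frequencies_ghz)
        assert loc == pytest.approx(3.565, abs=1e-6)
        assert val == pytest.approx(-35.3, abs=0.01)

    def test_sensor_b_transmission_dip(self, default_grid):
        profile = make_sensor_profile("B")
        curve = profile.sxy_mag_db(default_grid.frequencies_ghz)
        i = int(np.argmin(curve))
        assert default_grid.frequencies_ghz[i] == pytest.approx(3.604)
        assert curve[i] == pytest.approx(-65.87, abs=0.01)

    @pytest.mark.parametrize("sensor,f0", [
        ("C", 2.886), ("D", 3.21), ("E", 3.8), ("F", 4.4)])
    def test_remaining_sensors_resonate_at_documented_frequencies(
            self, sensor, f0, default_grid):
        profile = make_sensor_profile(sensor)
        curve = profile.sxx_mag_db(default_grid.frequencies_ghz)
        loc, _ = refine_minimum(curve, default_grid.frequencies_ghz)
        assert loc == pytest.approx(f0, abs=default_grid.spacing_ghz)

    def test_unknown_sensor_rejected(self):
        with pytest.raises(InvalidConfigError):
            make_sensor_profile("Z")


class TestSimulateTrial:
    def test_zero_coupling_zero_noise_reproduces_baseline(self, clean_config):
        trial = simulate_trial(clean_config)
        profile = make_sensor_profile("A")
        base = profile.baseline(clean_config.grid)
        for frame in trial.frames[:: len(trial.frames) // 4]:
            np.testing.assert_array_equal(frame.sxx_mag_db, base["sxx_mag"])
            np.testing.assert_array_equal(frame.sxy_mag_db, base["sxy_mag"])
            np.testing.assert_array_equal(frame.sxx_phase_rad,
                                          base["sxx_phase"])

    def test_resonance_shift_matches_analytic_translation(self):
        """Final-sweep dip sits where the shifted baseline's argmin sits."""
        cfg = _linear_cfg(
            duration_s=40.0, lead_s=2.0,
            trace_noise_db=0.0, trace_noise_phase_rad=0.0,
            pulse_amplitude_mmhg=0.0,
            coupling=CouplingModel(
                alpha_mag_db_per_mmhg=0.0,
                beta_freq_mhz_per_mmhg=0.1,
                gamma_phase_rad_per_mmhg=0.0,
            ))
        trial = simulate_trial(cfg)
        ref = trial.reference
        k, t_c = trial.triggers[-1]
        width = 1.0 / cfg.sweep_rate_hz
        mask = np.abs(ref.times_s - t_c) <= width / 2 + 1e-12
        p_eff = ref.p_mmhg[mask].mean()  # independent window mean
        f = cfg.grid.frequencies_ghz
        profile = make_sensor_profile("A")
        expected = profile.sxx_mag_db(f - 0.1e-3 * p_eff)
        got = trial.frames[k].sxx_mag_db
        assert int(np.argmin(got)) == int(np.argmin(expected))
        # the dip must have moved off the baseline bin
        assert int(np.argmin(got)) != int(np.argmin(profile.sxx_mag_db(f)))

    def test_same_seed_is_bit_identical(self, fast_config):
        a = simulate_trial(fast_config)
        b = simulate_trial(fast_config)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa.sxx_mag_db, fb.sxx_mag_db)
            np.testing.assert_array_equal(fa.sxy_phase_rad, fb.sxy_phase_rad)
        np.testing.assert_array_equal(a.reference.p_mmhg, b.reference.p_mmhg)
        assert a.triggers == b.triggers

    def test_different_seed_changes_noise(self, fast_config):
        from dataclasses import replace
        a = simulate_trial(fast_config)
        b = simulate_trial(replace(fast_config, seed=fast_config.seed + 1))
        assert not np.array_equal(a.frames[0].sxx_mag_db,
                                  b.frames[0].sxx_mag_db)

    def test_sweep_count_conservation(self, fast_config, fast_trial):
        expected = int(np.floor(
            fast_config.duration_s * fast_config.sweep_rate_hz))
        assert len(fast_trial.frames) == expected
        assert len(fast_trial.triggers) == expected

    def test_trace_noise_calibration(self, small_grid):
        """Per-bin temporal std of magnitude matches the configured RMS."""
        cfg = SimulationConfig(
            grid=small_grid, duration_s=350.0, ref_rate_hz=50.0,
            lead_s=0.0, lead_jitter_s=0.0, pulse_amplitude_mmhg=0.0,
            p_max_mmhg=1e-9,  # essentially constant pressure
            coupling=CouplingModel(0.0, 0.0, 0.0),
            seed=21,
        )
        trial = simulate_trial(cfg)
        mags = trial.channel("sxx_mag")
        assert mags.shape[0] >= 1000
        std = mags.std(axis=0).mean()
        assert std == pytest.approx(cfg.trace_noise_db, rel=0.1)

    def test_amplitude_coupling_is_linear(self, small_grid):
        def run(alpha):
            cfg = SimulationConfig(
                grid=small_grid, duration_s=20.0, ref_rate_hz=500.0,
                trace_noise_db=0.0, trace_noise_phase_rad=0.0,
                ramp_curvature=0.0, lead_jitter_s=0.0,
                coupling=CouplingModel(alpha, 0.0, 0.0), seed=5)
            trial = simulate_trial(cfg)
            base = make_sensor_profile("A").sxx_mag_db(
                small_grid.frequencies_ghz)
            return trial.channel("sxx_mag") - base

        np.testing.assert_allclose(2.0 * run(-0.05), run(-0.1),
                                   rtol=0, atol=1e-12)

    def test_shift_outside_grid_rejected(self, small_grid):
        cfg_kw = dict(grid=small_grid, duration_s=10.0, ref_rate_hz=500.0)
        with pytest.raises(InvalidConfigError):
            simulate_trial(SimulationConfig(
                coupling=CouplingModel(beta_freq_mhz_per_mmhg=50.0),
                **cfg_kw))
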