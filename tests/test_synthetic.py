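"""Simulator: default profiles, injected structure, cohort generator."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import signal as sg

from tvor.geometry import required_eye_trace
from tvor.preprocess import detect_blinks, resample_to_200
from tvor.stats import ols_adjusted_r2
from tvor.synthetic import (default_profile, simulate_cohort, simulate_eye,
                            simulate_head_pitch)


class TestDefaultProfile:
    def test_published_anchor_delays(self):
        a = default_profile("A")
        assert a.delays_ms[(1.0, 3)] == 37.0          # constant at 1.0 Hz
        assert a.delays_ms[(0.8, 1)] == 2.0
        assert a.delays_ms[(0.8, 6)] == 37.0
        assert a.delays_ms[(1.6, 1)] == 72.0
        assert a.delays_ms[(1.6, 6)] == 40.0
        assert a.delays_ms[(1.2, 1)] == 60.0          # interpolated default
        b = default_profile("B", "dorsiflexion")
        assert b.delays_ms[(0.254, 1)] == -137.0
        assert default_profile("B", "plantarflexion").delays_ms[(0.254, 1)] == -19.0
        assert b.delays_ms[(1.589, 11)] == 40.0
        assert all(b.delays_ms[k] == 41.0 for k in b.delays_ms if k[1] > 11)

    def test_gain_structure(self):
        a = default_profile("A")
        assert a.gains[(1.6, 1)] == pytest.approx(0.57)
        assert a.gains[(1.6, 6)] == pytest.approx(0.73)
        assert a.gains[(1.0, 4)] == pytest.approx(0.64)
        grand = np.mean(list(a.gains.values()))
        assert grand == pytest.approx(0.64, abs=0.01)
        b = default_profile("B", "dorsiflexion")
        assert set(b.gains.values()) == {0.74}

    def test_unknown_experiment_rejected(self):
        with pytest.raises(ValueError):
            default_profile("C")


class TestSimulateEye:
    def test_identity_configuration_reproduces_required_trace(self, expa_platform):
        prof = default_profile("A").noiseless()
        prof = replace(prof, delays_ms={k: 0.0 for k in prof.delays_ms},
                       gains={k: 1.0 for k in prof.gains})
        trial = simulate_eye(expa_platform, prof, 0)
        t = trial.eye.t
        required = -np.rad2deg(np.arctan2(
            12.5 * np.sin(np.deg2rad(expa_platform.plan.angle_at(t))), 50.0))
        assert np.allclose(trial.eye.eye_deg, required, atol=1e-12)

    def test_injected_delay_recovered_by_cross_correlation(self, expa_platform):
        # brute-force oracle: peak of the cross-correlation between eye and
        # required trace inside a 1.0 Hz window sits at the injected delay
        prof = default_profile("A").noiseless()
        delay = 40.0
        prof = replace(prof, delays_ms={k: delay for k in prof.delays_ms})
        trial = simulate_eye(expa_platform, prof, 0)
        eye200 = resample_to_200(trial.eye)
        req = required_eye_trace(expa_platform).eye_deg
        w = [w for w in expa_platform.cycle_windows
             if w.frequency_hz == 1.0][2]
        i0, i1 = int(w.start_s * 200), int(w.end_s * 200)
        lags = np.arange(-30, 31)
        xc = [np.dot(eye200.eye_deg[i0 + k:i1 + k], req[i0:i1]) for k in lags]
        best_ms = lags[int(np.argmax(xc))] / 200.0 * 1000.0
        assert best_ms == pytest.approx(delay, abs=1000.0 / 200.0)

    def test_blinks_counted_and_detected(self, expa_platform):
        prof = replace(default_profile("A").noiseless(), blink_rate_hz=0.2)
        trial = simulate_eye(expa_platform, prof, 31)
        intervals = detect_blinks(resample_to_200(trial.eye))
        # rate 0.2/s over 40.96 s -> expect a handful of blinks, all found
        assert 3 <= len(intervals) <= 16

    def test_seed_determinism_bit_exact(self, expb_platform):
        prof = default_profile("B", "plantarflexion")
        a = simulate_eye(expb_platform, prof, 99)
        b = simulate_eye(expb_platform, prof, 99)
        assert np.array_equal(a.eye.eye_deg, b.eye.eye_deg)
        assert np.array_equal(a.head_pitch_velocity, b.head_pitch_velocity)

    def test_seed_sequence_not_mutated(self, expb_platform):
        prof = default_profile("B", "plantarflexion")
        ss = np.random.SeedSequence(5)
        a = simulate_eye(expb_platform, prof, ss)
        b = simulate_eye(expb_platform, prof, ss)
        assert np.array_equal(a.eye.eye_deg, b.eye.eye_deg)

    def test_gain_linearity(self, expa_platform):
        base = default_profile("A").noiseless()
        double = replace(base, gains={k: 2 * v for k, v in base.gains.items()})
        t1 = simulate_eye(expa_platform, base, 0)
        t2 = simulate_eye(expa_platform, double, 0)
        w = expa_platform.cycle_windows[14]
        m = (t1.eye.t >= w.start_s) & (t1.eye.t < w.end_s)
        a1 = np.ptp(t1.eye.eye_deg[m])
        a2 = np.ptp(t2.eye.eye_deg[m])
        assert a2 == pytest.approx(2 * a1, rel=1e-6)

    def test_excessive_delay_rejected(self, expb_platform):
        prof = default_profile("B", "plantarflexion")
        bad = replace(prof, delays_ms={k: 900.0 for k in prof.delays_ms})
        with pytest.raises(ValueError):
            simulate_eye(expb_platform, bad, 0)

    def test_quantization_step(self, expa_platform):
        prof = replace(default_profile("A"), blink_rate_hz=0.0)
        trial = simulate_eye(expa_platform, prof, 7)
        steps = np.round(trial.eye.eye_deg / 0.02)
        assert np.allclose(trial.eye.eye_deg, steps * 0.02, atol=1e-12)


class TestHeadPitch:
    def test_zero_amplitude_gives_zeros(self, expa_platform):
        prof = replace(default_profile("A"), drift_amplitude_deg=0.0)
        assert not simulate_head_pitch(expa_platform, prof, 3).any()

    def test_velocity_integrates_back_to_zero(self, expa_platform):
        prof = default_profile("A")
        vel = simulate_head_pitch(expa_platform, prof, 3)
        # the pitch excursion returns toward zero outside stimulation, so
        # the net angle change over the trial is a small fraction of the
        # drift scale
        net = np.trapezoid(vel, dx=1.0 / prof.eye_fs)
        assert abs(net) < 0.1 * prof.drift_amplitude_deg

    def test_band_limited(self, expb_platform):
        prof = default_profile("B", "plantarflexion")
        vel = simulate_head_pitch(expb_platform, prof, 8)
        f, p = sg.periodogram(vel, fs=prof.eye_fs)
        assert p[f > 0.5].sum() / p.sum() < 0.05


class TestCohort:
    def test_matches_published_summary(self):
        df = simulate_cohort(n=200, seed=1)
        assert df.weight_kg.mean() == pytest.approx(67.4, abs=2.5)
        assert df.head_neck_length_cm.mean() == pytest.approx(25.5, abs=0.6)
        assert df.head_neck_mass_kg.mean() == pytest.approx(5.5, abs=0.25)
        assert df.stride_frequency_hz.mean() == pytest.approx(0.99, abs=0.03)
        assert (df.eye_height_cm > df.c7_height_cm).all()

    def test_default_cohort_mean_stride(self):
        means = [simulate_cohort(n=20, seed=s).stride_frequency_hz.mean()
                 for s in range(12)]
        assert np.mean(means) == pytest.approx(0.99, abs=0.02)

    def test_adjusted_r2_calibration(self):
        vals = []
        for s in range(40):
            df = simulate_cohort(n=20, seed=s)
            out = ols_adjusted_r2(
                df.stride_frequency_hz,
                df[["head_neck_length_cm", "head_neck_mass_kg"]].to_numpy())
            vals.append(out["adj_r2"])
        assert np.mean(vals) == pytest.approx(0.37, abs=0.08)

    def test_noiseless_plane_gives_unit_r2(self):
        df = simulate_cohort(n=20, seed=2)
        y = (0.99 - 0.022 * (df.head_neck_length_cm - 25.5)
             - 0.045 * (df.head_neck_mass_kg - 5.5))
        out = ols_adjusted_r2(
            y, df[["head_neck_length_cm", "head_neck_mass_kg"]].to_numpy())
        assert out["adj_r2"] == pytest.approx(1.0)

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            simulate_cohort(n=2, seed=0)
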