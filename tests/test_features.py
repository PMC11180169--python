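"""Signal-processing chain: filters, masking, and the four pursuit measures."""

import numpy as np
import pytest
from scipy.signal import savgol_filter

from spemlab.features import (
    ExtractionConfig,
    EyeTrace,
    SampleMask,
    acceleration_onset,
    count_mask_events,
    detect_blinks,
    detect_saccades,
    differentiate_velocity,
    extract_features,
    gaussian_lowpass,
    initial_acceleration,
    maintenance_gain,
    pursuit_latency,
)
from spemlab.simulate import SubjectProfile, simulate_session, simulate_trial
from spemlab.stimulus import TaskConfig, make_step_ramp_trajectory

FS = 500.0


class TestGaussianLowpass:
    def test_dc_preserved(self):
        out = gaussian_lowpass(np.full(500, 5.0), cutoff=30.0)
        assert np.allclose(out, 5.0)

    def test_minus_3db_at_cutoff(self):
        # analytic Gaussian frequency response: amplitude 1/sqrt(2) at 30 Hz
        t = np.arange(5000) / FS
        x = np.sin(2 * np.pi * 30.0 * t)
        y = gaussian_lowpass(x, cutoff=30.0)
        core = slice(500, -500)
        ratio = np.abs(y[core]).max() / np.abs(x[core]).max()
        assert ratio == pytest.approx(1.0 / np.sqrt(2.0), abs=0.02)

    def test_linear_ramp_unchanged_in_interior(self):
        t = np.arange(1000) / FS
        x = 18.7 * t
        y = gaussian_lowpass(x, cutoff=30.0)
        assert np.allclose(y[100:-100], x[100:-100], atol=1e-6)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            gaussian_lowpass(np.zeros(100), cutoff=300.0)


class TestMedianDifferentiation:
    def test_exact_on_linear_input(self):
        t = np.arange(500) / FS
        v = differentiate_velocity(18.7 * t, span=9.0)
        assert np.allclose(v[2:-2], 18.7, atol=1e-9)

    def test_quadratic_error_bounded(self):
        # x = 0.5*80*t^2 -> v = 80 t; central differences are exact on
        # quadratics up to O(dt^2) Taylor error
        t = np.arange(500) / FS
        v = differentiate_velocity(0.5 * 80.0 * t**2, span=9.0)
        assert np.max(np.abs(v[2:-2] - 80.0 * t[2:-2])) < 0.5

    def test_spike_attenuated_vs_plain_central_difference(self):
        x = np.zeros(101)
        x[50] = 1.0
        v = differentiate_velocity(x, span=9.0)
        dt = 1.0 / FS
        plain = np.abs(np.gradient(x, dt)).max()
        assert np.abs(v).max() < plain

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            differentiate_velocity(np.zeros(3), span=9.0)


class TestBlinkMask:
    def _trace(self, valid):
        n = len(valid)
        return EyeTrace(
            times=np.arange(n) * 2.0,
            eye_positions=np.zeros(n),
            valid=np.asarray(valid, bool),
            sampling_rate=FS,
        )

    def test_no_invalid_samples_empty_mask(self):
        mask = detect_blinks(self._trace(np.ones(200)), pad=50.0)
        assert not mask.excluded.any()

    def test_run_padded_both_sides(self):
        valid = np.ones(500, bool)
        valid[200:250] = False  # 100 ms
        mask = detect_blinks(self._trace(valid), pad=50.0)
        # 100 ms run + 50 ms pads = 200 ms = 100 samples (+1 boundary sample)
        assert mask.excluded.sum() == pytest.approx(100, abs=1)
        assert mask.excluded[175] and mask.excluded[274]

    def test_simulated_blink_count_recovered(self, task_config):
        profile = SubjectProfile(blink_rate=0.2, noise_sd=0.0)
        session = simulate_session(task_config, profile, seed=6)
        inserted = sum(
            int(np.sum(np.diff(np.concatenate(([0], (~tr.valid).view(np.int8)))) == 1))
            for tr in session
        )
        detected = sum(
            count_mask_events(detect_blinks(tr, pad=50.0), "blink") for tr in session
        )
        assert detected == inserted


class TestSaccadeMask:
    def test_pure_pursuit_clean(self, task_config):
        profile = SubjectProfile(
            true_gain_predictive=1.0, true_gain_early=1.0,
            saccade_threshold=np.inf, blink_rate=0.0, noise_sd=0.0,
        )
        sr = make_step_ramp_trajectory(task_config, 1)
        trace = simulate_trial(sr, profile, seed=0)
        from spemlab.features import _prepare_trial

        vel, mask = _prepare_trial(trace, ExtractionConfig())
        assert count_mask_events(mask, "saccade") == 0

    def test_inserted_saccades_detected(self, task_config):
        # low gain forces periodic catch-up saccades over a long trial
        from spemlab.features import _prepare_trial
        from spemlab.stimulus import make_triangular_trajectory

        profile = SubjectProfile(
            true_gain_predictive=0.75, true_gain_early=0.75,
            saccade_threshold=1.5, blink_rate=0.0, noise_sd=0.0,
        )
        tri = make_triangular_trajectory(task_config, 1, n_ramps=4)
        trace = simulate_trial(tri, profile, seed=2)
        dt = 1.0 / FS
        v = np.abs(np.diff(trace.eye_positions) / dt)
        n_true = int(np.sum((v[1:] > 40) & (v[:-1] <= 40)))
        assert n_true >= 1
        vel, mask = _prepare_trial(trace, ExtractionConfig())
        assert count_mask_events(mask, "saccade") == n_true

    def test_masked_fraction_covers_saccade_and_padding(self):
        # synthetic 4 deg / 40 ms saccade on a flat trace
        n = 600
        t = np.arange(n) / FS
        pos = np.zeros(n)
        sl = slice(300, 320)  # 40 ms
        pos[300:] = 4.0
        pos[sl] = 4.0 * (np.arange(20) + 1) / 20.0
        vel = differentiate_velocity(gaussian_lowpass(pos, 30.0), 9.0)
        mask = detect_saccades(vel, None, ExtractionConfig(), FS)
        assert mask.excluded[sl].all()
        assert mask.excluded.sum() >= 20  # at least the saccade itself


class TestMaintenanceGain:
    def _flat_tracking_trial(self, task_config, eye_gain):
        profile = SubjectProfile(
            true_gain_predictive=eye_gain, true_gain_early=eye_gain,
            saccade_threshold=np.inf, blink_rate=0.0, noise_sd=0.0,
        )
        from spemlab.features import _prepare_trial
        from spemlab.stimulus import make_triangular_trajectory

        tri = make_triangular_trajectory(task_config, 1, n_ramps=2)
        trace = simulate_trial(tri, profile, seed=0)
        vel, mask = _prepare_trial(trace, ExtractionConfig())
        return tri, vel, mask

    def test_090_gain_recovered(self, task_config):
        trial = self._flat_tracking_trial(task_config, 0.90)
        gain, n = maintenance_gain([trial], (300.0, 840.0), "reversal")
        assert gain == pytest.approx(0.90, abs=0.005)
        assert n == 1

    def test_perfect_tracking_gain_one(self, task_config):
        trial = self._flat_tracking_trial(task_config, 1.0)
        gain, _ = maintenance_gain([trial], (300.0, 840.0), "reversal")
        assert gain == pytest.approx(1.0, abs=0.005)

    def test_median_robust_to_masked_saccade(self, task_config):
        # masking a 40 ms stretch inside a 540 ms window must not move the
        # pooled median appreciably
        trial, vel, mask = self._flat_tracking_trial(task_config, 0.9)
        clean, _ = maintenance_gain([(trial, vel, mask)], (300.0, 840.0), "reversal")
        mask2 = SampleMask(mask.excluded.copy(), dict(mask.reasons))
        r0 = trial.reversal_times[0]
        extra = (trial.times >= r0 + 500) & (trial.times < r0 + 540)
        mask2.add("saccade", extra)
        dirty, _ = maintenance_gain([(trial, vel, mask2)], (300.0, 840.0), "reversal")
        assert dirty == pytest.approx(clean, abs=0.02)

    def test_no_contributing_trials_returns_none(self):
        gain, n = maintenance_gain([], (300.0, 840.0), "reversal")
        assert gain is None and n == 0


class TestOnsetAndAcceleration:
    def _step_trial(self, task_config, profile, seed=0):
        from spemlab.features import _prepare_trial

        sr = make_step_ramp_trajectory(task_config, 1)
        trace = simulate_trial(sr, profile, seed=seed)
        vel, mask = _prepare_trial(trace, ExtractionConfig())
        return sr, vel, mask

    def test_zero_velocity_gives_null_onset(self, task_config):
        sr = make_step_ramp_trajectory(task_config, 1)
        onset = acceleration_onset(np.zeros(sr.n_samples), sr)
        assert onset is None

    def test_noiseless_onset_near_true_latency(self, task_config):
        profile = SubjectProfile(
            true_latency=176.0, true_accel=80.0,
            saccade_threshold=np.inf, blink_rate=0.0, noise_sd=0.0,
        )
        sr, vel, mask = self._step_trial(task_config, profile)
        onset = acceleration_onset(vel, sr, mask)
        assert onset - sr.motion_onset == pytest.approx(176.0, abs=2.0)

    def test_savgol_preserves_cubics(self):
        # polynomial-preservation property the onset detector relies on
        t = np.arange(400) / FS
        x = 3.0 + 2.0 * t - 5.0 * t**2 + 40.0 * t**3
        y = savgol_filter(x, 63, 3)
        core = slice(63, -63)
        assert np.allclose(y[core], x[core], atol=1e-9)

    def test_linear_velocity_slope_exact(self, task_config):
        sr = make_step_ramp_trajectory(task_config, 1)
        vel = np.clip(80.0 * (sr.times - 576.0) / 1000.0, 0.0, None)
        slope = initial_acceleration(vel, sr, onset=600.0)
        assert slope == pytest.approx(80.0, rel=0.02)

    def test_robust_slope_resists_outliers(self, task_config):
        rng = np.random.default_rng(0)
        sr = make_step_ramp_trajectory(task_config, 1)
        vel = np.clip(80.0 * (sr.times - 576.0) / 1000.0, 0.0, None)
        w = (sr.times >= 600.0) & (sr.times < 700.0)
        idx = np.flatnonzero(w)
        bad = rng.choice(idx, size=len(idx) // 10, replace=False)
        vel = vel.copy()
        vel[bad] += 50.0
        cfg = ExtractionConfig(savgol_frame=5)  # minimal smoothing, near-raw series
        slope = initial_acceleration(vel, sr, onset=600.0, cfg=cfg)
        assert slope == pytest.approx(80.0, rel=0.05)
        ols = np.polyfit((sr.times[w] - 600.0) / 1000.0, vel[w], 1)[0]
        assert abs(ols - 80.0) > 0.05 * 80.0  # OLS fails this bound

    def test_zero_velocity_after_onset_gives_zero_slope(self, task_config):
        sr = make_step_ramp_trajectory(task_config, 1)
        slope = initial_acceleration(np.zeros(sr.n_samples), sr, onset=600.0)
        assert slope == 0.0

    def test_latency_is_onset_minus_motion_onset(self, task_config):
        sr = make_step_ramp_trajectory(task_config, 1)
        assert pursuit_latency(576.0, sr) == pytest.approx(176.0)
        assert pursuit_latency(sr.motion_onset, sr) == 0.0


class TestExtractFeatures:
    def test_noiseless_round_trip(self, noiseless_session, noiseless_profile):
        f = extract_features(noiseless_session)
        assert f.gain_predictive == pytest.approx(0.93, abs=0.02)
        assert f.gain_early == pytest.approx(0.79, abs=0.02)
        assert f.initial_accel == pytest.approx(80.0, rel=0.10)
        assert f.latency == pytest.approx(176.0, abs=2.0)

    @pytest.mark.parametrize("noise_sd,gain_tol,lat_tol,acc_rel", [
        (0.01, 0.02, 5.0, 0.10),
        (0.05, 0.03, 8.0, 0.15),
    ])
    def test_recovery_degrades_gracefully_with_noise(
        self, task_config, noise_sd, gain_tol, lat_tol, acc_rel
    ):
        profile = SubjectProfile(blink_rate=0.0, noise_sd=noise_sd)
        session = simulate_session(task_config, profile, seed=42)
        f = extract_features(session)
        assert f.gain_predictive == pytest.approx(0.93, abs=gain_tol)
        assert f.gain_early == pytest.approx(0.79, abs=gain_tol)
        assert f.initial_accel == pytest.approx(80.0, rel=acc_rel)
        assert f.latency == pytest.approx(176.0, abs=lat_tol)

    def test_direction_symmetry(self, noiseless_session):
        mirrored = []
        for tr in noiseless_session:
            trial = tr.trial
            import copy

            t2 = copy.copy(trial)
            t2.positions = -trial.positions
            t2.velocities = -trial.velocities
            t2.direction = -trial.direction
            m = EyeTrace(
                times=tr.times,
                eye_positions=-tr.eye_positions,
                valid=tr.valid,
                sampling_rate=tr.sampling_rate,
                trial=t2,
            )
            mirrored.append(m)
        a = extract_features(noiseless_session).as_dict()
        b = extract_features(mirrored).as_dict()
        for k in a:
            assert b[k] == pytest.approx(a[k], abs=1e-9)

    def test_trial_order_invariance(self, noiseless_session):
        a = extract_features(noiseless_session).as_dict()
        b = extract_features(list(reversed(noiseless_session))).as_dict()
        assert a == b

    def test_step_ramp_free_session_nulls_accel_latency(self, task_config, noiseless_profile):
        session = [
            tr for tr in simulate_session(task_config, noiseless_profile, seed=1)
            if tr.trial.task_kind == "full_ramp"
        ]
        f = extract_features(session)
        assert f.initial_accel is None and f.latency is None
        assert f.gain_predictive is not None and f.gain_early is None

    def test_empty_session_all_null(self):
        f = extract_features([])
        assert all(v is None for v in f.as_dict().values())

    def test_deterministic(self, noiseless_session):
        assert extract_features(noiseless_session).as_dict() == extract_features(
            noiseless_session
        ).as_dict()
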