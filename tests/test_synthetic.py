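"""Generator correctness: reach geometry, Poisson tuning statistics, drift."""

import numpy as np
import pytest

from alignnet.synthetic import (DriftSpec, NO_DRIFT, TuningModel, apply_day_drift,
                                default_tuning, make_centerout_trajectory,
                                make_raw_recording, make_session, make_tuned_spikes,
                                spike_template)
from alignnet.preprocessing import detect_spikes


class TestTrajectory:
    def test_noiseless_geometry_reaches_unit_target(self):
        traj = make_centerout_trajectory(0.0, 100, noise_sd=0.0)
        assert np.allclose(traj[:, 0], [0.0, 0.0])
        assert abs(traj[0, -1] - 1.0) < 1e-9 and abs(traj[1, -1]) < 1e-9

    def test_vertical_reach_is_symmetric(self):
        traj = make_centerout_trajectory(np.pi / 2, 50, noise_sd=0.0)
        assert np.abs(traj[0]).max() < 1e-12
        assert abs(traj[1, -1] - 1.0) < 1e-9

    def test_same_seed_bit_identical(self):
        a = make_centerout_trajectory(1.0, 100, 0.05, seed=3)
        b = make_centerout_trajectory(1.0, 100, 0.05, seed=3)
        assert np.array_equal(a, b)

    def test_rejects_degenerate_length(self):
        with pytest.raises(ValueError):
            make_centerout_trajectory(0.0, 1)


def _flat_tuning(n_ch, baseline, gain, pd=0.0):
    return TuningModel(preferred_direction=np.full(n_ch, pd),
                       gain=np.full(n_ch, float(gain)),
                       baseline=np.full(n_ch, float(baseline)),
                       relevant=np.ones(n_ch, bool))


class TestTunedSpikes:
    def test_zero_rate_gives_zero_counts(self):
        behavior = np.zeros((2, 50))
        counts = make_tuned_spikes(behavior, _flat_tuning(4, 0.0, 30.0), seed=0)
        assert counts.shape == (4, 50)
        assert counts.sum() == 0

    def test_baseline_poisson_mean_matches_closed_form(self):
        # gain 0 => homogeneous Poisson with rate r; Monte-Carlo mean over
        # 10,000 bins must sit within 3 standard errors of r * bin_width
        r, bw, nbins = 20.0, 0.02, 10_000
        behavior = np.zeros((2, nbins))
        counts = make_tuned_spikes(behavior, _flat_tuning(1, r, 0.0), bw, seed=5)
        lam = r * bw
        se = np.sqrt(lam / nbins)
        assert abs(counts.mean() - lam) < 3 * se

    def test_cosine_tuning_prefers_preferred_direction(self):
        tuning = _flat_tuning(1, 1.0, 30.0, pd=0.0)
        pref = opp = 0
        for k in range(100):
            t0 = make_centerout_trajectory(0.0, 100, 0.0)
            t1 = make_centerout_trajectory(np.pi, 100, 0.0)
            pref += make_tuned_spikes(t0, tuning, seed=2 * k).sum()
            opp += make_tuned_spikes(t1, tuning, seed=2 * k + 1).sum()
        assert pref > opp

    def test_rejects_nonpositive_bin_width(self):
        with pytest.raises(ValueError):
            make_tuned_spikes(np.zeros((2, 5)), _flat_tuning(1, 1, 1), bin_width=-0.1)


class TestDayDrift:
    def test_day_zero_is_identity(self):
        tuning = default_tuning(seed=0)
        out = apply_day_drift(tuning, DriftSpec(seed=1), day=0)
        assert np.array_equal(out.preferred_direction, tuning.preferred_direction)
        assert np.array_equal(out.gain, tuning.gain)

    def test_rotation_accumulates_linearly(self):
        tuning = _flat_tuning(4, 1.0, 10.0, pd=0.5)
        drift = DriftSpec(rotation_per_day=0.1, gain_multiplier=1.0,
                          dropout_prob=0.0, baseline_jitter=0.0, seed=0)
        out = apply_day_drift(tuning, drift, day=3)
        assert np.allclose(out.preferred_direction, (0.5 + 0.3) % (2 * np.pi))

    def test_full_dropout_silences_all_channels(self):
        tuning = default_tuning(seed=0)
        drift = DriftSpec(dropout_prob=1.0, seed=0)
        out = apply_day_drift(tuning, drift, day=1)
        assert np.all(out.gain == 0) and np.all(out.baseline == 0)

    def test_dropout_never_increases_expected_population_count(self):
        # monotonicity in expectation, averaged over seeds
        totals = {p: [] for p in (0.0, 0.4)}
        for p in totals:
            for seed in range(5):
                tuning = default_tuning(seed=seed)
                drift = DriftSpec(rotation_per_day=0.0, gain_multiplier=1.0,
                                  dropout_prob=p, baseline_jitter=0.0, seed=seed)
                sess = make_session(16, day=2, tuning=tuning, drift=drift, seed=seed)
                totals[p].append(sess.spikes().sum())
        assert np.mean(totals[0.4]) < np.mean(totals[0.0])

    def test_negative_day_rejected(self):
        with pytest.raises(ValueError):
            apply_day_drift(default_tuning(), DriftSpec(), day=-1)


class TestSession:
    def test_directions_balanced_over_80_trials(self):
        sess = make_session(80, day=0, seed=0)
        counts = np.bincount(sess.directions(), minlength=8)
        assert np.all(counts == 10)

    def test_same_seed_same_day_bit_identical(self):
        a = make_session(10, day=0, seed=4)
        b = make_session(10, day=0, seed=4)
        assert np.array_equal(a.spikes(), b.spikes())
        assert np.array_equal(a.behavior(), b.behavior())

    def test_counts_are_nonnegative_integers(self, session8):
        s = session8.spikes()
        assert s.dtype.kind == "i" and s.min() >= 0

    def test_drift_changes_mean_firing_rates(self):
        tuning = default_tuning(seed=0)
        drift = DriftSpec(rotation_per_day=0.2, gain_multiplier=0.9,
                          dropout_prob=0.05, baseline_jitter=1.0, seed=0)
        s0 = make_session(40, day=0, tuning=tuning, drift=drift, seed=0)
        s5 = make_session(40, day=5, tuning=tuning, drift=drift, seed=0)
        r0 = s0.spikes().mean(axis=(0, 2))
        r5 = s5.spikes().mean(axis=(0, 2))
        assert np.linalg.norm(r0 - r5) > 0

    def test_zero_drift_days_statistically_exchangeable(self):
        # same tuning, no drift: per-channel mean rates agree within
        # Monte-Carlo error at n = 500 trials
        tuning = default_tuning(seed=2)
        a = make_session(500, day=0, tuning=tuning, drift=NO_DRIFT, seed=10)
        b = make_session(500, day=3, tuning=tuning, drift=NO_DRIFT, seed=11)
        ma, mb = a.spikes().mean(axis=(0, 2)), b.spikes().mean(axis=(0, 2))
        n_bins = 500 * 100
        se = np.sqrt((ma + mb) / 2 / n_bins) + 1e-12
        assert np.all(np.abs(ma - mb) < 5 * se)


class TestRawEmulation:
    def test_zero_spikes_zero_noise_flat_voltage(self, session8):
        trial = session8.trials[0]
        silent = trial.__class__(spikes=np.zeros_like(trial.spikes),
                                 behavior=trial.behavior, day=trial.day)
        rec = make_raw_recording(silent, noise_sd=0.0, seed=0)
        assert np.all(rec.voltage == 0)
        assert rec.joystick.shape[0] == 2

    def test_single_spike_yields_single_detectable_event(self, session8):
        trial = session8.trials[0]
        spikes = np.zeros_like(trial.spikes)
        spikes[5, 0] = 1
        one = trial.__class__(spikes=spikes, behavior=trial.behavior, day=trial.day)
        rec = make_raw_recording(one, noise_sd=1.0, seed=0)
        # trough must dwarf the noise floor
        assert rec.voltage[5].min() < -5 * 1.0
        events = detect_spikes(rec, 4.5, 1e-3)
        assert len(events.times[5]) == 1
        assert abs(events.times[5][0] - rec.event_times[5][0]) <= 1e-3

    def test_rejects_non_multiple_rates(self, session8):
        with pytest.raises(ValueError):
            make_raw_recording(session8.trials[0], raw_rate=3001.0)
        with pytest.raises(ValueError):
            make_raw_recording(session8.trials[0], raw_rate=3000.0,
                               joystick_rate=4000.0)

    def test_template_trough_is_flat_and_negative(self):
        t = spike_template(amplitude=50.0)
        assert t.min() == -50.0
        assert (t == -50.0).sum() >= 3
        assert np.all(t <= 0)
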