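"""Preprocessing chain: detection, binning, resampling, smoothing, segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alignnet.preprocessing import (ContinuousRecording, PreprocessConfig,
                                    SpikeEventList, SpikeMatrix,
                                    build_spike_matrix, detect_spikes,
                                    downsample_spikes, gaussian_kernel,
                                    interpolate_linear, segment_trials,
                                    smooth_gaussian)
from alignnet.synthetic import spike_template


def _recording(voltage, rate=30000.0):
    voltage = np.atleast_2d(voltage)
    joy = np.zeros((2, 10))
    return ContinuousRecording(voltage=voltage, voltage_rate=rate,
                               joystick=joy, joystick_rate=500.0)


class TestDetectSpikes:
    def test_silent_recording_yields_no_events(self):
        events = detect_spikes(_recording(np.zeros((3, 1000))))
        assert events.n_events == 0

    def test_injected_template_found_at_injection_time(self):
        rng = np.random.default_rng(0)
        rate = 30000.0
        x = rng.normal(0, 1.0, 30000)
        tmpl = spike_template(amplitude=6.0)
        t_true = 12345
        x[t_true:t_true + len(tmpl)] += tmpl
        events = detect_spikes(_recording(x, rate), 4.5, 1e-3)
        assert len(events.times[0]) == 1
        assert abs(events.times[0][0] - (t_true + len(tmpl) // 2) / rate) < 1e-3

    def test_refractory_merges_close_pair(self):
        # two troughs 0.5 ms apart with a 1 ms refractory -> one event
        rng = np.random.default_rng(1)
        rate = 30000.0
        x = rng.normal(0, 1.0, 30000)
        tmpl = spike_template(amplitude=8.0)
        x[9000:9000 + len(tmpl)] += tmpl
        x[9015:9015 + len(tmpl)] += tmpl          # 15 samples = 0.5 ms later
        events = detect_spikes(_recording(x, rate), 4.5, 1e-3)
        assert len(events.times[0]) == 1

    def test_empty_recording_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(_recording(np.zeros((1, 0))))


class TestBuildSpikeMatrix:
    def test_no_events_all_zero(self):
        m = build_spike_matrix(SpikeEventList([np.empty(0)] * 3, duration=1.0), 50.0)
        assert m.counts.shape == (3, 50)
        assert m.counts.sum() == 0

    def test_events_in_same_bin_accumulate(self):
        ev = SpikeEventList([np.array([0.001, 0.019])], duration=0.1)
        m = build_spike_matrix(ev, 50.0)
        assert m.counts[0, 0] == 2
        assert m.counts.sum() == 2

    def test_total_count_conserved_on_random_events(self):
        rng = np.random.default_rng(3)
        ev = SpikeEventList([np.sort(rng.uniform(0, 2.0, rng.integers(0, 40)))
                             for _ in range(5)], duration=2.0)
        m = build_spike_matrix(ev, 50.0)
        assert m.counts.sum() == ev.n_events

    def test_out_of_range_event_rejected(self):
        ev = SpikeEventList([np.array([2.5])], duration=2.0)
        with pytest.raises(ValueError):
            build_spike_matrix(ev, 50.0)


class TestInterpolateLinear:
    def test_two_point_upsample(self):
        assert np.allclose(interpolate_linear([0.0, 10.0], 3), [0.0, 5.0, 10.0])

    def test_equal_lengths_identity(self):
        x = np.random.default_rng(0).normal(size=17)
        assert np.array_equal(interpolate_linear(x, 17), x)

    def test_matches_independent_piecewise_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            m = rng.integers(2, 40)
            n = rng.integers(2, 60)
            x = rng.normal(size=m)
            got = interpolate_linear(x, n)
            # independent oracle: numpy's piecewise-linear evaluator on the
            # fractional source positions
            want = np.interp(np.arange(n) * (m - 1) / (n - 1), np.arange(m), x)
            assert np.max(np.abs(got - want)) < 1e-12

    @given(a=st.floats(-5, 5), b=st.floats(-5, 5),
           m=st.integers(2, 30), n=st.integers(2, 50))
    @settings(deadline=None, max_examples=40)
    def test_exact_on_affine_sequences(self, a, b, m, n):
        x = a * np.arange(m) + b
        y = interpolate_linear(x, n)
        p = np.arange(n) * (m - 1) / (n - 1)
        assert np.allclose(y, a * p + b, atol=1e-9)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            interpolate_linear([1.0], 5)


class TestDownsample:
    def test_hand_summed_windows(self):
        m = SpikeMatrix(np.array([[1, 0, 1, 0, 0, 0]]), bin_rate=150.0)
        out = downsample_spikes(m, 3)
        assert np.array_equal(out.counts, [[2, 0]])
        assert out.bin_rate == 50.0

    def test_window_one_is_identity(self):
        m = SpikeMatrix(np.arange(12).reshape(2, 6), bin_rate=50.0)
        assert np.array_equal(downsample_spikes(m, 1).counts, m.counts)

    def test_conserves_counts_on_divisible_length(self):
        rng = np.random.default_rng(0)
        m = SpikeMatrix(rng.integers(0, 5, (4, 30)), bin_rate=500.0)
        assert downsample_spikes(m, 10).counts.sum() == m.counts.sum()

    def test_partial_window_dropped_with_warning(self):
        m = SpikeMatrix(np.ones((1, 7), dtype=int), bin_rate=50.0)
        with pytest.warns(UserWarning):
            out = downsample_spikes(m, 3)
        assert np.array_equal(out.counts, [[3, 3]])

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            downsample_spikes(SpikeMatrix(np.ones((1, 4), int), 50.0), 0)


class TestSmoothGaussian:
    def test_constants_pass_unchanged(self):
        out = smooth_gaussian(np.full(40, 5.0), sigma=2.0, half_width=6)
        assert np.max(np.abs(out - 5.0)) < 1e-12

    def test_impulse_response_central_weight(self):
        # hand-evaluated kernel: w_i = exp(-i^2/2)/sqrt(2 pi), renormalized
        i = np.arange(-3, 4)
        w = np.exp(-i**2 / 2.0) / np.sqrt(2 * np.pi)
        expected = w[3] / w.sum()                 # ~0.39905
        x = np.zeros(21)
        x[10] = 1.0
        out = smooth_gaussian(x, sigma=1.0, half_width=3)
        assert abs(out[10] - expected) < 1e-12
        assert abs(expected - 0.3990502796524549) < 1e-12

    def test_output_bounded_by_input_range(self):
        x = np.random.default_rng(2).normal(size=100)
        out = smooth_gaussian(x, 2.0)
        assert out.min() >= x.min() - 1e-12 and out.max() <= x.max() + 1e-12

    @given(shift=st.floats(-10, 10), scale=st.floats(0.1, 10))
    @settings(deadline=None, max_examples=25)
    def test_linear_and_shift_equivariance(self, shift, scale):
        x = np.random.default_rng(5).normal(size=50)
        base = smooth_gaussian(x, 2.0, 6)
        assert np.allclose(smooth_gaussian(x + shift, 2.0, 6), base + shift, atol=1e-9)
        assert np.allclose(smooth_gaussian(x * scale, 2.0, 6), base * scale, atol=1e-9)

    def test_kernel_normalized(self):
        assert abs(gaussian_kernel(2.0, 6).sum() - 1.0) < 1e-12

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian(np.ones(10), sigma=0.0)


class TestSegmentTrials:
    def _streams(self, n):
        rng = np.random.default_rng(0)
        return (SpikeMatrix(rng.integers(0, 3, (4, n)), 50.0),
                rng.normal(size=(2, n)))

    def test_exact_partition(self):
        spikes, beh = self._streams(300)
        trials = segment_trials(spikes, beh, [0, 100, 200])
        assert len(trials) == 3
        rebuilt = np.concatenate([t.spikes for t in trials], axis=1)
        assert np.array_equal(rebuilt, spikes.counts)

    def test_trailing_short_segment_dropped(self):
        spikes, beh = self._streams(250)
        trials = segment_trials(spikes, beh, [0, 100, 200])
        assert len(trials) == 2

    def test_mismatched_lengths_rejected(self):
        spikes, _ = self._streams(200)
        with pytest.raises(ValueError):
            segment_trials(spikes, np.zeros((2, 150)), [0])


class TestEndToEndConservation:
    def test_detected_events_survive_binning_and_downsampling(self):
        rng = np.random.default_rng(4)
        ev = SpikeEventList([np.sort(rng.uniform(0, 2.0, 30)) for _ in range(3)],
                            duration=2.0)
        hi = build_spike_matrix(ev, 500.0)
        lo = downsample_spikes(hi, 10)
        assert hi.counts.sum() == ev.n_events == lo.counts.sum()
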