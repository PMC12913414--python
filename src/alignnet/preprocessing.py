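"""Preprocessing chain from raw voltage to aligned 50 Hz trials.

Steps, in pipeline order: threshold spike detection on the continuous
multi-channel recording, spike-matrix reconstruction (event binning),
linear interpolation of the behavior trace onto a target length, spike
downsampling by window summation, Gaussian smoothing of behavior, and
segmentation into fixed-length trials (64 channels x 100 points at 50 Hz,
behavior 2 x 100).

Conventions: 0-based time indexing, half-open bins [t, t+1); all arithmetic
in float64.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

TRIAL_RATE_HZ = 50.0
TRIAL_LEN = 100


@dataclass
class ContinuousRecording:
    """Raw high-rate voltage plus a lower-rate 2-D joystick trace."""

    voltage: np.ndarray          # (channels, samples)
    voltage_rate: float          # Hz
    joystick: np.ndarray         # (2, samples)
    joystick_rate: float         # Hz
    event_times: list[np.ndarray] | None = None   # ground truth, seconds

    def __post_init__(self):
        self.voltage = np.asarray(self.voltage, dtype=np.float64)
        self.joystick = np.asarray(self.joystick, dtype=np.float64)
        if self.voltage_rate <= 0 or self.joystick_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if not (np.all(np.isfinite(self.voltage)) and np.all(np.isfinite(self.joystick))):
            raise ValueError("recording contains non-finite values")

    @property
    def duration(self) -> float:
        return self.voltage.shape[1] / self.voltage_rate


@dataclass
class SpikeEventList:
    """Per-channel sorted spike times in seconds."""

    times: list[np.ndarray]
    duration: float

    def __post_init__(self):
        self.times = [np.sort(np.asarray(t, dtype=np.float64)) for t in self.times]

    @property
    def n_channels(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(sum(len(t) for t in self.times))


@dataclass
class SpikeMatrix:
    counts: np.ndarray           # (channels, bins) non-negative integers
    bin_rate: float              # Hz

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")


@dataclass
class Trial:
    """One aligned sample: spike counts (C x T) + behavior (2 x T)."""

    spikes: np.ndarray
    behavior: np.ndarray
    day: int = 0
    direction: int | None = None
    rate: float = TRIAL_RATE_HZ

    def __post_init__(self):
        self.spikes = np.asarray(self.spikes)
        self.behavior = np.asarray(self.behavior, dtype=np.float64)
        if self.spikes.shape[1] != self.behavior.shape[1]:
            raise ValueError("spikes and behavior must share time length")
        if np.any(self.spikes < 0):
            raise ValueError("spike counts must be non-negative")
        if not np.all(np.isfinite(self.behavior)):
            raise ValueError("behavior must be finite")


@dataclass
class ResampleSpec:
    """Lengths and widths of the resampling chain: interpolation source /
    target lengths, the downsampling window, and the smoothing kernel."""

    source_len: int
    target_len: int
    window: int = 1
    sigma: float = 2.0
    half_width: int = 6

    def __post_init__(self):
        if self.source_len < 2 or self.target_len < 2:
            raise ValueError("interpolation needs at least 2 points on each side")
        if self.window < 1:
            raise ValueError("window width must be >= 1")
        if self.sigma <= 0 or self.half_width < 1:
            raise ValueError("invalid smoothing parameters")


# ---- spike detection ----------------------------------------------------

def detect_spikes(recording: ContinuousRecording,
                  threshold_multiplier: float = 4.5,
                  refractory: float = 1e-3) -> SpikeEventList:
    """Negative-threshold-crossing detection with a refractory window.

    The per-channel noise scale is the median absolute deviation divided by
    0.6745 (robust Gaussian sigma); threshold = -multiplier * scale.  Each
    crossing is timed at the local minimum within one refractory window;
    subsequent crossings inside the window are suppressed.
    """
    v = recording.voltage
    if v.size == 0:
        raise ValueError("empty recording")
    rate = recording.voltage_rate
    win = max(1, int(round(refractory * rate)))
    out: list[np.ndarray] = []
    for ch in range(v.shape[0]):
        x = v[ch]
        scale = np.median(np.abs(x - np.median(x))) / 0.6745
        if scale == 0:
            scale = np.std(x)
        thr = -threshold_multiplier * scale
        if scale == 0:
            out.append(np.empty(0))
            continue
        idx = np.flatnonzero(x < thr)
        events = []
        last = -np.inf
        k = 0
        while k < len(idx):
            # one sub-threshold excursion: sub-threshold samples separated by
            # less than the refractory window belong to the same event
            end = k
            while end + 1 < len(idx) and idx[end + 1] - idx[end] <= win:
                end += 1
            seg = idx[k:end + 1]
            j = seg[int(np.argmin(x[seg]))]
            t = j / rate
            if t - last >= refractory:
                events.append(t)
                last = t
            k = end + 1
        out.append(np.asarray(events))
    return SpikeEventList(times=out, duration=recording.duration)


def build_spike_matrix(events: SpikeEventList, bin_rate: float,
                       duration: float | None = None) -> SpikeMatrix:
    """Bin events into half-open bins [t/rate, (t+1)/rate); conserves counts."""
    if bin_rate <= 0:
        raise ValueError("bin_rate must be positive")
    duration = events.duration if duration is None else duration
    n_bins = int(round(duration * bin_rate))
    counts = np.zeros((events.n_channels, n_bins), dtype=np.int64)
    for ch, times in enumerate(events.times):
        if len(times) == 0:
            continue
        if times.min() < 0 or times.max() >= duration:
            raise ValueError("event time outside [0, duration)")
        idx = np.floor(times * bin_rate).astype(np.int64)
        np.add.at(counts[ch], idx, 1)
    return SpikeMatrix(counts=counts, bin_rate=bin_rate)


# ---- resampling ---------------------------------------------------------

def interpolate_linear(x, n: int) -> np.ndarray:
    """Linear interpolation of a length-m sequence onto n points.

    y[j] = (1-a) x[floor(p_j)] + a x[ceil(p_j)] with p_j = j (m-1)/(n-1),
    a = p_j - floor(p_j); endpoints are preserved exactly.  2-D input is
    interpolated row-wise.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        return np.stack([interpolate_linear(row, n) for row in x])
    m = x.shape[0]
    if m < 2 or n < 2:
        raise ValueError("interpolation needs at least 2 points on each side")
    p = np.arange(n) * (m - 1) / (n - 1)
    lo = np.floor(p).astype(np.int64)
    hi = np.ceil(p).astype(np.int64)
    a = p - lo
    return (1.0 - a) * x[lo] + a * x[hi]


def downsample_spikes(matrix: SpikeMatrix, window: int) -> SpikeMatrix:
    """Sum counts over consecutive windows of `window` bins per channel.

    A trailing partial window (non-divisible length) is dropped with a
    warning, to avoid a rate-biased last bin.
    """
    if window <= 0:
        raise ValueError("window width must be positive")
    counts = matrix.counts
    n = counts.shape[1]
    n_keep = (n // window) * window
    if n_keep != n:
        warnings.warn(f"dropping trailing partial window of {n - n_keep} bins",
                      stacklevel=2)
    c = counts[:, :n_keep].reshape(counts.shape[0], n_keep // window, window)
    return SpikeMatrix(counts=c.sum(axis=2), bin_rate=matrix.bin_rate / window)


def gaussian_kernel(sigma: float, half_width: int) -> np.ndarray:
    """Gaussian weights G[i] = exp(-i^2 / 2 sigma^2) / (sqrt(2 pi) sigma),
    i = -k..k, renormalized to sum to 1 so constants pass unchanged."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if half_width < 1:
        raise ValueError("half-width must be >= 1")
    i = np.arange(-half_width, half_width + 1, dtype=np.float64)
    g = np.exp(-i ** 2 / (2.0 * sigma ** 2)) / (np.sqrt(2.0 * np.pi) * sigma)
    return g / g.sum()


def smooth_gaussian(x, sigma: float = 2.0, half_width: int | None = None) -> np.ndarray:
    """Correlate with a renormalized Gaussian under edge replication.

    The output is a convex combination of inputs, so it is bounded by the
    input range and leaves constants untouched.  2-D input smooths row-wise.
    """
    x = np.asarray(x, dtype=np.float64)
    if half_width is None:
        half_width = max(1, int(round(3 * sigma)))
    if x.ndim == 2:
        return np.stack([smooth_gaussian(row, sigma, half_width) for row in x])
    g = gaussian_kernel(sigma, half_width)
    xp = np.pad(x, half_width, mode="edge")
    return np.convolve(xp, g[::-1], mode="valid")


def segment_trials(spikes: SpikeMatrix, behavior: np.ndarray,
                   boundaries, *, day: int = 0,
                   directions=None, length: int = TRIAL_LEN) -> list[Trial]:
    """Cut the aligned 50 Hz streams into fixed-length trials.

    Each boundary starts a segment of `length` points; segments running past
    the end of the recording are discarded.
    """
    counts = spikes.counts
    behavior = np.asarray(behavior, dtype=np.float64)
    if counts.shape[1] != behavior.shape[1]:
        raise ValueError("spikes and behavior must share time length")
    trials = []
    for k, b in enumerate(boundaries):
        if b + length > counts.shape[1]:
            continue
        trials.append(Trial(
            spikes=counts[:, b:b + length],
            behavior=behavior[:, b:b + length],
            day=day,
            direction=None if directions is None else int(directions[k]),
            rate=spikes.bin_rate,
        ))
    return trials


# ---- full chain ---------------------------------------------------------

@dataclass
class PreprocessConfig:
    threshold_multiplier: float = 4.5
    refractory: float = 1e-3
    intermediate_rate: float = 500.0    # event-binning rate before windowed downsampling
    target_rate: float = TRIAL_RATE_HZ
    sigma: float = 2.0
    half_width: int | None = None
    trial_len: int = TRIAL_LEN


def preprocess_recording(recording: ContinuousRecording,
                         config: PreprocessConfig = PreprocessConfig(),
                         *, day: int = 0, directions=None) -> list[Trial]:
    """Run the full chain: detect -> bin -> downsample spikes; interpolate ->
    smooth behavior; segment into aligned fixed-length trials."""
    events = detect_spikes(recording, config.threshold_multiplier, config.refractory)
    hi = build_spike_matrix(events, config.intermediate_rate)
    window = int(round(config.intermediate_rate / config.target_rate))
    if window * config.target_rate != config.intermediate_rate:
        raise ValueError("intermediate rate must be an integer multiple of target rate")
    lo = downsample_spikes(hi, window)
    n_bins = lo.counts.shape[1]
    beh = interpolate_linear(recording.joystick, n_bins)
    beh = smooth_gaussian(beh, config.sigma, config.half_width)
    boundaries = range(0, n_bins, config.trial_len)
    return segment_trials(lo, beh, boundaries, day=day, directions=directions)
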