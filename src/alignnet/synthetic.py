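"""Synthetic center-out motor-cortex sessions with controllable day drift.

Generates paired trials — a 64-channel x 100-bin spike-count matrix and a
2-D cursor trajectory at 50 Hz — for the eight-direction center-out
paradigm, plus optional raw-fidelity continuous voltage for exercising the
preprocessing chain.

Generative model: minimum-jerk reaches from the origin to unit-radius
targets; Poisson spiking with rectified cosine tuning on instantaneous
velocity (the standard M1 model),

    rate_c(t) = baseline_c + gain_c * speed(t) * max(0, cos(theta(t) - pd_c)),

where pd_c is channel c's preferred direction.  Half the channels are
behavior-irrelevant (gain 0, low baseline), mirroring recordings in which
channel groups 33-64 carry little movement information.  Day-to-day drift
rotates preferred directions, scales gains, jitters baselines and drops
channels, cumulatively per day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import ContinuousRecording, Trial, smooth_gaussian

N_CHANNELS = 64
N_DIRECTIONS = 8
TRIAL_LEN = 100
TRIAL_RATE = 50.0
BIN_WIDTH = 1.0 / TRIAL_RATE


@dataclass
class TuningModel:
    """Per-channel cosine-tuning parameters."""

    preferred_direction: np.ndarray   # radians, (C,)
    gain: np.ndarray                  # Hz per unit speed, (C,)
    baseline: np.ndarray              # Hz, (C,)
    relevant: np.ndarray              # bool, (C,)

    def __post_init__(self):
        self.preferred_direction = np.asarray(self.preferred_direction, dtype=np.float64)
        self.gain = np.asarray(self.gain, dtype=np.float64)
        self.baseline = np.asarray(self.baseline, dtype=np.float64)
        self.relevant = np.asarray(self.relevant, dtype=bool)
        n = len(self.preferred_direction)
        if not (len(self.gain) == len(self.baseline) == len(self.relevant) == n):
            raise ValueError("tuning fields must share channel count")
        if np.any(self.baseline < 0) or np.any(self.gain < 0):
            raise ValueError("baseline and gain must be non-negative")

    @property
    def n_channels(self) -> int:
        return len(self.gain)


@dataclass(frozen=True)
class DriftSpec:
    """Parametric day-to-day change of the spike-behavior mapping."""

    rotation_per_day: float = 0.1      # radians
    gain_multiplier: float = 0.95      # per day
    dropout_prob: float = 0.02        # per channel per day
    baseline_jitter: float = 0.5       # Hz, sd of cumulative per-day jitter
    seed: int = 0

    def __post_init__(self):
        if not self.gain_multiplier > 0:
            raise ValueError("gain multiplier must be positive")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout probability must lie in [0, 1]")


NO_DRIFT = DriftSpec(rotation_per_day=0.0, gain_multiplier=1.0,
                     dropout_prob=0.0, baseline_jitter=0.0)


@dataclass
class SessionSet:
    """All trials of one recording day, plus generation metadata."""

    trials: list[Trial]
    day: int
    seed: int | None = None
    tuning: TuningModel | None = None
    drift: DriftSpec | None = None

    def __post_init__(self):
        if any(t.day != self.day for t in self.trials):
            raise ValueError("all trials must carry the session's day index")

    def __len__(self):
        return len(self.trials)

    def spikes(self) -> np.ndarray:
        return np.stack([t.spikes for t in self.trials])

    def behavior(self) -> np.ndarray:
        return np.stack([t.behavior for t in self.trials])

    def directions(self) -> np.ndarray:
        return np.array([t.direction for t in self.trials])


def default_tuning(n_channels: int = N_CHANNELS, seed: int = 0) -> TuningModel:
    """Half the array is direction-tuned; the second half is near-silent and
    carries no movement signal."""
    rng = np.random.default_rng(seed)
    n_rel = n_channels // 2
    pd = np.concatenate([
        (np.arange(n_rel) % N_DIRECTIONS) * 2 * np.pi / N_DIRECTIONS
        + rng.uniform(-0.2, 0.2, n_rel),
        rng.uniform(0, 2 * np.pi, n_channels - n_rel),
    ])
    gain = np.concatenate([rng.uniform(20.0, 40.0, n_rel),
                           np.zeros(n_channels - n_rel)])
    baseline = np.concatenate([rng.uniform(2.0, 8.0, n_rel),
                               rng.uniform(0.5, 2.0, n_channels - n_rel)])
    relevant = np.arange(n_channels) < n_rel
    return TuningModel(pd % (2 * np.pi), gain, baseline, relevant)


def make_centerout_trajectory(direction: float, n_points: int = TRIAL_LEN,
                              noise_sd: float = 0.02, seed: int = 0) -> np.ndarray:
    """Minimum-jerk reach from the origin to a unit-radius target.

    Position follows 10 s^3 - 15 s^4 + 6 s^5 (bell-shaped speed profile)
    along the target direction, with additive Gaussian position noise.
    Returns a (2, n_points) array; deterministic given seed.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    s = np.linspace(0.0, 1.0, n_points)
    profile = 10 * s ** 3 - 15 * s ** 4 + 6 * s ** 5
    target = np.array([np.cos(direction), np.sin(direction)])
    traj = np.outer(target, profile)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        traj = traj + rng.normal(0.0, noise_sd, traj.shape)
    return traj


def make_tuned_spikes(behavior: np.ndarray, tuning: TuningModel,
                      bin_width: float = BIN_WIDTH, seed: int = 0) -> np.ndarray:
    """Poisson counts from rectified cosine tuning on instantaneous velocity.

    Velocity is the finite-difference derivative of the (2, T) behavior at
    the trial rate; the per-bin rate is floored at zero.  Returns a
    (channels, T) integer matrix, deterministic given seed.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    behavior = np.asarray(behavior, dtype=np.float64)
    vel = np.gradient(behavior, axis=1) / bin_width
    speed = np.linalg.norm(vel, axis=0)
    theta = np.arctan2(vel[1], vel[0])
    cos_term = np.maximum(0.0, np.cos(theta[None, :] - tuning.preferred_direction[:, None]))
    rate = tuning.baseline[:, None] + tuning.gain[:, None] * speed[None, :] * cos_term
    rate = np.maximum(rate, 0.0)
    rng = np.random.default_rng(seed)
    return rng.poisson(rate * bin_width).astype(np.int64)


def apply_day_drift(tuning: TuningModel, drift: DriftSpec, day: int) -> TuningModel:
    """Drifted tuning for a given day; day 0 is the reference (unchanged).

    Rotation and gain scaling accumulate linearly/geometrically with day;
    baseline jitter and channel dropout are resampled per day from the
    drift seed and accumulate (a dropped channel stays dropped).
    """
    if day < 0:
        raise ValueError("day must be >= 0")
    if day == 0:
        return tuning
    pd = tuning.preferred_direction.copy()
    gain = tuning.gain.copy()
    baseline = tuning.baseline.copy()
    dropped = np.zeros(tuning.n_channels, dtype=bool)
    for d in range(1, day + 1):
        rng = np.random.default_rng([drift.seed, d])
        pd = pd + drift.rotation_per_day
        gain = gain * drift.gain_multiplier
        if drift.baseline_jitter > 0:
            baseline = np.maximum(
                0.0, baseline + rng.normal(0.0, drift.baseline_jitter, len(baseline)))
        dropped |= rng.random(tuning.n_channels) < drift.dropout_prob
    gain[dropped] = 0.0
    baseline[dropped] = 0.0
    return TuningModel(pd % (2 * np.pi), gain, baseline,
                       tuning.relevant & ~dropped)


def make_session(n_trials: int, day: int = 0,
                 tuning: TuningModel | None = None,
                 drift: DriftSpec = NO_DRIFT,
                 seed: int = 0, *,
                 n_points: int = TRIAL_LEN,
                 noise_sd: float = 0.02,
                 smooth_sigma: float = 2.0) -> SessionSet:
    """One day of center-out trials, directions cycling 0..7.

    Spikes are generated from the drift-adjusted tuning using the noisy
    trajectory; the stored behavior is the Gaussian-smoothed trajectory
    (what the preprocessing chain would deliver).  Reproducible from seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if tuning is None:
        tuning = default_tuning(seed=seed)
    day_tuning = apply_day_drift(tuning, drift, day)
    ss = np.random.SeedSequence([seed, day])
    child_seeds = ss.generate_state(2 * n_trials)
    trials = []
    for k in range(n_trials):
        direction_idx = k % N_DIRECTIONS
        angle = direction_idx * 2 * np.pi / N_DIRECTIONS
        traj = make_centerout_trajectory(angle, n_points, noise_sd,
                                         seed=int(child_seeds[2 * k]))
        spikes = make_tuned_spikes(traj, day_tuning, BIN_WIDTH,
                                   seed=int(child_seeds[2 * k + 1]))
        behavior = smooth_gaussian(traj, smooth_sigma) if smooth_sigma > 0 else traj
        trials.append(Trial(spikes=spikes, behavior=behavior, day=day,
                            direction=direction_idx, rate=TRIAL_RATE))
    return SessionSet(trials=trials, day=day, seed=seed,
                      tuning=day_tuning, drift=drift)


# ---- raw-fidelity emulation --------------------------------------------

def spike_template(amplitude: float = 50.0, flat: int = 4, rise: int = 2) -> np.ndarray:
    """A fixed negative-deflection waveform with a flat trough.

    The support is defined in samples, not seconds: at full acquisition rates
    an action-potential trough spans several samples, and the reduced-rate
    emulation preserves that so threshold detection sees the same number of
    chances to catch the trough.  The trough is flat over `flat` samples
    (kept within one detector refractory window) with raised-cosine
    shoulders of `rise` samples each side.
    """
    edge = np.hanning(2 * rise + 4)[1:rise + 1]
    wave = np.concatenate([edge, np.ones(flat), edge[::-1]])
    return -amplitude * wave


def make_raw_recording(trial: Trial, raw_rate: float = 3000.0,
                       joystick_rate: float = 500.0,
                       noise_sd: float = 10.0, seed: int = 0,
                       amplitude: float = 50.0) -> ContinuousRecording:
    """Expand a binned trial back into continuous voltage + joystick traces.

    Each spike count becomes that many template waveforms placed at jittered,
    evenly spaced offsets inside its 20 ms bin, over Gaussian background
    noise; behavior is linearly resampled to `joystick_rate`.  Ground-truth
    event times are kept as metadata.  Default signal-to-noise: template
    amplitude five times the noise sd.
    """
    upsample = raw_rate / trial.rate
    if abs(upsample - round(upsample)) > 1e-9:
        raise ValueError("raw_rate must be an integer multiple of the trial rate")
    if joystick_rate >= raw_rate:
        raise ValueError("joystick_rate must be below raw_rate")
    upsample = int(round(upsample))
    C, T = trial.spikes.shape
    n_samples = T * upsample
    rng = np.random.default_rng(seed)
    v = (rng.normal(0.0, noise_sd, (C, n_samples)) if noise_sd > 0
         else np.zeros((C, n_samples)))
    template = spike_template(amplitude)
    half = len(template) // 2
    event_times: list[np.ndarray] = []
    for ch in range(C):
        times = []
        for t_bin in range(T):
            count = int(trial.spikes[ch, t_bin])
            if count == 0:
                continue
            # evenly spaced slots with jitter keep within-bin events well
            # separated (>> 1 ms refractory for realistic counts)
            offsets = (np.arange(count) + 0.2 + 0.6 * rng.random(count)) / count
            for off in offsets:
                center = int((t_bin + off) * upsample)
                lo = max(0, center - half)
                hi = min(n_samples, center - half + len(template))
                v[ch, lo:hi] += template[:hi - lo]
                times.append(center / raw_rate)
        event_times.append(np.asarray(times))
    n_joy = int(round(T / trial.rate * joystick_rate))
    joystick = np.stack([np.interp(np.arange(n_joy) / joystick_rate,
                                   np.arange(T) / trial.rate, row)
                         for row in trial.behavior])
    return ContinuousRecording(voltage=v, voltage_rate=raw_rate,
                               joystick=joystick, joystick_rate=joystick_rate,
                               event_times=event_times)


def make_raw_session(session: SessionSet, raw_rate: float = 3000.0,
                     joystick_rate: float = 500.0, noise_sd: float = 10.0,
                     seed: int = 0) -> ContinuousRecording:
    """Concatenate a session's trials into one continuous recording."""
    recs = [make_raw_recording(t, raw_rate, joystick_rate, noise_sd,
                               seed=seed + i)
            for i, t in enumerate(session.trials)]
    voltage = np.concatenate([r.voltage for r in recs], axis=1)
    joystick = np.concatenate([r.joystick for r in recs], axis=1)
    dur = recs[0].duration
    events = [np.concatenate([r.event_times[ch] + i * dur
                              for i, r in enumerate(recs)])
              for ch in range(voltage.shape[0])]
    return ContinuousRecording(voltage=voltage, voltage_rate=raw_rate,
                               joystick=joystick, joystick_rate=joystick_rate,
                               event_times=events)
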