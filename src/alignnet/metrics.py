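"""Evaluation metrics and report assembly.

R-squared (coefficient of determination), Pearson correlation, and the
binary firing rate FR[i] = fraction of bins in which channel i registers at
least one spike.  Decoding reports R-squared per behavior dimension (test
trials concatenated along time) and their mean; simulation reports PCC per
channel averaged over channels with nonzero truth variance, plus a grouped
firing-rate table (8 channels per group by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd


def r_squared(y, y_hat) -> float:
    """1 - SS_res / SS_tot.  Constant truth is undefined: returns NaN with a
    warning."""
    y = np.asarray(y, dtype=np.float64).ravel()
    y_hat = np.asarray(y_hat, dtype=np.float64).ravel()
    if len(y) != len(y_hat) or len(y) < 2:
        raise ValueError("need equal-length sequences of length >= 2")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        warnings.warn("constant truth sequence: R^2 undefined", stacklevel=2)
        return float("nan")
    return float(1.0 - np.sum((y - y_hat) ** 2) / ss_tot)


def pcc(x, y) -> float:
    """Pearson correlation; zero-variance input returns NaN with a warning."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need equal-length sequences of length >= 2")
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2))
    if denom == 0:
        warnings.warn("zero-variance sequence: PCC undefined", stacklevel=2)
        return float("nan")
    return float(np.sum(xc * yc) / denom)


def firing_rate(spikes) -> np.ndarray:
    """Fraction of bins with >= 1 spike, per channel.

    Accepts (channels, time) or (trials, channels, time); trials and time
    pool into the bin axis per channel.
    """
    s = np.asarray(spikes)
    if np.any(s < 0):
        raise ValueError("spike counts must be non-negative")
    active = s >= 1
    if s.ndim == 2:
        return active.mean(axis=1)
    if s.ndim == 3:
        return active.mean(axis=(0, 2))
    raise ValueError("expected 2-D or 3-D spike array")


def channel_group_report(truth, pred, group_size: int = 8) -> pd.DataFrame:
    """Mean firing rate per channel for truth and prediction, organized into
    channel groups (64 channels / 8 -> 8 groups)."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction must share shape")
    n_ch = truth.shape[-2]
    if n_ch % group_size:
        raise ValueError(f"{n_ch} channels not divisible by group size {group_size}")
    fr_truth = firing_rate(truth)
    fr_pred = firing_rate((pred >= 0.5).astype(np.int64))  # binarize analog output
    return pd.DataFrame({
        "channel": np.arange(n_ch),
        "group": np.arange(n_ch) // group_size,
        "rate_truth": fr_truth,
        "rate_pred": fr_pred,
    })


@dataclass
class MetricsReport:
    task: str
    protocol: str
    n_test_trials: int
    r2_per_dim: list = field(default_factory=list)
    r2: float = float("nan")
    pcc_per_channel: list = field(default_factory=list)
    pcc: float = float("nan")
    n_excluded_channels: int = 0
    firing_rate_truth: list = field(default_factory=list)
    firing_rate_pred: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        return cls(**json.loads(text))


def decode_metrics(truth: np.ndarray, pred: np.ndarray) -> tuple[list, float]:
    """Per-dimension R^2 with test trials concatenated along time."""
    per_dim = [r_squared(truth[:, d, :].ravel(), pred[:, d, :].ravel())
               for d in range(truth.shape[1])]
    return per_dim, float(np.mean(per_dim))


def simulate_metrics(truth: np.ndarray, pred: np.ndarray):
    """Per-channel PCC on concatenated counts; zero-variance channels are
    excluded from the average (their correlation is undefined) and counted."""
    n_ch = truth.shape[1]
    vals, excluded = [], 0
    for c in range(n_ch):
        t = truth[:, c, :].ravel()
        if t.std() == 0:
            excluded += 1
            vals.append(float("nan"))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vals.append(pcc(t, pred[:, c, :].ravel()))
    finite = [v for v in vals if np.isfinite(v)]
    mean = float(np.mean(finite)) if finite else float("nan")
    return vals, mean, excluded


def evaluate_task(predict_fn, sessions, plan, task: str, *,
                  meta: dict | None = None) -> MetricsReport:
    """Run a fitted predictor over the plan's test split and assemble the
    report.  `predict_fn` maps an (n, C_in, T) array to (n, C_out, T)."""
    from .training import gather

    spikes, behavior = gather(sessions, plan.test_indices)
    if len(spikes) == 0:
        raise ValueError("empty test split")
    n = len(spikes)
    report = MetricsReport(task=task, protocol=plan.protocol, n_test_trials=n,
                           meta=meta or {})
    if task == "decode":
        pred = np.asarray(predict_fn(spikes))
        per_dim, pooled = decode_metrics(behavior, pred)
        report.r2_per_dim, report.r2 = per_dim, pooled
    elif task == "simulate":
        pred = np.asarray(predict_fn(behavior))
        vals, mean, excl = simulate_metrics(spikes, pred)
        report.pcc_per_channel = vals
        report.pcc = mean
        report.n_excluded_channels = excl
        report.firing_rate_truth = firing_rate(spikes.astype(np.int64)).tolist()
        report.firing_rate_pred = firing_rate((pred >= 0.5).astype(np.int64)).tolist()
    else:
        raise ValueError(f"unknown task {task!r}")
    return report
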