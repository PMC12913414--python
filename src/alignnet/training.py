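"""Pretraining, task fine-tuning, and single-/cross-day split protocols.

Pretraining jointly minimizes both reconstruction losses plus the weighted
contrastive alignment term over trials pooled across the pretraining days:

    L_total = MSE_spike + MSE_behavior + lambda_CL * L_CL.

Fine-tuning is supervised on the cross-modal path: decoding trains
spike-encoder -> behavior-decoder against ground-truth trajectories;
simulation trains behavior-encoder -> spike-decoder against raw spike
counts.  Scope is either "all" parameters or "decoder-only" (encoders
frozen).

Split protocols: single-day holds out a random 20% of one day's trials;
cross-day trains on the two days preceding a held-out test day.
Spike inputs are z-scored per channel from the training split before the
encoder; simulate-path targets stay raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AlignNet, contrastive_loss, reconstruction_loss
from .nn import Adam
from .synthetic import SessionSet


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    lr: float = 1e-3
    optimizer: str = "adam"
    lambda_contrastive: float = 0.5
    seed: int = 0
    scope: str = "all"                    # "all" | "decoder-only"
    contrastive_in_finetune: bool = False
    log_every: int = 0                    # epochs between log lines; 0 = silent
    log_fn: object = field(default=None, repr=False)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.lr <= 0:
            raise ValueError("epochs/batch_size must be >= 1 and lr > 0")
        if self.scope not in ("all", "decoder-only"):
            raise ValueError(f"unknown fine-tune scope {self.scope!r}")


@dataclass
class SplitPlan:
    """Disjoint train/test trial indices, keyed by day."""

    protocol: str                          # "single-day" | "cross-day"
    train_indices: dict
    test_indices: dict
    train_fraction: float = 0.8

    def __post_init__(self):
        for day in set(self.train_indices) & set(self.test_indices):
            if np.intersect1d(self.train_indices[day], self.test_indices[day]).size:
                raise ValueError("train/test indices overlap")

    @property
    def train_days(self):
        return sorted(self.train_indices)

    @property
    def test_days(self):
        return sorted(self.test_indices)


def split_single_day(session: SessionSet, fraction: float = 0.8,
                     seed: int = 0) -> SplitPlan:
    """Random shuffle; first floor(fraction * n) trials train, rest test."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(session)
    if n == 0:
        raise ValueError("empty session")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(fraction * n)
    return SplitPlan(protocol="single-day",
                     train_indices={session.day: np.sort(perm[:n_train])},
                     test_indices={session.day: np.sort(perm[n_train:])},
                     train_fraction=fraction)


def split_cross_day(sessions: list[SessionSet], test_day: int) -> SplitPlan:
    """All trials of the two days preceding `test_day` train; `test_day` tests."""
    days = sorted(s.day for s in sessions)
    if len(days) < 3:
        raise ValueError("cross-day protocol needs at least 3 sessions")
    if test_day not in days:
        raise ValueError(f"test day {test_day} not among sessions {days}")
    pos = days.index(test_day)
    if pos < 2:
        raise ValueError("need two days preceding the test day")
    by_day = {s.day: s for s in sessions}
    train = {d: np.arange(len(by_day[d])) for d in days[pos - 2:pos]}
    test = {test_day: np.arange(len(by_day[test_day]))}
    return SplitPlan(protocol="cross-day", train_indices=train,
                     test_indices=test, train_fraction=1.0)


def gather(sessions: list[SessionSet], indices: dict) -> tuple[np.ndarray, np.ndarray]:
    """Stack (spikes, behavior) arrays for the given day->indices map."""
    by_day = {s.day: s for s in sessions}
    spikes, behavior = [], []
    for day in sorted(indices):
        sess = by_day[day]
        for i in indices[day]:
            spikes.append(sess.trials[i].spikes)
            behavior.append(sess.trials[i].behavior)
    return np.stack(spikes).astype(np.float64), np.stack(behavior)


@dataclass
class Standardizer:
    """Per-channel z-scoring of spike counts, fit on the training split."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, spikes: np.ndarray) -> "Standardizer":
        m = spikes.mean(axis=(0, 2), keepdims=True)[0]
        s = spikes.std(axis=(0, 2), keepdims=True)[0]
        return cls(mean=m, std=np.maximum(s, 1e-3))

    def transform(self, spikes: np.ndarray) -> np.ndarray:
        return ((np.asarray(spikes, dtype=np.float64) - self.mean)
                / self.std).astype(np.float32)


def _check_finite(value: float, context: str):
    if not np.isfinite(value):
        raise RuntimeError(f"training diverged: non-finite loss during {context}")


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start:start + batch_size]


def pretrain(sessions: list[SessionSet], model: AlignNet, config: TrainConfig,
             standardizer: Standardizer | None = None):
    """Joint autoencoder + contrastive pretraining over pooled sessions.

    Returns (standardizer, per-epoch loss history).  Reproducible given
    (config.seed, data); λ_CL = 0 reduces exactly to two independent
    autoencoder objectives.
    """
    if not sessions:
        raise ValueError("no sessions supplied")
    spikes_raw = np.concatenate([s.spikes() for s in sessions]).astype(np.float64)
    behavior = np.concatenate([s.behavior() for s in sessions]).astype(np.float32)
    if standardizer is None:
        standardizer = Standardizer.fit(spikes_raw)
    xs_all = standardizer.transform(spikes_raw)
    lam = config.lambda_contrastive
    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed)
    model.train()
    history = []
    for epoch in range(config.epochs):
        tot = np.zeros(3)
        n_batch = 0
        for idx in _batches(len(xs_all), config.batch_size, rng):
            xs, xb = xs_all[idx], behavior[idx]
            lat_s = model.encode_spike(xs)
            lat_b = model.encode_behavior(xb)
            loss_s = reconstruction_loss(xs, model.decode(lat_s, "spike"))
            loss_b = reconstruction_loss(xb, model.decode(lat_b, "behavior"))
            loss = loss_s + loss_b
            cl = 0.0
            if lam > 0 and len(idx) > 1:
                cl_t = contrastive_loss(model.embed(lat_s), model.embed(lat_b),
                                        model.config.temperature,
                                        model.config.normalize_embeddings)
                loss = loss + lam * cl_t
                cl = cl_t.item()
            _check_finite(loss.item(), "pretraining")
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot += (loss_s.item(), loss_b.item(), cl)
            n_batch += 1
        avg = tot / n_batch
        entry = {"epoch": epoch, "mse_spike": avg[0], "mse_behavior": avg[1],
                 "contrastive": avg[2],
                 "total": avg[0] + avg[1] + lam * avg[2]}
        history.append(entry)
        if config.log_every and (epoch % config.log_every == 0) and config.log_fn:
            config.log_fn({"stage": "pretrain", **entry})
    return standardizer, history


def _finetune_params(model: AlignNet, task: str, scope: str):
    if scope == "all":
        return model.parameters()
    if task == "decode":
        mods = [model.behavior_decoder, model.inv_fc1, model.inv_fc2]
    else:
        mods = [model.spike_decoder]
    return [p for m in mods for p in m.parameters()]


def _finetune(model: AlignNet, plan: SplitPlan, sessions, config: TrainConfig,
              standardizer: Standardizer, task: str):
    spikes_raw, behavior = gather(sessions, plan.train_indices)
    xs_all = standardizer.transform(spikes_raw)
    xb_all = behavior.astype(np.float32)
    counts_all = spikes_raw.astype(np.float32)
    opt = Adam(_finetune_params(model, task, config.scope), lr=config.lr)
    rng = np.random.default_rng(config.seed)
    lam = config.lambda_contrastive if config.contrastive_in_finetune else 0.0
    model.train()
    history = []
    for epoch in range(config.epochs):
        tot, n_batch = 0.0, 0
        for idx in _batches(len(xs_all), config.batch_size, rng):
            if task == "decode":
                lat = model.encode_spike(xs_all[idx])
                pred = model.decode(lat, "behavior")
                loss = reconstruction_loss(xb_all[idx], pred)
            else:
                lat = model.encode_behavior(xb_all[idx])
                pred = model.decode(lat, "spike", nonneg=True)
                loss = reconstruction_loss(counts_all[idx], pred)
            if lam > 0 and len(idx) > 1:
                other = (model.encode_behavior(xb_all[idx]) if task == "decode"
                         else model.encode_spike(xs_all[idx]))
                loss = loss + lam * contrastive_loss(
                    model.embed(lat), model.embed(other),
                    model.config.temperature, model.config.normalize_embeddings)
            _check_finite(loss.item(), f"fine-tuning ({task})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot += loss.item()
            n_batch += 1
        entry = {"epoch": epoch, "loss": tot / n_batch}
        history.append(entry)
        if config.log_every and (epoch % config.log_every == 0) and config.log_fn:
            config.log_fn({"stage": f"finetune-{task}", **entry})
    return history


def finetune_decode(model: AlignNet, plan: SplitPlan, sessions,
                    config: TrainConfig, standardizer: Standardizer):
    """Supervised spike -> behavior fine-tuning on the plan's train split."""
    return _finetune(model, plan, sessions, config, standardizer, "decode")


def finetune_simulate(model: AlignNet, plan: SplitPlan, sessions,
                      config: TrainConfig, standardizer: Standardizer):
    """Supervised behavior -> spike fine-tuning on the plan's train split."""
    return _finetune(model, plan, sessions, config, standardizer, "simulate")


def predict_decode(model: AlignNet, standardizer: Standardizer,
                   spikes: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Decode behavior from raw spike counts (n, C, T) in evaluation mode."""
    model.eval()
    xs = standardizer.transform(np.asarray(spikes, dtype=np.float64))
    out = [model.decode(model.encode_spike(xs[i:i + batch_size]), "behavior").data
           for i in range(0, len(xs), batch_size)]
    model.train()
    return np.concatenate(out).astype(np.float64)


def predict_simulate(model: AlignNet, behavior: np.ndarray,
                     batch_size: int = 64) -> np.ndarray:
    """Simulate non-negative spike-count predictions from behavior (n, 2, T)."""
    model.eval()
    xb = np.asarray(behavior, dtype=np.float32)
    out = [model.decode(model.encode_behavior(xb[i:i + batch_size]), "spike",
                        nonneg=True).data
           for i in range(0, len(xb), batch_size)]
    model.train()
    return np.concatenate(out).astype(np.float64)
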