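"""Reference decoders/simulators: Wiener filter, MLP, GRU.

Each baseline maps per-trial input sequences (C_in x T) to output sequences
(C_out x T) and is usable in both directions (spike -> behavior decoding and
behavior -> spike simulation).  The Wiener filter is the classical linear
anchor: a ridge-regularized least-squares readout from a causal window of
lagged inputs, solved in closed form by the normal equations, with lags
never leaking across trial boundaries (each trial's history is zero-padded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Adam, Linear, Module, Tensor


# ---- Wiener filter ------------------------------------------------------

@dataclass
class WienerModel:
    lags: int
    weights: np.ndarray          # (lags * C_in + 1, C_out), last row = intercept
    ridge: float

    def __post_init__(self):
        if self.lags < 1:
            raise ValueError("lag count must be >= 1")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite Wiener weights")


def lagged_design(x: np.ndarray, lags: int) -> np.ndarray:
    """Causal lagged design matrix for one trial (C, T) -> (T, lags*C + 1).

    Row t holds [x[:, t-lags+1], ..., x[:, t], 1]; history before the trial
    start is zero-padded, so trials never leak into each other.
    """
    C, T = x.shape
    xp = np.concatenate([np.zeros((C, lags - 1)), x], axis=1)
    cols = [xp[:, lag:lag + T] for lag in range(lags)]       # oldest..newest
    design = np.concatenate(cols, axis=0).T                  # (T, lags*C)
    return np.concatenate([design, np.ones((T, 1))], axis=1)


def wiener_fit(inputs: list[np.ndarray], targets: list[np.ndarray],
               lags: int = 5, ridge: float = 1e-3) -> WienerModel:
    """Closed-form ridge solution of targets[t] ~ W . lagged inputs.

    The intercept is not penalized.  `ridge=0` on a singular system raises
    with advice to set ridge > 0.
    """
    if len(inputs) == 0 or len(inputs) != len(targets):
        raise ValueError("need equal, non-empty input/target trial lists")
    X = np.concatenate([lagged_design(np.asarray(x, dtype=np.float64), lags)
                        for x in inputs])
    Y = np.concatenate([np.asarray(y, dtype=np.float64).T for y in targets])
    gram = X.T @ X
    penalty = ridge * np.eye(gram.shape[0])
    penalty[-1, -1] = 0.0                                    # free intercept
    try:
        w = np.linalg.solve(gram + penalty, X.T @ Y)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular normal equations; use ridge > 0") from err
    if not np.all(np.isfinite(w)):
        raise np.linalg.LinAlgError("singular normal equations; use ridge > 0")
    return WienerModel(lags=lags, weights=w, ridge=ridge)


def wiener_predict(model: WienerModel, inputs: list[np.ndarray]) -> list[np.ndarray]:
    """Per-trial linear readout from the lagged window."""
    out = []
    for x in inputs:
        x = np.asarray(x, dtype=np.float64)
        if model.lags * x.shape[0] + 1 != model.weights.shape[0]:
            raise ValueError("input channel count does not match fitted model")
        out.append((lagged_design(x, model.lags) @ model.weights).T)
    return out


# ---- gradient-trained baselines ----------------------------------------

@dataclass
class BaselineConfig:
    epochs: int = 40
    batch_size: int = 32
    lr: float = 1e-3
    hidden: int = 256            # MLP hidden width (two layers)
    gru_hidden: int = 128
    seed: int = 0


class MLPRegressor(Module):
    """Two-hidden-layer feed-forward net on flattened trials."""

    def __init__(self, n_in: int, n_out: int, hidden: int, rng):
        super().__init__()
        self.fc1 = Linear(n_in, hidden, rng)
        self.fc2 = Linear(hidden, hidden, rng)
        self.fc3 = Linear(hidden, n_out, rng)

    def forward(self, x) -> Tensor:
        return self.fc3(nn.relu(self.fc2(nn.relu(self.fc1(x)))))


class GRURegressor(Module):
    """Single-layer GRU over the trial's time axis with a linear readout."""

    def __init__(self, n_in: int, n_out: int, hidden: int, rng):
        super().__init__()
        self.hidden = hidden
        self.wz = Linear(n_in, hidden, rng)
        self.uz = Linear(hidden, hidden, rng)
        self.wr = Linear(n_in, hidden, rng)
        self.ur = Linear(hidden, hidden, rng)
        self.wn = Linear(n_in, hidden, rng)
        self.un = Linear(hidden, hidden, rng)
        self.out = Linear(hidden, n_out, rng)

    def forward(self, x: np.ndarray) -> Tensor:
        # x: (B, C_in, T) numpy; returns (B, C_out, T)
        B, _, T = x.shape
        h = Tensor(np.zeros((B, self.hidden), dtype=np.float32))
        ys = []
        for t in range(T):
            xt = Tensor(np.ascontiguousarray(x[:, :, t], dtype=np.float32))
            z = nn.sigmoid(self.wz(xt) + self.uz(h))
            r = nn.sigmoid(self.wr(xt) + self.ur(h))
            n_ = nn.tanh(self.wn(xt) + self.un(r * h))
            h = (1.0 - z) * n_ + z * h
            ys.append(self.out(h))
        stacked = nn.concat([nn.reshape(y, (B, -1, 1)) for y in ys], axis=2)
        return stacked


def _train_regressor(model, make_batch_pred, targets: np.ndarray,
                     n: int, config: BaselineConfig):
    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed)
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            pred = make_batch_pred(idx)
            loss = nn.mse(pred, targets[idx])
            if not np.isfinite(loss.item()):
                raise RuntimeError("baseline training diverged")
            opt.zero_grad()
            loss.backward()
            opt.step()


def _standardize(train_x: np.ndarray, test_x: np.ndarray):
    m = train_x.mean(axis=(0, 2), keepdims=True)
    s = np.maximum(train_x.std(axis=(0, 2), keepdims=True), 1e-3)
    return (train_x - m) / s, (test_x - m) / s


def mlp_baseline(train: tuple, test: tuple,
                 config: BaselineConfig = BaselineConfig()) -> dict:
    """Train the MLP on flattened trials; returns test predictions.

    `train`/`test` are (inputs, targets) arrays of shape (n, C, T).
    Deterministic given config.seed.
    """
    (tr_x, tr_y), (te_x, te_y) = train, test
    n, ci, T = tr_x.shape
    co = tr_y.shape[1]
    tr_xs, te_xs = _standardize(np.asarray(tr_x, dtype=np.float64),
                                np.asarray(te_x, dtype=np.float64))
    Xtr = tr_xs.reshape(n, ci * T).astype(np.float32)
    Ytr = np.asarray(tr_y, dtype=np.float32).reshape(n, co * T)
    rng = np.random.default_rng(config.seed)
    model = MLPRegressor(ci * T, co * T, config.hidden, rng)
    _train_regressor(model, lambda idx: model(Xtr[idx]), Ytr, n, config)
    Xte = te_xs.reshape(len(te_x), ci * T).astype(np.float32)
    pred = model(Xte).data.reshape(len(te_x), co, T).astype(np.float64)
    return {"model": model, "predictions": pred, "targets": np.asarray(te_y)}


def gru_baseline(train: tuple, test: tuple,
                 config: BaselineConfig = BaselineConfig()) -> dict:
    """Train the GRU sequence regressor over the time axis."""
    (tr_x, tr_y), (te_x, te_y) = train, test
    n, ci, T = tr_x.shape
    co = tr_y.shape[1]
    tr_xs, te_xs = _standardize(np.asarray(tr_x, dtype=np.float64),
                                np.asarray(te_x, dtype=np.float64))
    Ytr = np.asarray(tr_y, dtype=np.float32)
    rng = np.random.default_rng(config.seed)
    model = GRURegressor(ci, co, config.gru_hidden, rng)
    _train_regressor(model, lambda idx: model(tr_xs[idx]), Ytr, n, config)
    pred = model(te_xs).data.astype(np.float64)
    return {"model": model, "predictions": pred, "targets": np.asarray(te_y)}
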