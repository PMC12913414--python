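"""HDF5 readers/writers, checkpoints, and run configuration.

Session files hold one group per day (``day_000``, ``day_001``, ...) with
datasets ``spikes`` (int16, trials x channels x time) and ``behavior``
(float32, trials x 2 x time), a ``direction`` label vector, and day/seed
attributes.  Raw recordings use the same per-day grouping with ``voltage``
and ``joystick`` datasets carrying their rates as attributes.

Configuration merges defaults < YAML file < command-line overrides; unknown
keys are rejected with a suggestion.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .model import AlignNet, ModelConfig
from .preprocessing import ContinuousRecording, Trial
from .synthetic import SessionSet
from .training import Standardizer


# ---- sessions -----------------------------------------------------------

def write_sessions(path, sessions: list[SessionSet]):
    with h5py.File(path, "w") as f:
        for s in sessions:
            g = f.create_group(f"day_{s.day:03d}")
            g.attrs["day"] = s.day
            if s.seed is not None:
                g.attrs["seed"] = s.seed
            g.create_dataset("spikes", data=s.spikes().astype(np.int16))
            g.create_dataset("behavior", data=s.behavior().astype(np.float32))
            directions = s.directions()
            if not any(d is None for d in directions):
                g.create_dataset("direction", data=directions.astype(np.int16))


def read_sessions(path) -> list[SessionSet]:
    sessions = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            for ds in ("spikes", "behavior"):
                if ds not in g:
                    raise KeyError(f"malformed session file: group {name!r} "
                                   f"is missing dataset {ds!r}")
            day = int(g.attrs.get("day", int(name.split("_")[-1])))
            spikes = g["spikes"][...].astype(np.int64)
            behavior = g["behavior"][...].astype(np.float64)
            directions = g["direction"][...] if "direction" in g else None
            trials = [Trial(spikes=spikes[i], behavior=behavior[i], day=day,
                            direction=None if directions is None else int(directions[i]))
                      for i in range(len(spikes))]
            sessions.append(SessionSet(trials=trials, day=day,
                                       seed=int(g.attrs["seed"]) if "seed" in g.attrs else None))
    return sessions


def write_behavior_csv(path, sessions: list[SessionSet]):
    """Behavior export: one row per time point (day, trial, t, x, y)."""
    import pandas as pd

    rows = []
    for s in sessions:
        for k, tr in enumerate(s.trials):
            for t in range(tr.behavior.shape[1]):
                rows.append((s.day, k, t, tr.behavior[0, t], tr.behavior[1, t]))
    pd.DataFrame(rows, columns=["day", "trial", "t", "x", "y"]).to_csv(
        path, index=False)


# ---- raw recordings -----------------------------------------------------

def write_recordings(path, recordings: dict[int, ContinuousRecording],
                     directions: dict[int, np.ndarray] | None = None):
    with h5py.File(path, "w") as f:
        for day, rec in recordings.items():
            g = f.create_group(f"day_{day:03d}")
            g.attrs["day"] = day
            v = g.create_dataset("voltage", data=rec.voltage.astype(np.float32))
            v.attrs["rate"] = rec.voltage_rate
            j = g.create_dataset("joystick", data=rec.joystick.astype(np.float32))
            j.attrs["rate"] = rec.joystick_rate
            if directions is not None and day in directions:
                g.create_dataset("direction", data=np.asarray(directions[day], dtype=np.int16))


def read_recordings(path):
    out = {}
    dirs = {}
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            for ds in ("voltage", "joystick"):
                if ds not in g:
                    raise KeyError(f"malformed recording file: group {name!r} "
                                   f"is missing dataset {ds!r}")
            day = int(g.attrs.get("day", int(name.split("_")[-1])))
            out[day] = ContinuousRecording(
                voltage=g["voltage"][...].astype(np.float64),
                voltage_rate=float(g["voltage"].attrs["rate"]),
                joystick=g["joystick"][...].astype(np.float64),
                joystick_rate=float(g["joystick"].attrs["rate"]))
            if "direction" in g:
                dirs[day] = g["direction"][...].astype(np.int64)
    return out, dirs


# ---- checkpoints --------------------------------------------------------

def save_checkpoint(path, model: AlignNet, standardizer: Standardizer | None = None):
    """Single-file checkpoint: weights + embedded model config."""
    payload = {f"state/{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    if standardizer is not None:
        payload["standardizer/mean"] = standardizer.mean
        payload["standardizer/std"] = standardizer.std
    np.savez(path, **payload)


def load_checkpoint(path):
    """Returns (model, standardizer-or-None) rebuilt from a checkpoint."""
    with np.load(path) as data:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(data["config_json"]).decode()))
        model = AlignNet(cfg)
        model.load_state_dict({k[len("state/"):]: data[k]
                               for k in data.files if k.startswith("state/")})
        std = None
        if "standardizer/mean" in data.files:
            std = Standardizer(mean=data["standardizer/mean"],
                               std=data["standardizer/std"])
    return model, std


# ---- run configuration --------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulation": {
        "days": 3,
        "trials_per_day": 80,
        "drift_rotation": 0.1,
        "drift_gain_multiplier": 0.95,
        "drift_dropout": 0.02,
        "drift_baseline_jitter": 0.5,
        "noise_sd": 0.02,
    },
    "preprocessing": {
        "threshold": 4.5,
        "refractory_ms": 1.0,
        "intermediate_rate": 500.0,
        "target_rate": 50.0,
        "sigma": 2.0,
    },
    "model": {
        "depth": 3,
        "base_width": 32,
        "latent_dim": 128,
        "temperature": 0.07,
        "lambda_contrastive": 0.5,
    },
    "training": {
        "epochs": 50,
        "batch_size": 32,
        "lr": 1.0e-3,
        "scope": "all",
    },
    "evaluation": {
        "group_size": 8,
    },
}


@dataclass
class RunConfig:
    """Fully merged configuration tree for one command invocation."""

    tree: dict = field(default_factory=lambda: _deep_copy(DEFAULT_CONFIG))

    def __getitem__(self, key):
        return self.tree[key]

    @property
    def seed(self) -> int:
        return int(self.tree["seed"])

    def dump(self, path):
        Path(path).write_text(yaml.safe_dump(self.tree, sort_keys=True))


def _deep_copy(d: dict) -> dict:
    return {k: _deep_copy(v) if isinstance(v, dict) else v for k, v in d.items()}


def _merge(base: dict, override: dict, path: str = ""):
    for key, value in override.items():
        here = f"{path}{key}"
        if key not in base:
            candidates = difflib.get_close_matches(key, base.keys(), n=1)
            hint = f"; did you mean {candidates[0]!r}?" if candidates else ""
            raise KeyError(f"unknown config key {here!r}{hint} "
                           f"(valid keys: {sorted(base.keys())})")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"config key {here!r} expects a mapping")
            _merge(base[key], value, here + ".")
        else:
            if value is not None and base[key] is not None \
                    and isinstance(base[key], (int, float)) != isinstance(value, (int, float)) \
                    and not isinstance(value, type(base[key])):
                raise TypeError(f"config key {here!r} expects "
                                f"{type(base[key]).__name__}, got {type(value).__name__}")
            base[key] = value


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """defaults < YAML file < CLI overrides, with unknown keys rejected."""
    tree = _deep_copy(DEFAULT_CONFIG)
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise TypeError("config file must contain a mapping")
        _merge(tree, loaded)
    if overrides:
        _merge(tree, overrides)
    return RunConfig(tree=tree)
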