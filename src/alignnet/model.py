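"""Hybrid SNN-ANN pair of U-shaped autoencoders with contrastive alignment.

Two structurally identical U-Nets operate on the (time x channel) plane of a
trial.  The spike autoencoder uses Leaky Integrate-and-Fire activations
("LN" stages) after every convolution; the behavior autoencoder uses ReLU.
A per-time-point MLP first projects the 2-D behavior into the 64-channel
space so both modalities enter identical trunks and their feature shapes
match level by level — which is what lets either decoder consume either
encoder's latent and skip maps (spike -> behavior decoding, behavior ->
spike simulation).

The bottleneck embeddings of matched spike/behavior pairs are pulled
together by a symmetric InfoNCE objective

    L = (L_spike + L_behavior) / 2,
    L_spike = -(1/N) sum_i log softmax_j(<z_s^i, z_b^j> / temperature)_i,

with embeddings flattened and L2-normalized before the inner product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import (BatchNorm2d, Conv2d, ConvTranspose2d, Linear, Module,
                 ReLU, Tensor, accumulate, as_tensor, make_op)
from .snn import LIF, LIFParams


@dataclass(frozen=True)
class ModelConfig:
    n_channels: int = 64
    n_time: int = 100
    behavior_dim: int = 2
    depth: int = 3                   # number of downsampling stages k
    base_width: int = 32
    latent_dim: int = 128
    temperature: float = 0.07        # contrastive temperature (not the LIF tau)
    lambda_contrastive: float = 0.5
    lif: LIFParams = field(default_factory=LIFParams)
    normalize_embeddings: bool = True
    proj_hidden: int = 64

    def __post_init__(self):
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_channels % (2 ** self.depth):
            raise ValueError("channel count must be divisible by 2^depth")

    @property
    def padded_time(self) -> int:
        m = 2 ** self.depth
        return ((self.n_time + m - 1) // m) * m

    @property
    def time_pad(self) -> tuple[int, int]:
        extra = self.padded_time - self.n_time
        return extra // 2, extra - extra // 2

    @property
    def latent_time(self) -> int:
        return self.padded_time // (2 ** self.depth)

    @property
    def latent_channels(self) -> int:
        return self.n_channels // (2 ** self.depth)

    @property
    def embed_dim(self) -> int:
        return self.latent_dim * self.latent_time * self.latent_channels

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_channels", "n_time", "behavior_dim", "depth", "base_width",
            "latent_dim", "temperature", "lambda_contrastive",
            "normalize_embeddings", "proj_hidden")}
        d["lif"] = vars(self.lif).copy() if not hasattr(self.lif, "__dataclass_fields__") \
            else {k: getattr(self.lif, k) for k in ("tau", "v_th", "v_reset", "surrogate_width")}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "lif" in d:
            d["lif"] = LIFParams(**d["lif"])
        return cls(**d)


@dataclass
class LatentCode:
    """Bottleneck feature map plus the per-level skip maps needed to decode."""

    h: Tensor                    # (B, D, S', C')
    skips: list                  # level 0 (shallowest) .. depth-1, pre-pool
    modality: str                # "spike" | "behavior"


def _pad_axis(x: Tensor, axis: int, left: int, right: int) -> Tensor:
    if left == 0 and right == 0:
        return x
    pads = [(0, 0)] * x.ndim
    pads[axis] = (left, right)
    out_data = np.pad(x.data, pads)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(left, left + x.shape[axis])
    sl = tuple(sl)

    def bwd(g):
        accumulate(x, g[sl])

    return make_op(out_data, (x,), bwd)


def _identity_avgpool(x: Tensor) -> Tensor:
    """1x1 average pooling with stride 1 — the identity, applied literally."""
    return x


def _make_activation(kind: str, lif: LIFParams) -> Module:
    return LIF(lif) if kind == "lif" else ReLU()


class _Encoder(Module):
    """k downsampling stages of [conv3x3-BN-act, conv3x3-BN-act, maxpool2x2]
    over the (time x channel) plane, then a 1x1-conv bottleneck."""

    def __init__(self, cfg: ModelConfig, activation: str, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        widths = [cfg.base_width * 2 ** i for i in range(cfg.depth)]
        self.blocks = []
        c_in = 1
        for w in widths:
            self.blocks.append([
                Conv2d(c_in, w, 3, rng, pad=1), BatchNorm2d(w),
                _make_activation(activation, cfg.lif),
                Conv2d(w, w, 3, rng, pad=1), BatchNorm2d(w),
                _make_activation(activation, cfg.lif),
            ])
            c_in = w
        self.bottleneck_conv = Conv2d(widths[-1], cfg.latent_dim, 1, rng)
        self.bottleneck_act = _make_activation(activation, cfg.lif)

    def forward(self, x: Tensor):
        skips = []
        for conv1, bn1, act1, conv2, bn2, act2 in self.blocks:
            x = act1(bn1(conv1(x)))
            x = act2(bn2(conv2(x)))
            skips.append(x)
            x = nn.maxpool2d(x)
        x = _identity_avgpool(x)
        h = self.bottleneck_act(self.bottleneck_conv(x))
        return h, skips


class _Decoder(Module):
    """k upsampling stages: transposed conv, skip concatenation, then two
    conv-BN-act blocks; a final 1x1 conv maps back to one plane."""

    def __init__(self, cfg: ModelConfig, activation: str, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        widths = [cfg.base_width * 2 ** i for i in range(cfg.depth)]
        self.stages = []
        c_in = cfg.latent_dim
        for w in reversed(widths):
            self.stages.append([
                ConvTranspose2d(c_in, w, rng),
                Conv2d(2 * w, w, 3, rng, pad=1), BatchNorm2d(w),
                _make_activation(activation, cfg.lif),
                Conv2d(w, w, 3, rng, pad=1), BatchNorm2d(w),
                _make_activation(activation, cfg.lif),
            ])
            c_in = w
        self.head = Conv2d(widths[0], 1, 1, rng)

    def forward(self, h: Tensor, skips: list) -> Tensor:
        x = h
        for stage, skip in zip(self.stages, reversed(skips)):
            up, conv1, bn1, act1, conv2, bn2, act2 = stage
            x = up(x)
            x = nn.concat([x, skip], axis=1)
            x = act1(bn1(conv1(x)))
            x = act2(bn2(conv2(x)))
        return self.head(x)


class AlignNet(Module):
    """The paired autoencoders with cross-modal decode/simulate paths."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        h, C = config.proj_hidden, config.n_channels
        self.proj_fc1 = Linear(config.behavior_dim, h, rng)
        self.proj_fc2 = Linear(h, C, rng)
        self.inv_fc1 = Linear(C, h, rng)
        self.inv_fc2 = Linear(h, config.behavior_dim, rng)
        self.spike_encoder = _Encoder(config, "lif", rng)
        self.behavior_encoder = _Encoder(config, "relu", rng)
        self.spike_decoder = _Decoder(config, "lif", rng)
        self.behavior_decoder = _Decoder(config, "relu", rng)

    # ---- plumbing -------------------------------------------------------
    def _check_batch(self, x, n_rows: int, name: str):
        x = as_tensor(x)
        if x.ndim == 2:
            x = nn.reshape(x, (1,) + x.shape)
        if x.ndim != 3 or x.shape[1] != n_rows or x.shape[2] != self.config.n_time:
            raise ValueError(
                f"{name} must have shape (batch, {n_rows}, {self.config.n_time}), "
                f"got {x.shape}")
        return x

    def _to_image(self, x: Tensor) -> Tensor:
        # (B, rows, S) -> one-plane (B, 1, S_pad, rows) image
        x = nn.transpose(x, (0, 2, 1))
        left, right = self.config.time_pad
        x = _pad_axis(x, 1, left, right)
        return nn.reshape(x, (x.shape[0], 1, x.shape[1], x.shape[2]))

    def _from_image(self, y: Tensor) -> Tensor:
        # (B, 1, S_pad, rows) -> (B, rows, S), cropping the time padding
        left, _ = self.config.time_pad
        y = nn.reshape(y, (y.shape[0], y.shape[2], y.shape[3]))
        y = y[:, left:left + self.config.n_time, :]
        return nn.transpose(y, (0, 2, 1))

    # ---- operations -----------------------------------------------------
    def behavior_project(self, behavior) -> Tensor:
        """Per-time-point MLP lifting (B, 2, S) behavior to (B, C, S)."""
        b = self._check_batch(behavior, self.config.behavior_dim, "behavior")
        B, _, S = b.shape
        flat = nn.reshape(nn.transpose(b, (0, 2, 1)), (B * S, self.config.behavior_dim))
        out = self.proj_fc2(nn.relu(self.proj_fc1(flat)))
        return nn.transpose(nn.reshape(out, (B, S, self.config.n_channels)), (0, 2, 1))

    def _behavior_unproject(self, y: Tensor) -> Tensor:
        B, C, S = y.shape
        flat = nn.reshape(nn.transpose(y, (0, 2, 1)), (B * S, C))
        out = self.inv_fc2(nn.relu(self.inv_fc1(flat)))
        return nn.transpose(nn.reshape(out, (B, S, self.config.behavior_dim)), (0, 2, 1))

    def encode_spike(self, spikes) -> LatentCode:
        x = self._check_batch(spikes, self.config.n_channels, "spikes")
        h, skips = self.spike_encoder(self._to_image(x))
        return LatentCode(h=h, skips=skips, modality="spike")

    def encode_behavior(self, behavior) -> LatentCode:
        proj = self.behavior_project(behavior)
        h, skips = self.behavior_encoder(self._to_image(proj))
        return LatentCode(h=h, skips=skips, modality="behavior")

    def decode(self, latent: LatentCode, target: str, nonneg: bool = False) -> Tensor:
        """Reconstruct the target modality from a latent code (either
        encoder's), using the code's own skip maps."""
        if target not in ("spike", "behavior"):
            raise ValueError(f"unknown target modality {target!r}")
        if len(latent.skips) != self.config.depth:
            raise ValueError("skip list length does not match decoder depth")
        dec = self.spike_decoder if target == "spike" else self.behavior_decoder
        y = self._from_image(dec(latent.h, latent.skips))
        if target == "behavior":
            y = self._behavior_unproject(y)
        if nonneg:
            y = nn.softplus(y)
        return y

    def embed(self, latent: LatentCode) -> Tensor:
        """Flatten the bottleneck map to (B, D*S'*C') for the contrastive term."""
        h = latent.h
        return nn.reshape(h, (h.shape[0], int(np.prod(h.shape[1:]))))


def contrastive_loss(h_spike, h_behavior, temperature: float = 0.07,
                     normalize: bool = True) -> Tensor:
    """Symmetric InfoNCE over a batch of matched embedding pairs.

    Both directions (spike anchors over behavior candidates and vice versa)
    are averaged.  Embeddings are L2-normalized before the inner product by
    default.  N = 1 gives exactly zero; full collapse gives ln N.
    """
    hs, hb = as_tensor(h_spike), as_tensor(h_behavior)
    if hs.ndim != 2 or hb.ndim != 2:
        raise ValueError("embeddings must be 2-D (batch, dim)")
    if hs.shape[0] == 0:
        raise ValueError("empty batch")
    if hs.shape != hb.shape:
        raise ValueError(f"batch mismatch: {hs.shape} vs {hb.shape}")
    if normalize:
        hs = nn.l2_normalize(hs, axis=1)
        hb = nn.l2_normalize(hb, axis=1)
    n = hs.shape[0]
    sim = nn.matmul(hs, nn.transpose(hb)) * (1.0 / temperature)
    eye = np.eye(n, dtype=sim.data.dtype)
    diag = nn.tsum(sim * eye, axis=1)
    loss_spike = nn.tmean(nn.logsumexp(sim, axis=1) - diag)
    loss_behavior = nn.tmean(nn.logsumexp(sim, axis=0) - diag)
    return (loss_spike + loss_behavior) * 0.5


def reconstruction_loss(x, x_hat) -> Tensor:
    """Mean squared error between an input and its reconstruction."""
    return nn.mse(as_tensor(x_hat), as_tensor(x))
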