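"""Leaky Integrate-and-Fire dynamics with a surrogate-gradient pathway.

The LIF neuron used as the activation stage of the spike autoencoder follows
the discrete update

    V_t = H_{t-1} + (1/tau) * (I_t - (H_{t-1} - V_reset))
    S_t = Heaviside(V_t - v_th)
    H_t = V_reset * S_t + V_t * (1 - S_t)

with the current step's input driving the previous step's post-reset
potential.  Defaults: tau = 2, v_th = 0.3, V_reset = 0.

The Heaviside step has zero derivative almost everywhere, so training uses a
surrogate: the backward pass substitutes the derivative of a scaled-arctan
sigmoid, maximal at the threshold and symmetric.  The reset pathway is kept
in the gradient (H_t depends on S_t), so in "smooth" mode — where the spike
is replaced by the arctan sigmoid itself — backpropagation through time is
the exact gradient of the smoothed model, which is how the BPTT code is
gradient-checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np

from .nn import Tensor, accumulate, as_tensor, make_op


@numba.njit(cache=True, fastmath=True)
def _lif_fwd_kernel(x, tau, v_th, v_reset, V, S):  # pragma: no cover - jitted
    N, T = x.shape
    for n in range(N):
        h = v_reset
        for t in range(T):
            v = h + (x[n, t] - (h - v_reset)) / tau
            s = 1.0 if v >= v_th else 0.0
            h = v_reset * s + v * (1.0 - s)
            V[n, t] = v
            S[n, t] = s


@numba.njit(cache=True, fastmath=True)
def _lif_bwd_kernel(gs, V, S, tau, v_th, v_reset, width, gx):  # pragma: no cover
    N, T = V.shape
    decay = 1.0 - 1.0 / tau
    for n in range(N):
        gh = 0.0
        for t in range(T - 1, -1, -1):
            u = np.pi * width * (V[n, t] - v_th) / 2.0
            surr = width / (2.0 * (1.0 + u * u))
            a = gs[n, t] + gh * (v_reset - V[n, t])
            gv = gh * (1.0 - S[n, t]) + a * surr
            gx[n, t] = gv / tau
            gh = gv * decay


@dataclass(frozen=True)
class LIFParams:
    """Membrane parameters; tau is the dimensionless leak time constant."""

    tau: float = 2.0
    v_th: float = 0.3
    v_reset: float = 0.0
    surrogate_width: float = 2.0

    def __post_init__(self):
        if not self.tau > 1:
            raise ValueError(f"tau must exceed 1, got {self.tau}")
        if not self.v_th > self.v_reset:
            raise ValueError("v_th must exceed v_reset")
        if not self.surrogate_width > 0:
            raise ValueError("surrogate width must be positive")


@dataclass
class LIFState:
    """Post-reset membrane potential per unit, plus the step index."""

    h: np.ndarray
    t: int = 0

    @classmethod
    def zeros(cls, shape, params: LIFParams) -> "LIFState":
        return cls(h=np.full(shape, params.v_reset, dtype=np.float64), t=0)


def surrogate_grad(x, width: float = 2.0):
    """Derivative of the scaled-arctan sigmoid: width / (2 (1 + (pi w x / 2)^2)).

    Peaks at x = 0 (the threshold) with value width/2 and decays
    symmetrically; the standard arctan surrogate for spiking networks.
    """
    x = np.asarray(x)
    return width / (2.0 * (1.0 + (np.pi * width * x / 2.0) ** 2))


def smooth_heaviside(x, width: float = 2.0):
    """The arctan sigmoid whose derivative is :func:`surrogate_grad`."""
    x = np.asarray(x, dtype=np.float64)
    return np.arctan(np.pi * width * x / 2.0) / np.pi + 0.5


def heaviside(x):
    x = np.asarray(x)
    dtype = x.dtype if np.issubdtype(x.dtype, np.floating) else np.float64
    return (x >= 0).astype(dtype)


def lif_step(state: LIFState, inputs, params: LIFParams = LIFParams()):
    """One LIF update; returns (new state, binary spikes)."""
    i_t = np.asarray(inputs, dtype=np.float64)
    if not np.all(np.isfinite(i_t)):
        raise ValueError("non-finite LIF input")
    if i_t.shape != state.h.shape:
        raise ValueError(f"input shape {i_t.shape} != state shape {state.h.shape}")
    v = state.h + (i_t - (state.h - params.v_reset)) / params.tau
    s = heaviside(v - params.v_th)
    h = params.v_reset * s + v * (1.0 - s)
    return LIFState(h=h, t=state.t + 1), s


def lif_sequence(inputs, params: LIFParams = LIFParams(), time_axis: int = -1,
                 _smooth: bool = False) -> Tensor:
    """Run LIF dynamics along `time_axis` of a tensor of input currents.

    State starts at V_reset and is private to the call (trials are
    independent).  Differentiable: backward is hand-rolled BPTT using the
    arctan surrogate for dS/dV, including the reset pathway.  With
    `_smooth=True` the spike nonlinearity itself is the arctan sigmoid and
    the backward pass is the exact gradient (used for gradient checking).
    """
    x = as_tensor(inputs)
    axis = time_axis % x.ndim
    xt = np.ascontiguousarray(np.moveaxis(x.data, axis, -1))
    T = xt.shape[-1]
    if T < 1:
        raise ValueError("sequence must have at least one step")
    tau, v_th, v_reset, width = (params.tau, params.v_th,
                                 params.v_reset, params.surrogate_width)
    x2 = xt.reshape(-1, T)
    V = np.empty_like(x2)
    S = np.empty_like(x2)
    if _smooth:
        h = np.full(x2.shape[0], v_reset, dtype=x2.dtype)
        for t in range(T):
            v = h + (x2[:, t] - (h - v_reset)) / tau
            s = smooth_heaviside(v - v_th, width)
            h = v_reset * s + v * (1.0 - s)
            V[:, t] = v
            S[:, t] = s
    else:
        _lif_fwd_kernel(x2, tau, v_th, v_reset, V, S)
    out_data = np.moveaxis(S.reshape(xt.shape), -1, axis)

    def bwd(g):
        gs = np.ascontiguousarray(
            np.moveaxis(np.asarray(g, dtype=V.dtype), axis, -1)).reshape(-1, T)
        gx = np.empty_like(V)
        if _smooth:
            gh = np.zeros(x2.shape[0], dtype=V.dtype)
            decay = 1.0 - 1.0 / tau
            for t in range(T - 1, -1, -1):
                a = gs[:, t] + gh * (v_reset - V[:, t])  # incl. reset pathway
                gv = gh * (1.0 - S[:, t]) + a * surrogate_grad(V[:, t] - v_th, width)
                gx[:, t] = gv / tau
                gh = gv * decay
        else:
            _lif_bwd_kernel(gs, V, S, tau, v_th, v_reset, width, gx)
        accumulate(x, np.moveaxis(gx.reshape(xt.shape), -1, axis))

    return make_op(out_data, (x,), bwd)


from .nn import Module  # noqa: E402  (after Tensor machinery)


class LIF(Module):
    """LIF activation layer over feature maps (B, feat, T, C); the map's
    temporal axis (axis 2) is the LIF time axis, so deeper layers — whose
    maps were pooled — simply run on the shorter axis."""

    def __init__(self, params: LIFParams = LIFParams(), time_axis: int = 2):
        super().__init__()
        self.params = params
        self.time_axis = time_axis

    def forward(self, x) -> Tensor:
        return lif_sequence(x, self.params, time_axis=self.time_axis)
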