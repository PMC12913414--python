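"""Minimal reverse-mode automatic differentiation and neural-network layers.

Everything trainable in this package (the U-shaped autoencoders, the MLP and
GRU baselines) runs on this engine: a :class:`Tensor` wrapping a numpy array
with a gradient slot, a small set of differentiable ops, layer `Module`s and
an Adam optimizer.  Ops keep the dtype of their inputs (float64 inputs give
float64 graphs, used by closed-form tests); parameters are float32.

Only what the models need is implemented: broadcasting elementwise ops,
2-D matmul, reshape/transpose/concat/slicing, reductions, the usual
nonlinearities, 2-D convolution / transposed convolution / max pooling, and
batch normalization.  The convolution inner loops are numba-compiled;
stride-1 convolution backward uses the flipped-kernel identity.  Gradients
accumulate (+=) so shared parameters and reused tensors are handled
correctly.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numba
import numpy as np

PARAM_DTYPE = np.float32


def _coerce(data) -> np.ndarray:
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(PARAM_DTYPE)
    return arr


class Tensor:
    """A numpy array with a grad slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _coerce(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # ---- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # ---- autograd -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be 10^4 nodes deep in BPTT
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, c):
        return power(self, c)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    @property
    def T(self) -> "Tensor":
        return transpose(self)

    def reshape(self, *shape) -> "Tensor":
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def make_op(data: np.ndarray, parents: Sequence[Tensor],
            backward: Callable[[np.ndarray], None]) -> Tensor:
    """Build a graph node. `backward` receives the output grad and must call
    :func:`accumulate` on each parent."""
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def accumulate(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    g = np.asarray(g, dtype=t.data.dtype)
    t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---- elementwise ops ----------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        accumulate(a, _unbroadcast(g, a.shape))
        accumulate(b, _unbroadcast(g, b.shape))

    return make_op(out_data, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def bwd(g):
        accumulate(a, _unbroadcast(g * b.data, a.shape))
        accumulate(b, _unbroadcast(g * a.data, b.shape))

    return make_op(out_data, (a, b), bwd)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def bwd(g):
        accumulate(a, _unbroadcast(g / b.data, a.shape))
        accumulate(b, _unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    return make_op(out_data, (a, b), bwd)


def power(a, c: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** c

    def bwd(g):
        accumulate(a, g * c * a.data ** (c - 1))

    return make_op(out_data, (a,), bwd)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def bwd(g):
        accumulate(a, g * out_data)

    return make_op(out_data, (a,), bwd)


def log(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)

    def bwd(g):
        accumulate(a, g / a.data)

    return make_op(out_data, (a,), bwd)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def bwd(g):
        accumulate(a, g * mask)

    return make_op(out_data, (a,), bwd)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        accumulate(a, g * out_data * (1.0 - out_data))

    return make_op(out_data, (a,), bwd)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def bwd(g):
        accumulate(a, g * (1.0 - out_data ** 2))

    return make_op(out_data, (a,), bwd)


def softplus(a) -> Tensor:
    a = as_tensor(a)
    # numerically stable log(1 + e^x)
    out_data = np.logaddexp(0.0, a.data)

    def bwd(g):
        accumulate(a, g / (1.0 + np.exp(-a.data)))

    return make_op(out_data, (a,), bwd)


# ---- shape ops ----------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def bwd(g):
        accumulate(a, g.reshape(a.shape))

    return make_op(out_data, (a,), bwd)


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.T if axes is None else a.data.transpose(axes)
    inv = None if axes is None else np.argsort(axes)

    def bwd(g):
        accumulate(a, g.T if axes is None else g.transpose(inv))

    return make_op(out_data, (a,), bwd)


def take(a, idx) -> Tensor:
    a = as_tensor(a)
    out_data = a.data[idx]

    def bwd(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        accumulate(a, full)

    return make_op(out_data, (a,), bwd)


def concat(tensors: Sequence, axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            accumulate(t, piece)

    return make_op(out_data, tuple(ts), bwd)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        accumulate(a, np.broadcast_to(g, a.shape))

    return make_op(out_data, (a,), bwd)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.size if axis is None else a.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    out_data = a.data @ b.data

    def bwd(g):
        accumulate(a, g @ b.data.T)
        accumulate(b, a.data.T @ g)

    return make_op(out_data, (a, b), bwd)


def logsumexp(a, axis: int) -> Tensor:
    """Numerically stable log-sum-exp along `axis` (keepdims dropped)."""
    a = as_tensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    shifted = exp(a - m)
    return log(tsum(shifted, axis=axis)) + np.squeeze(m, axis=axis)


def l2_normalize(a, axis: int = 1, eps: float = 1e-12) -> Tensor:
    a = as_tensor(a)
    norm = sqrt(tsum(power(a, 2.0), axis=axis, keepdims=True) + eps)
    return div(a, norm)


def mse(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return tmean(power(a - b, 2.0))


# ---- convolution family -------------------------------------------------

@numba.njit(cache=True)
def _im2col_kernel(xp, kh, kw, stride, Ho, Wo, out):  # pragma: no cover - jitted
    B, C, _, _ = xp.shape
    for b in range(B):
        for i in range(Ho):
            for j in range(Wo):
                row = (b * Ho + i) * Wo + j
                col = 0
                for c in range(C):
                    for di in range(kh):
                        for dj in range(kw):
                            out[row, col] = xp[b, c, i * stride + di, j * stride + dj]
                            col += 1


@numba.njit(cache=True)
def _col2im_kernel(cols, kh, kw, stride, Ho, Wo, xp):  # pragma: no cover - jitted
    B, C, _, _ = xp.shape
    for b in range(B):
        for i in range(Ho):
            for j in range(Wo):
                row = (b * Ho + i) * Wo + j
                col = 0
                for c in range(C):
                    for di in range(kh):
                        for dj in range(kw):
                            xp[b, c, i * stride + di, j * stride + dj] += cols[row, col]
                            col += 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """Patches of x (B,C,H,W) as a GEMM-ready (B*Ho*Wo, C*kh*kw) matrix."""
    B, C, H, W = x.shape
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else \
        np.ascontiguousarray(x)
    out = np.empty((B * Ho * Wo, C * kh * kw), dtype=x.dtype)
    _im2col_kernel(xp, kh, kw, stride, Ho, Wo, out)
    return out


def _col2im(cols: np.ndarray, xshape: tuple, kh: int, kw: int,
            stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back onto the image."""
    B, C, H, W = xshape
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    xp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    _col2im_kernel(np.ascontiguousarray(cols.reshape(B * Ho * Wo, -1)),
                   kh, kw, stride, Ho, Wo, xp)
    return xp[:, :, pad:pad + H, pad:pad + W] if pad else xp


@numba.njit(cache=True, fastmath=True)
def _conv_fwd_kernel(xp, w, y):  # pragma: no cover - jitted
    # xp (B,C,Hp,Wp) pre-padded, w (O,C,kh,kw), y (B,O,H,W) preallocated zeros
    B, C, _, _ = xp.shape
    O, _, kh, kw = w.shape
    H, W = y.shape[2], y.shape[3]
    for bb in range(B):
        for i in range(H):
            for c in range(C):
                for di in range(kh):
                    xrow = xp[bb, c, i + di]
                    for o in range(O):
                        for dj in range(kw):
                            wv = w[o, c, di, dj]
                            yrow = y[bb, o, i]
                            for j in range(W):
                                yrow[j] += wv * xrow[j + dj]


@numba.njit(cache=True, fastmath=True)
def _conv_dw_kernel(xp, g, gw):  # pragma: no cover - jitted
    # gw[o,c,di,dj] += sum_{b,i,j} g[b,o,i,j] * xp[b,c,i+di,j+dj]
    B, C, _, _ = xp.shape
    O, _, kh, kw = gw.shape
    H, W = g.shape[2], g.shape[3]
    for bb in range(B):
        for i in range(H):
            for c in range(C):
                for di in range(kh):
                    xrow = xp[bb, c, i + di]
                    for o in range(O):
                        grow = g[bb, o, i]
                        for dj in range(kw):
                            acc = 0.0
                            for j in range(W):
                                acc += grow[j] * xrow[j + dj]
                            gw[o, c, di, dj] += acc


def _conv_same(xd: np.ndarray, wd: np.ndarray, pad: int) -> np.ndarray:
    """Direct stride-1 convolution via the jitted kernel."""
    B, C, H, W = xd.shape
    O, _, kh, kw = wd.shape
    xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else \
        np.ascontiguousarray(xd)
    y = np.zeros((B, O, H + 2 * pad - kh + 1, W + 2 * pad - kw + 1), dtype=xd.dtype)
    _conv_fwd_kernel(xp, np.ascontiguousarray(wd.astype(xd.dtype, copy=False)), y)
    return y


def conv2d(x, w, b=None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), x (B,Cin,H,W), w (Cout,Cin,kh,kw).

    Stride 1 only (all convolutions in the U-trunks are stride 1; spatial
    reduction is done by pooling).
    """
    if stride != 1:
        raise ValueError("conv2d implements stride 1 only")
    x, w = as_tensor(x), as_tensor(w)
    B, Cin, H, W = x.shape
    Cout, _, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else \
        np.ascontiguousarray(x.data)
    dtype = x.data.dtype
    wd = np.ascontiguousarray(w.data.astype(dtype, copy=False))
    Ho, Wo = H + 2 * pad - kh + 1, W + 2 * pad - kw + 1
    out_data = np.zeros((B, Cout, Ho, Wo), dtype=dtype)
    _conv_fwd_kernel(xp, wd, out_data)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out_data += b.data.astype(dtype, copy=False).reshape(1, Cout, 1, 1)
        parents.append(b)

    def bwd(g):
        g = np.ascontiguousarray(g)
        if b is not None:
            accumulate(b, g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.zeros_like(wd)
            _conv_dw_kernel(xp, g, gw)
            accumulate(w, gw)
        if x.requires_grad:
            # stride-1 adjoint = convolution of g with flipped kernels
            wflip = np.ascontiguousarray(
                wd[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
            accumulate(x, _conv_same(g, wflip, kh - 1 - pad))

    return make_op(out_data, tuple(parents), bwd)


def conv_transpose2d(x, w, b=None, stride: int = 2) -> Tensor:
    """Transposed 2-D convolution, x (B,Cin,H,W), w (Cin,Cout,kh,kw).

    The k = stride case (non-overlapping patches) is a pure reshape scatter.
    """
    x, w = as_tensor(x), as_tensor(w)
    B, Cin, H, W = x.shape
    _, Cout, kh, kw = w.shape
    Ho = (H - 1) * stride + kh
    Wo = (W - 1) * stride + kw
    xt = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)).reshape(B * H * W, Cin)
    w2 = w.data.reshape(Cin, Cout * kh * kw)
    cols = xt @ w2                                        # (B*H*W, Cout*kh*kw)
    out_data = _col2im(cols, (B, Cout, Ho, Wo), kh, kw, stride, 0)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data.reshape(1, Cout, 1, 1)
        parents.append(b)

    def bwd(g):
        if b is not None:
            accumulate(b, g.sum(axis=(0, 2, 3)))
        if not (x.requires_grad or w.requires_grad):
            return
        gcols = _im2col(g, kh, kw, stride, 0)             # (B*H*W, Cout*kh*kw)
        if x.requires_grad:
            gx = (gcols @ w2.T).reshape(B, H, W, Cin).transpose(0, 3, 1, 2)
            accumulate(x, gx)
        if w.requires_grad:
            accumulate(w, (xt.T @ gcols).reshape(w.shape))

    return make_op(out_data, tuple(parents), bwd)


def maxpool2d(x) -> Tensor:
    """2x2 max pooling with stride 2 (even spatial dims required)."""
    x = as_tensor(x)
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2d needs even spatial dims, got {(H, W)}")
    Ho, Wo = H // 2, W // 2
    xr = x.data.reshape(B, C, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(B, C, Ho, Wo, 4)
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        z = np.zeros((B, C, Ho, Wo, 4), dtype=g.dtype)
        np.put_along_axis(z, idx[..., None], g[..., None], axis=-1)
        z = z.reshape(B, C, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        accumulate(x, z.reshape(B, C, H, W))

    return make_op(out_data, (x,), bwd)


# ---- modules ------------------------------------------------------------

def _named_children(obj, prefix: str):
    """Yield (name, Tensor|Module) pairs from attributes, recursing through
    arbitrarily nested lists/tuples."""
    if isinstance(obj, (Tensor, Module)):
        yield prefix, obj
    elif isinstance(obj, (list, tuple)):
        for i, item in enumerate(obj):
            yield from _named_children(item, f"{prefix}.{i}")


class Module:
    """Tiny module system: parameter discovery by attribute walk."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, v in self.__dict__.items():
            yield from _named_children(v, name)

    def modules(self):
        yield self
        for _, child in self._children():
            if isinstance(child, Module):
                yield from child.modules()

    def named_parameters(self, prefix: str = ""):
        for name, child in self._children():
            full = f"{prefix}{name}"
            if isinstance(child, Tensor):
                if child.requires_grad:
                    yield full, child
            else:
                yield from child.named_parameters(full + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, child in self._children():
            if isinstance(child, Module):
                yield from child.named_buffers(f"{prefix}{name}.")
        for name, arr in getattr(self, "_buffers", {}).items():
            yield f"{prefix}{name}", arr

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        d = {f"param:{k}": p.data for k, p in self.named_parameters()}
        d.update({f"buffer:{k}": b for k, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, arr in d.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data = np.asarray(arr, dtype=params[name].data.dtype)
            else:
                buffers[name][...] = arr

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(PARAM_DTYPE)
    return Tensor(w, requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _he(rng, (n_in, n_out), n_in)
        self.bias = Tensor(np.zeros(n_out, dtype=PARAM_DTYPE), requires_grad=True)

    def forward(self, x) -> Tensor:
        return matmul(x, self.weight) + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, pad: int = 0):
        super().__init__()
        self.pad = pad
        self.weight = _he(rng, (c_out, c_in, kernel, kernel), c_in * kernel * kernel)
        self.bias = Tensor(np.zeros(c_out, dtype=PARAM_DTYPE), requires_grad=True)

    def forward(self, x) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=1, pad=self.pad)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 2, stride: int = 2):
        super().__init__()
        self.stride = stride
        self.weight = _he(rng, (c_in, c_out, kernel, kernel), c_in * kernel * kernel)
        self.bias = Tensor(np.zeros(c_out, dtype=PARAM_DTYPE), requires_grad=True)

    def forward(self, x) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    """Per-feature-map normalization; batch statistics while training,
    running statistics in evaluation mode (momentum 0.1)."""

    def __init__(self, n_feat: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(n_feat, dtype=PARAM_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(n_feat, dtype=PARAM_DTYPE), requires_grad=True)
        self._buffers = {
            "running_mean": np.zeros(n_feat, dtype=np.float64),
            "running_var": np.ones(n_feat, dtype=np.float64),
        }

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        gamma, beta, eps = self.gamma, self.beta, self.eps
        if self.training:
            axes = (0, 2, 3)
            m = x.data.mean(axis=axes)
            v = x.data.var(axis=axes)
            n = x.data.size / x.shape[1]
            rb = self._buffers
            rb["running_mean"] += self.momentum * (m - rb["running_mean"])
            unbiased = v * n / max(n - 1, 1)
            rb["running_var"] += self.momentum * (unbiased - rb["running_var"])
            mu = m.reshape(1, -1, 1, 1)
            ivar = 1.0 / np.sqrt(v + eps)
            iv = ivar.reshape(1, -1, 1, 1)
            xhat = (x.data - mu) * iv
            out_data = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

            def bwd(g):
                accumulate(gamma, (g * xhat).sum(axis=axes))
                accumulate(beta, g.sum(axis=axes))
                dxhat = g * gamma.data.reshape(1, -1, 1, 1)
                # standard batchnorm backward, per feature map
                t1 = dxhat - dxhat.mean(axis=axes, keepdims=True)
                t2 = xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
                accumulate(x, iv * (t1 - t2))

            return make_op(out_data, (x, gamma, beta), bwd)
        # eval: affine transform with frozen statistics
        rb = self._buffers
        iv = (1.0 / np.sqrt(rb["running_var"] + eps)).reshape(1, -1, 1, 1)
        mu = rb["running_mean"].reshape(1, -1, 1, 1)
        xhat = (x.data - mu) * iv
        out_data = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

        def bwd_eval(g):
            accumulate(gamma, (g * xhat).sum(axis=(0, 2, 3)))
            accumulate(beta, g.sum(axis=(0, 2, 3)))
            accumulate(x, g * gamma.data.reshape(1, -1, 1, 1) * iv)

        return make_op(out_data, (x, gamma, beta), bwd_eval)


class ReLU(Module):
    def forward(self, x) -> Tensor:
        return relu(x)


class Adam:
    """Adam with bias correction; operates in-place on parameter data."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
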