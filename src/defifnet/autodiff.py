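"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps an ``ndarray`` and
records, for every primitive operation, a closure that propagates the upstream
gradient to the operation's inputs.  Calling :meth:`Tensor.backward` performs a
topological sweep over the recorded graph.  Only the primitives needed by the
segmentation network are provided (elementwise arithmetic, activations,
reductions, channel slicing/permutation, stride-1 "same" convolutions with
groups, 2x2 max pooling and x2 bilinear upsampling).

A module-level MAC counter can be armed with :func:`counting_macs`; while
active, every primitive adds its multiply-accumulate cost to the counter:
``k^2 * C_in/groups * C_out * H_out * W_out`` for convolutions and one
operation per output element for elementwise, pooling and resampling stages.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "conv2d",
    "max_pool2x2",
    "upsample_bilinear2x",
    "global_avg_pool",
    "relu",
    "sigmoid",
    "softmax_channels",
    "log",
    "clip",
    "concat",
    "chunk",
    "permute_channels",
    "counting_macs",
    "mac_count",
]

# ---------------------------------------------------------------------------
# MAC counting machinery
# ---------------------------------------------------------------------------

_MAC_COUNTER: list[int] | None = None


@contextlib.contextmanager
def counting_macs():
    """Context manager arming the global MAC counter.

    Yields a one-element list whose single entry accumulates the cost of every
    primitive executed inside the ``with`` block.
    """
    global _MAC_COUNTER
    prev = _MAC_COUNTER
    _MAC_COUNTER = [0]
    try:
        yield _MAC_COUNTER
    finally:
        _MAC_COUNTER = prev


def mac_count(n: int) -> None:
    if _MAC_COUNTER is not None:
        _MAC_COUNTER[0] += int(n)


# ---------------------------------------------------------------------------
# Tensor
# ---------------------------------------------------------------------------


class Tensor:
    """An ndarray plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- plumbing ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs are deep for big networks
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, as_tensor(np.asarray(-1.0, dtype=self.data.dtype)))

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, as_tensor(other))

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def sum(self):
        return sum_all(self)

    def mean(self):
        return mean_all(self)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._prev = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `g` down to `shape` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Elementwise primitives
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data
    mac_count(out.size)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data
    mac_count(out.size)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    out = a.data / b.data
    mac_count(out.size)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _make(out, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0)
    mac_count(out.size)

    def backward(g):
        x._accumulate(g * (x.data > 0))

    return _make(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    d = x.data
    out = np.where(d >= 0, 1.0 / (1.0 + np.exp(-np.abs(d))),
                   np.exp(-np.abs(d)) / (1.0 + np.exp(-np.abs(d))))
    mac_count(out.size)

    def backward(g):
        x._accumulate(g * out * (1.0 - out))

    return _make(out, (x,), backward)


def log(x: Tensor) -> Tensor:
    out = np.log(x.data)
    mac_count(out.size)

    def backward(g):
        x._accumulate(g / x.data)

    return _make(out, (x,), backward)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    out = np.clip(x.data, lo, hi)
    mac_count(out.size)
    mask = (x.data >= lo) & (x.data <= hi)

    def backward(g):
        x._accumulate(g * mask)

    return _make(out, (x,), backward)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 of a (B, C, H, W) tensor."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=1, keepdims=True)
    mac_count(3 * out.size)

    def backward(g):
        dot = (g * out).sum(axis=1, keepdims=True)
        x._accumulate(out * (g - dot))

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# Reductions
# ---------------------------------------------------------------------------


def sum_all(x: Tensor) -> Tensor:
    out = np.asarray(x.data.sum())
    mac_count(x.data.size)

    def backward(g):
        x._accumulate(np.broadcast_to(g, x.data.shape))

    return _make(out, (x,), backward)


def mean_all(x: Tensor) -> Tensor:
    n = x.data.size
    out = np.asarray(x.data.mean())
    mac_count(n)

    def backward(g):
        x._accumulate(np.broadcast_to(g / n, x.data.shape))

    return _make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Spatial mean of a (B, C, H, W) tensor, keeping singleton H, W axes."""
    B, C, H, W = x.data.shape
    out = x.data.mean(axis=(2, 3), keepdims=True)
    mac_count(x.data.size)

    def backward(g):
        x._accumulate(np.broadcast_to(g / (H * W), x.data.shape))

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# Channel slicing / permutation
# ---------------------------------------------------------------------------


def concat(tensors: Iterable[Tensor]) -> Tensor:
    ts = list(tensors)
    out = np.concatenate([t.data for t in ts], axis=1)
    splits = np.cumsum([t.data.shape[1] for t in ts])[:-1]

    def backward(g):
        for t, piece in zip(ts, np.split(g, splits, axis=1)):
            if t.requires_grad:
                t._accumulate(piece)

    return _make(out, ts, backward)


def chunk(x: Tensor, n: int) -> list[Tensor]:
    """Split along the channel axis into `n` equal parts."""
    C = x.data.shape[1]
    if C % n:
        raise ValueError(f"channel count {C} not divisible into {n} chunks")
    step = C // n
    outs = []
    for i in range(n):
        sl = slice(i * step, (i + 1) * step)
        piece = x.data[:, sl]

        def backward(g, sl=sl):
            full = np.zeros_like(x.data)
            full[:, sl] = g
            x._accumulate(full)

        outs.append(_make(piece, (x,), backward))
    return outs


def permute_channels(x: Tensor, perm: Sequence[int]) -> Tensor:
    perm = np.asarray(perm)
    out = x.data[:, perm]
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))

    def backward(g):
        x._accumulate(g[:, inv])

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# Convolution (stride 1, "same" padding, odd kernel, grouped)
# ---------------------------------------------------------------------------


def _conv2d_raw(x: np.ndarray, w: np.ndarray, groups: int) -> np.ndarray:
    """Correlate x (B,Cin,H,W) with w (Cout,Cin/g,k,k); stride 1, same pad."""
    B, Cin, H, W = x.shape
    Cout, Cin_g, k, _ = w.shape
    pad = k // 2
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = sliding_window_view(x, (k, k), axis=(2, 3))  # (B,Cin,H,W,k,k)
    cols = cols.transpose(0, 1, 4, 5, 2, 3).reshape(B, groups, Cin_g * k * k, H * W)
    wm = w.reshape(groups, Cout // groups, Cin_g * k * k)
    out = np.einsum("gof,bgfp->bgop", wm, np.ascontiguousarray(cols), optimize=True)
    return out.reshape(B, Cout, H, W)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution, stride 1, zero "same" padding, odd kernel."""
    B, Cin, H, W = x.data.shape
    Cout, Cin_g, k, k2 = w.data.shape
    if k != k2 or k % 2 == 0:
        raise ValueError("only odd square kernels are supported")
    if Cin_g * groups != Cin or Cout % groups:
        raise ValueError(
            f"channel/group mismatch: x has {Cin} channels, kernel expects "
            f"{Cin_g}x{groups}, {Cout} outputs over {groups} groups"
        )
    out = _conv2d_raw(x.data, w.data, groups)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1)
    mac_count(k * k * Cin_g * Cout * H * W + (out.size if b is not None else 0))

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g = np.ascontiguousarray(g)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            pad = k // 2
            xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
            cols = sliding_window_view(xp, (k, k), axis=(2, 3))
            cols = cols.transpose(0, 1, 4, 5, 2, 3).reshape(B, groups, Cin_g * k * k, H * W)
            gm = g.reshape(B, groups, Cout // groups, H * W)
            dw = np.einsum("bgop,bgfp->gof", gm, cols, optimize=True)
            w._accumulate(dw.reshape(w.data.shape))
        if x.requires_grad:
            # full correlation of g with the flipped kernel, channels swapped
            wf = w.data[:, :, ::-1, ::-1]
            wf = wf.reshape(groups, Cout // groups, Cin_g, k, k)
            wt = wf.transpose(0, 2, 1, 3, 4).reshape(Cin, Cout // groups, k, k)
            x._accumulate(_conv2d_raw(g, wt, groups))

    return _make(out, parents, backward)


# ---------------------------------------------------------------------------
# Pooling / resampling
# ---------------------------------------------------------------------------


def max_pool2x2(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"spatial size ({H}, {W}) not divisible by 2")
    r = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(B, C, H // 2, W // 2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    mac_count(out.size)

    def backward(g):
        gr = np.zeros((B, C, H // 2, W // 2, 4), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gr.reshape(B, C, H, W))

    return _make(out, (x,), backward)


_BILINEAR_CACHE: dict[tuple[int, int], tuple] = {}


def _bilinear_maps(Hin: int, Win: int):
    """Index/weight maps for x2 bilinear upsampling, corner alignment off."""
    key = (Hin, Win)
    if key not in _BILINEAR_CACHE:
        def axis_maps(n):
            pos = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
            lo = np.clip(np.floor(pos).astype(int), 0, n - 1)
            hi = np.clip(lo + 1, 0, n - 1)
            frac = np.clip(pos - lo, 0.0, 1.0)
            return lo, hi, frac

        _BILINEAR_CACHE[key] = (*axis_maps(Hin), *axis_maps(Win))
    return _BILINEAR_CACHE[key]


def upsample_bilinear2x(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    ylo, yhi, fy, xlo, xhi, fx = _bilinear_maps(H, W)
    fy = fy[:, None]
    fxr = fx[None, :]
    d = x.data
    top = d[:, :, ylo][:, :, :, xlo] * (1 - fxr) + d[:, :, ylo][:, :, :, xhi] * fxr
    bot = d[:, :, yhi][:, :, :, xlo] * (1 - fxr) + d[:, :, yhi][:, :, :, xhi] * fxr
    out = top * (1 - fy) + bot * fy
    mac_count(out.size)

    def backward(g):
        gx = np.zeros_like(x.data)
        w00 = (1 - fy) * (1 - fxr)
        w01 = (1 - fy) * fxr
        w10 = fy * (1 - fxr)
        w11 = fy * fxr
        for wgt, yy, xx in ((w00, ylo, xlo), (w01, ylo, xhi), (w10, yhi, xlo), (w11, yhi, xhi)):
            contrib = g * wgt
            np.add.at(gx, (slice(None), slice(None), yy[:, None], xx[None, :]), contrib)
        x._accumulate(gx)

    return _make(out, (x,), backward)
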