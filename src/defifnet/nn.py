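"""Layer kit built on :mod:`defifnet.autodiff`.

Modules follow the familiar container pattern: each layer owns named
:class:`~defifnet.autodiff.Tensor` parameters, submodules are discovered by
attribute inspection, and ``state_dict``/``load_state_dict`` round-trip all
parameters and buffers through plain numpy arrays.  Weights use fan-in scaled
(Kaiming) initialization from an explicit ``numpy.random.Generator`` so every
network build is reproducible from a seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DTYPE = np.float32


class Module:
    """Base class: parameter/buffer registry + train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    # -- registry ----------------------------------------------------------
    def register_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(value, dtype=DTYPE), requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=DTYPE)
        self._buffers[name] = arr
        return arr

    def children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, t in self._params.items():
            yield prefix + name, t
        for cname, child in self.children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, a in self._buffers.items():
            yield prefix + name, a
        for cname, child in self.children():
            yield from child.named_buffers(prefix + cname + ".")

    def num_parameters(self) -> int:
        return sum(t.data.size for t in self.parameters())

    def zero_grad(self) -> None:
        for t in self.parameters():
            t.grad = None

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self.children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: t.data.copy() for name, t in self.named_parameters()}
        state.update({"buf:" + n: a.copy() for n, a in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buf:"):
                target = buffers[key[4:]]
                target[...] = value
            else:
                t = params[key]
                if t.data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: {t.data.shape} vs {value.shape}"
                    )
                t.data = np.asarray(value, dtype=DTYPE).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """Stride-1 "same" 2-D convolution with optional channel groups."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 groups: int = 1, bias: bool = True):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError(f"groups={groups} must divide channels ({in_ch}->{out_ch})")
        self.in_ch, self.out_ch, self.k, self.groups = in_ch, out_ch, k, groups
        fan_in = (in_ch // groups) * k * k
        self.weight = self.register_param(
            "weight", kaiming(rng, (out_ch, in_ch // groups, k, k), fan_in))
        self.bias = self.register_param("bias", np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, groups=self.groups)


class BatchNorm2d(Module):
    """Batch normalization over (B, H, W) per channel with running stats."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.gamma = self.register_param("gamma", np.ones(ch))
        self.beta = self.register_param("beta", np.zeros(ch))
        self.running_mean = self.register_buffer("running_mean", np.zeros(ch))
        self.running_var = self.register_buffer("running_var", np.ones(ch))

    def forward(self, x: Tensor) -> Tensor:
        data = x.data
        if self.training:
            mean = data.mean(axis=(0, 2, 3))
            var = data.var(axis=(0, 2, 3))
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mean.astype(DTYPE)
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * var.astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        m = mean.reshape(1, -1, 1, 1)
        inv = (1.0 / np.sqrt(var + self.eps)).reshape(1, -1, 1, 1)
        xhat = _normalize(x, m, inv, axes=(0, 2, 3), batch_stats=self.training)
        g = self.gamma
        b = self.beta
        return xhat * _reshape_ch(g, x) + _reshape_ch(b, x)


def _reshape_ch(t: Tensor, like: Tensor) -> Tensor:
    """View a length-C parameter as (1, C, 1, 1) sharing storage and gradient."""
    view = t.data.reshape(1, -1, 1, 1)

    def backward(g):
        t._accumulate(g.sum(axis=(0, 2, 3)))

    out = Tensor(view, requires_grad=t.requires_grad)
    if t.requires_grad:
        out._prev = (t,)
        out._backward = backward
    return out


def _normalize(x: Tensor, mean: np.ndarray, inv_std: np.ndarray,
               axes: tuple[int, ...], batch_stats: bool) -> Tensor:
    """(x - mean) * inv_std with the full Jacobian when stats come from x."""
    xhat = (x.data - mean) * inv_std
    ad.mac_count(2 * xhat.size)

    def backward(g):
        if not batch_stats:
            x._accumulate(g * inv_std)
            return
        gm = g.mean(axis=axes, keepdims=True)
        gxm = (g * xhat).mean(axis=axes, keepdims=True)
        x._accumulate(inv_std * (g - gm - xhat * gxm))

    out = Tensor(xhat, requires_grad=x.requires_grad)
    if x.requires_grad:
        out._prev = (x,)
        out._backward = backward
    return out


class GroupNorm2d(Module):
    """Group normalization (per sample); affine optional."""

    def __init__(self, groups: int, ch: int, eps: float = 1e-5, affine: bool = False):
        super().__init__()
        if ch % groups:
            raise ValueError(f"groups={groups} must divide channels={ch}")
        self.groups, self.ch, self.eps = groups, ch, eps
        self.affine = affine
        if affine:
            self.gamma = self.register_param("gamma", np.ones(ch))
            self.beta = self.register_param("beta", np.zeros(ch))

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.data.shape
        g = self.groups
        d = x.data.reshape(B, g, C // g, H, W)
        mean = d.mean(axis=(2, 3, 4), keepdims=True)
        var = d.var(axis=(2, 3, 4), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((d - mean) * inv).reshape(B, C, H, W)
        ad.mac_count(2 * x.data.size)
        n = (C // g) * H * W

        def backward(grad):
            gr = grad.reshape(B, g, C // g, H, W)
            xh = xhat.reshape(B, g, C // g, H, W)
            gm = gr.mean(axis=(2, 3, 4), keepdims=True)
            gxm = (gr * xh).mean(axis=(2, 3, 4), keepdims=True)
            dx = inv * (gr - gm - xh * gxm)
            x._accumulate(dx.reshape(B, C, H, W))

        out = Tensor(xhat, requires_grad=x.requires_grad)
        if x.requires_grad:
            out._prev = (x,)
            out._backward = backward
        if self.affine:
            out = out * _reshape_ch(self.gamma, out) + _reshape_ch(self.beta, out)
        return out


class ConvBNReLU(Module):
    """conv -> batch norm -> ReLU, the standard encoder/decoder unit."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 groups: int = 1):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, k, rng, groups=groups)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return ad.relu(self.bn(self.conv(x)))


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
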