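"""Neural-network layers on top of the autodiff engine.

Layout convention is NCHW.  Convolutions are implemented by im2col +
matmul; the backward pass w.r.t. the input is itself a correlation with the
spatially flipped kernel, so no scatter-add is needed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor


# ---------------------------------------------------------------------------
# raw conv arithmetic (numpy only)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """(B,C,H,W) -> windows (B, Ho, Wo, C, kh, kw), contiguous copy."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (B,C,Ho',Wo',kh,kw)
    win = win[:, :, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


def _corr2d(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlation; returns (output (B,Cout,Ho,Wo), saved im2col windows)."""
    co, ci, kh, kw = w.shape
    cols = _im2col(x, kh, kw, stride, pad)
    b, ho, wo = cols.shape[:3]
    out = cols.reshape(b * ho * wo, ci * kh * kw) @ w.reshape(co, ci * kh * kw).T
    return out.reshape(b, ho, wo, co).transpose(0, 3, 1, 2), cols


def _dilate(g: np.ndarray, stride: int, out_h: int, out_w: int) -> np.ndarray:
    """Insert stride-1 zeros between gradient pixels (transpose of subsampling)."""
    if stride == 1:
        return g
    b, c, h, w = g.shape
    full = np.zeros((b, c, out_h, out_w), dtype=g.dtype)
    full[:, :, ::stride, ::stride] = g
    return full


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2D cross-correlation, weight layout (Cout, Cin, kh, kw)."""
    co, ci, kh, kw = w.shape
    bsz, cin, h, width = x.shape
    if cin != ci:
        raise ValueError(f"conv2d: input has {cin} channels, weight expects {ci}")
    out_data, cols = _corr2d(x.data, w.data, stride, pad)
    if b is not None:
        out_data = out_data + b.data.reshape(1, co, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        bo, _, ho, wo = g.shape
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gm = g.transpose(0, 2, 3, 1).reshape(bo * ho * wo, co)
            dw = gm.T @ cols.reshape(bo * ho * wo, ci * kh * kw)
            w._accum(dw.reshape(co, ci, kh, kw))
        if x.requires_grad:
            hp, wp = h + 2 * pad, width + 2 * pad
            gfull = _dilate(g, stride, hp - kh + 1, wp - kw + 1)
            wt = np.ascontiguousarray(w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
            dxp, _ = _corr2d(gfull, wt, 1, kh - 1)
            x._accum(dxp[:, :, pad:pad + h, pad:pad + width])

    return Tensor._result(out_data, parents, bw)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """Depthwise conv, weight layout (C, kh, kw); one kernel per channel."""
    c, kh, kw = w.shape
    bsz, cin, h, width = x.shape
    if cin != c:
        raise ValueError(f"depthwise_conv2d: {cin} channels vs {c} kernels")
    cols = _im2col(x.data, kh, kw, stride, pad)  # (B,Ho,Wo,C,kh,kw)
    out_data = np.einsum("bijckl,ckl->bcij", cols, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data.reshape(1, c, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accum(np.einsum("bijckl,bcij->ckl", cols, g, optimize=True))
        if x.requires_grad:
            hp, wp = h + 2 * pad, width + 2 * pad
            gfull = _dilate(g, stride, hp - kh + 1, wp - kw + 1)
            gcols = _im2col(gfull, kh, kw, 1, kh - 1)
            wf = w.data[:, ::-1, ::-1]
            dxp = np.einsum("bijckl,ckl->bcij", gcols, wf, optimize=True)
            x._accum(dxp[:, :, pad:pad + h, pad:pad + width])

    return Tensor._result(out_data, parents, bw)


# ---------------------------------------------------------------------------
# module system
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container with parameter discovery and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self):
        for m in self.modules():
            object.__setattr__(m, "training", True)
        return self

    def eval(self):
        for m in self.modules():
            object.__setattr__(m, "training", False)
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters() if p.requires_grad)

    def state_dict(self) -> dict:
        return {n: p.data.copy() for n, p in self.named_parameters()} | {
            f"__buffer__.{i}.{n}": b.copy()
            for i, m in enumerate(self.modules())
            for n, b in getattr(m, "_buffers", {}).items()
        }

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for n, v in state.items():
            if n.startswith("__buffer__."):
                _, idx, bn = n.split(".", 2)
                list(self.modules())[int(idx)]._buffers[bn][...] = v
            else:
                params[n].data[...] = v

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(ModuleList):
    def forward(self, x):
        for m in self:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y if self.bias is None else y + self.bias


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, bias: bool = True):
        super().__init__()
        if pad is None:
            pad = kernel // 2
        self.stride, self.pad = stride, pad
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, kernel, kernel), in_ch * kernel * kernel))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, bias: bool = True):
        super().__init__()
        if pad is None:
            pad = kernel // 2
        self.stride, self.pad = stride, pad
        self.weight = Parameter(_kaiming(rng, (channels, kernel, kernel), kernel * kernel))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm2d(Module):
    """Standard batch norm: batch statistics in training, running in eval."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self._buffers = {
            "running_mean": np.zeros(channels, dtype=np.float32),
            "running_var": np.ones(channels, dtype=np.float32),
        }

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.reshape(c)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.reshape(c)
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, c, 1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, c, 1, 1))
        xn = (x - mu) / (var + self.eps).sqrt()
        return xn * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class LayerNorm(Module):
    """Layer norm over the channel axis of an NCHW map (per-position)."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        mu = x.mean(axis=1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=1, keepdims=True)
        xn = (x - mu) / (var + self.eps).sqrt()
        return xn * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class SiLU(Module):
    def forward(self, x):
        return x.silu()
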