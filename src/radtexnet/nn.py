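"""Minimal dense/convolutional/attention layers with explicit backprop.

The volumetric classifier in this package is small enough at desk scale that
a self-contained numpy implementation is the most transparent choice: every
layer is a :class:`Module` with ``forward(x, train)`` and ``backward(dy)``,
parameters are mutable :class:`Param` holders updated in place by
:class:`AdamW`, and all randomness flows through an explicit
``numpy.random.Generator`` so runs are bit-reproducible.

Shapes follow the channels-first convention ``(B, C, D, H, W)`` for volumes
and ``(B, T, dim)`` for token sequences.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

# im2col buffers larger than this many elements are processed in depth chunks
_CHUNK_ELEMENTS = 32_000_000


class Param:
    """A learnable array with its gradient and a weight-decay flag."""

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool = True, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay
        self.name = name


class Module:
    def parameters(self) -> List[Param]:
        params: List[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x, train: bool = False):
        return self.forward(x, train=train)


# ---------------------------------------------------------------------------
# basic layers


class Linear(Module):
    """Affine map on the last axis; inputs may carry leading batch axes."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float64, bias: bool = True, name: str = "linear"):
        std = np.sqrt(2.0 / n_in)
        self.W = Param((rng.standard_normal((n_out, n_in)) * std).astype(dtype), name=f"{name}.W")
        self.b = Param(np.zeros(n_out, dtype=dtype), decay=False, name=f"{name}.b") if bias else None
        self._x = None

    def forward(self, x, train: bool = False):
        self._x = x
        y = x @ self.W.value.T
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy):
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += dy2.T @ x2
        if self.b is not None:
            self.b.grad += dy2.sum(axis=0)
        return (dy2 @ self.W.value).reshape(x.shape)


class ReLU(Module):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class GELU(Module):
    """Exact Gaussian-error-linear unit."""

    def forward(self, x, train: bool = False):
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        return x * self._cdf

    def backward(self, dy):
        x = self._x
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        return dy * (self._cdf + x * pdf)


class LayerNorm(Module):
    def __init__(self, dim: int, dtype=np.float64, eps: float = 1e-5, name: str = "ln"):
        self.g = Param(np.ones(dim, dtype=dtype), decay=False, name=f"{name}.g")
        self.b = Param(np.zeros(dim, dtype=dtype), decay=False, name=f"{name}.b")
        self.eps = eps

    def forward(self, x, train: bool = False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.g.value * self._xhat + self.b.value

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        self.g.grad += np.sum(dy * xhat, axis=tuple(range(dy.ndim - 1)))
        self.b.grad += np.sum(dy, axis=tuple(range(dy.ndim - 1)))
        dxhat = dy * self.g.value
        n = xhat.shape[-1]
        return (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        ) * inv


class Conv3d(Module):
    """3D convolution via im2col; large forward passes are depth-chunked."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator, dtype=np.float64,
                 bias: bool = True, name: str = "conv"):
        fan_in = c_in * kernel**3
        std = np.sqrt(2.0 / fan_in)
        self.W = Param((rng.standard_normal((c_out, c_in, kernel, kernel, kernel)) * std).astype(dtype),
                       name=f"{name}.W")
        self.b = Param(np.zeros(c_out, dtype=dtype), decay=False, name=f"{name}.b") if bias else None
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out
        self._cache = None

    def out_shape(self, spatial: Sequence[int]) -> Tuple[int, int, int]:
        k, s, p = self.kernel, self.stride, self.padding
        return tuple((d + 2 * p - k) // s + 1 for d in spatial)

    def forward(self, x, train: bool = False):
        B, C, D, H, Wd = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {C}")
        k, s, p = self.kernel, self.stride, self.padding
        Do, Ho, Wo = self.out_shape((D, H, Wd))
        if min(Do, Ho, Wo) < 1:
            raise ValueError(f"input spatial {x.shape[2:]} too small for kernel {k}")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        Wm = self.W.value.reshape(self.c_out, -1)

        n_cols = B * Do * Ho * Wo * C * k**3
        if train or n_cols <= _CHUNK_ELEMENTS:
            cols = self._im2col(xp, Do, Ho, Wo)
            y = cols @ Wm.T
            # cache in eval mode too: explanation maps backprop through a
            # frozen model (the chunked large-input path stays forward-only)
            self._cache = (cols, x.shape, xp.shape)
        else:
            y = np.empty((B * Do * Ho * Wo, self.c_out), dtype=x.dtype)
            chunk = max(1, _CHUNK_ELEMENTS // max(1, B * Ho * Wo * C * k**3))
            for d0 in range(0, Do, chunk):
                d1 = min(Do, d0 + chunk)
                sub = xp[:, :, d0 * s : (d1 - 1) * s + k]
                cols = self._im2col(sub, d1 - d0, Ho, Wo)
                yc = cols @ Wm.T
                y3 = y.reshape(B, Do, Ho, Wo, self.c_out)
                y3[:, d0:d1] = yc.reshape(B, d1 - d0, Ho, Wo, self.c_out)
            self._cache = None
        if self.b is not None:
            y = y + self.b.value
        y = y.reshape(B, Do, Ho, Wo, self.c_out).transpose(0, 4, 1, 2, 3)
        self._out_spatial = (Do, Ho, Wo)
        return np.ascontiguousarray(y)

    def _im2col(self, xp, Do, Ho, Wo):
        k, s = self.kernel, self.stride
        view = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        view = view[:, :, ::s, ::s, ::s][:, :, :Do, :Ho, :Wo]
        cols = view.transpose(0, 2, 3, 4, 1, 5, 6, 7)
        B = xp.shape[0]
        return cols.reshape(B * Do * Ho * Wo, self.c_in * k**3)

    def backward(self, dy):
        if self._cache is None:
            raise RuntimeError("backward requires a forward pass with train=True")
        cols, x_shape, xp_shape = self._cache
        B, C, D, H, Wd = x_shape
        k, s, p = self.kernel, self.stride, self.padding
        Do, Ho, Wo = self._out_spatial
        dy2 = dy.transpose(0, 2, 3, 4, 1).reshape(-1, self.c_out)
        self.W.grad += (dy2.T @ cols).reshape(self.W.value.shape)
        if self.b is not None:
            self.b.grad += dy2.sum(axis=0)
        dcols = dy2 @ self.W.value.reshape(self.c_out, -1)
        dcols = dcols.reshape(B, Do, Ho, Wo, C, k, k, k)
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    dxp[:, :, a : a + s * Do : s, b : b + s * Ho : s, c : c + s * Wo : s] += (
                        dcols[..., a, b, c].transpose(0, 4, 1, 2, 3)
                    )
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class BatchNorm3d(Module):
    def __init__(self, c: int, dtype=np.float64, eps: float = 1e-5,
                 momentum: float = 0.1, name: str = "bn"):
        self.g = Param(np.ones(c, dtype=dtype), decay=False, name=f"{name}.g")
        self.b = Param(np.zeros(c, dtype=dtype), decay=False, name=f"{name}.b")
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.eps, self.momentum = eps, momentum

    def forward(self, x, train: bool = False):
        axes = (0, 2, 3, 4)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        shape = (1, -1, 1, 1, 1)
        xhat = (x - mu.reshape(shape)) * inv.reshape(shape)
        self._cache = (xhat, inv, train, x.shape)
        return self.g.value.reshape(shape) * xhat + self.b.value.reshape(shape)

    def backward(self, dy):
        xhat, inv, was_train, x_shape = self._cache
        shape = (1, -1, 1, 1, 1)
        axes = (0, 2, 3, 4)
        self.g.grad += np.sum(dy * xhat, axis=axes)
        self.b.grad += np.sum(dy, axis=axes)
        dxhat = dy * self.g.value.reshape(shape)
        if not was_train:
            return dxhat * inv.reshape(shape)
        n = x_shape[0] * x_shape[2] * x_shape[3] * x_shape[4]
        mean_dxhat = dxhat.mean(axis=axes).reshape(shape)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes).reshape(shape)
        return (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) * inv.reshape(shape)


class GlobalAvgPool3d(Module):
    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy):
        B, C, D, H, W = self._shape
        return np.broadcast_to(
            dy.reshape(B, C, 1, 1, 1) / (D * H * W), self._shape
        ).copy()


class Sequential(Module):
    def __init__(self, modules: Sequence[Module]):
        self.modules_list = list(modules)

    def forward(self, x, train: bool = False):
        for m in self.modules_list:
            x = m.forward(x, train=train)
        return x

    def forward_recorded(self, x, train: bool = False):
        """Forward pass returning the output of every submodule."""
        outs = []
        for m in self.modules_list:
            x = m.forward(x, train=train)
            outs.append(x)
        return x, outs

    def backward(self, dy):
        for m in reversed(self.modules_list):
            dy = m.backward(dy)
        return dy

    def backward_recorded(self, dy):
        """Backward pass returning the gradient flowing *out of* each submodule."""
        grads = [None] * len(self.modules_list)
        for i in reversed(range(len(self.modules_list))):
            grads[i] = dy  # gradient w.r.t. the output of module i
            dy = self.modules_list[i].backward(dy)
        return dy, grads


# ---------------------------------------------------------------------------
# attention


def softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiheadSelfAttention(Module):
    """Standard scaled dot-product self-attention; retains attention maps."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 dtype=np.float64, name: str = "attn"):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.dh = dim, heads, dim // heads
        self.qkv = Linear(dim, 3 * dim, rng, dtype=dtype, name=f"{name}.qkv")
        self.proj = Linear(dim, dim, rng, dtype=dtype, name=f"{name}.proj")
        self.last_attention: Optional[np.ndarray] = None  # (B, h, T, T)

    def forward(self, x, train: bool = False):
        B, T, D = x.shape
        qkv = self.qkv.forward(x, train=train).reshape(B, T, 3, self.heads, self.dh)
        q, k, v = (qkv[:, :, i].transpose(0, 2, 1, 3) for i in range(3))  # (B,h,T,dh)
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.dh)
        att = softmax(scores, axis=-1)
        y = att @ v  # (B,h,T,dh)
        out = y.transpose(0, 2, 1, 3).reshape(B, T, D)
        self._cache = (q, k, v, att)
        self.last_attention = att
        return self.proj.forward(out, train=train)

    def backward(self, dy):
        q, k, v, att = self._cache
        B, h, T, dh = q.shape
        dout = self.proj.backward(dy)
        dy_h = dout.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
        datt = dy_h @ v.transpose(0, 1, 3, 2)
        dv = att.transpose(0, 1, 3, 2) @ dy_h
        dscores = att * (datt - np.sum(datt * att, axis=-1, keepdims=True))
        dscores /= np.sqrt(dh)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dqkv = np.stack(
            [g.transpose(0, 2, 1, 3) for g in (dq, dk, dv)], axis=2
        ).reshape(B, T, 3 * h * dh)
        return self.qkv.backward(dqkv)


class TransformerBlock(Module):
    """Pre-norm block: x + MHSA(LN(x)), then + MLP(LN(.))."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 mlp_ratio: int = 4, dtype=np.float64, name: str = "blk"):
        self.ln1 = LayerNorm(dim, dtype=dtype, name=f"{name}.ln1")
        self.attn = MultiheadSelfAttention(dim, heads, rng, dtype=dtype, name=f"{name}.attn")
        self.ln2 = LayerNorm(dim, dtype=dtype, name=f"{name}.ln2")
        self.mlp = Sequential([
            Linear(dim, mlp_ratio * dim, rng, dtype=dtype, name=f"{name}.fc1"),
            GELU(),
            Linear(mlp_ratio * dim, dim, rng, dtype=dtype, name=f"{name}.fc2"),
        ])

    def forward(self, x, train: bool = False):
        u = x + self.attn.forward(self.ln1.forward(x, train=train), train=train)
        return u + self.mlp.forward(self.ln2.forward(u, train=train), train=train)

    def backward(self, dy):
        du = dy + self.ln2.backward(self.mlp.backward(dy))
        return du + self.ln1.backward(self.attn.backward(du))


# ---------------------------------------------------------------------------
# losses and optimization


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def bce_loss(logits: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits; returns (loss, dlogits)."""
    p = sigmoid(logits)
    eps = 1e-12
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    dlogits = (p - y) / logits.shape[0]
    return float(loss), dlogits


class AdamW(Module):
    """Decoupled-weight-decay Adam; decay applies only to Params flagged decay."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-5,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            update = mhat / (np.sqrt(vhat) + self.eps)
            if p.decay and self.weight_decay:
                update = update + self.weight_decay * p.value
            p.value -= self.lr * update
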