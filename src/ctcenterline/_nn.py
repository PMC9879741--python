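"""Minimal convolutional-network layers with manual backpropagation.

Everything is float32 numpy, deterministic for a fixed seed, and sized for
desk-scale training (batch size 1, images of a few thousand pixels).  The
layer set is exactly what the localizer-to-volume encoder--decoder needs:
stride-2 3x3 convolutions, batch normalization, ReLU, nearest-neighbour
upsampling, channel concatenation, and an Adam optimizer.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

_F32 = np.float32


# ---------------------------------------------------------------------------
# im2col machinery (indices cached per geometry)

_IDX_CACHE: Dict[Tuple, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _im2col_indices(C: int, H: int, W: int, k: int, stride: int, pad: int):
    key = (C, H, W, k, stride, pad)
    if key in _IDX_CACHE:
        return _IDX_CACHE[key]
    out_h = (H + 2 * pad - k) // stride + 1
    out_w = (W + 2 * pad - k) // stride + 1
    i0 = np.repeat(np.arange(k), k)
    i0 = np.tile(i0, C)
    i1 = stride * np.repeat(np.arange(out_h), out_w)
    j0 = np.tile(np.arange(k), k * C)
    j1 = stride * np.tile(np.arange(out_w), out_h)
    i = i0.reshape(-1, 1) + i1.reshape(1, -1)
    j = j0.reshape(-1, 1) + j1.reshape(1, -1)
    ch = np.repeat(np.arange(C), k * k).reshape(-1, 1)
    _IDX_CACHE[key] = (ch, i, j)
    return _IDX_CACHE[key]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    ch, i, j = _im2col_indices(C, H, W, k, stride, pad)
    return xp[:, ch, i, j]  # (N, C*k*k, L)


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    N, C, H, W = x_shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    ch, i, j = _im2col_indices(C, H, W, k, stride, pad)
    flat = (ch * Hp * Wp + i * Wp + j).ravel()
    out = np.zeros((N, C * Hp * Wp), dtype=np.float64)
    for n in range(N):
        out[n] = np.bincount(flat, weights=cols[n].ravel(),
                             minlength=C * Hp * Wp)
    out = out.reshape(N, C, Hp, Wp).astype(_F32)
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


# ---------------------------------------------------------------------------
# Layers


class Layer:
    """Base: forward caches what backward needs; params/grads by name."""

    #: per-layer learning-rate multiplier (parameter-group style)
    lr_scale: float = 1.0

    def params(self) -> Dict[str, np.ndarray]:
        return {}

    def grads(self) -> Dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 rng: Optional[np.random.Generator] = None):
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = k // 2
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        self.W = (rng.standard_normal((out_ch, fan_in))
                  * np.sqrt(2.0 / fan_in)).astype(_F32)
        self.b = np.zeros(out_ch, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training):
        self._x_shape = x.shape
        cols = _im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        N = x.shape[0]
        out_h = (x.shape[2] + 2 * self.pad - self.k) // self.stride + 1
        out_w = (x.shape[3] + 2 * self.pad - self.k) // self.stride + 1
        out = np.einsum("of,nfl->nol", self.W, cols, optimize=True)
        out += self.b[None, :, None]
        return out.reshape(N, self.out_ch, out_h, out_w)

    def backward(self, dout):
        N = dout.shape[0]
        dflat = dout.reshape(N, self.out_ch, -1)
        self.dW[...] = np.einsum("nol,nfl->of", dflat, self._cols,
                                 optimize=True)
        self.db[...] = dflat.sum(axis=(0, 2))
        dcols = np.einsum("of,nol->nfl", self.W, dflat, optimize=True)
        return _col2im(dcols, self._x_shape, self.k, self.stride, self.pad)


class BatchNorm2d(Layer):
    """Normalizes each channel over (N, H, W); with batch size 1 this acts on
    the spatial extent alone, which is well defined for these image sizes."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(ch, dtype=_F32)
        self.beta = np.zeros(ch, dtype=_F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=_F32)
        self.running_var = np.ones(ch, dtype=_F32)
        self.eps, self.momentum = eps, momentum

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def forward(self, x, training):
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(_F32)
        self._xhat = (x - mean[None, :, None, None]) * self._inv_std[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        axes = (0, 2, 3)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma[...] = (dout * self._xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        g = self.gamma[None, :, None, None] * self._inv_std[None, :, None, None]
        dxhat = dout
        dx = g * (dxhat
                  - dxhat.mean(axis=axes, keepdims=True)
                  - self._xhat * (dxhat * self._xhat).mean(axis=axes, keepdims=True))
        return dx.astype(_F32)


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    """Leaky rectifier; used where unit death would sever a gradient path."""

    def __init__(self, alpha: float = 0.1):
        self.alpha = float(alpha)

    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout).astype(_F32)


class UpsampleNearest2(Layer):
    def forward(self, x, training):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout):
        N, C, H, W = dout.shape
        return dout.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class GlobalContext(Layer):
    """Squeeze-and-excite style global pathway: global-average-pooled channel
    statistics pass through a small MLP and are added back as per-channel
    biases.  Gives every spatial location immediate access to image-global
    cues (e.g. the apparent width of structures, which encodes geometric
    magnification) without waiting for receptive fields to grow."""

    def __init__(self, ch: int, rng: Optional[np.random.Generator] = None,
                 lr_scale: float = 1.0):
        rng = rng or np.random.default_rng(0)
        self.lr_scale = float(lr_scale)
        self.W1 = (rng.standard_normal((ch, ch)) * np.sqrt(2.0 / ch)).astype(_F32)
        self.b1 = np.zeros(ch, dtype=_F32)
        self.W2 = np.zeros((ch, ch), dtype=_F32)  # start as identity mapping
        self.b2 = np.zeros(ch, dtype=_F32)
        self.dW1 = np.zeros_like(self.W1)
        self.db1 = np.zeros_like(self.b1)
        self.dW2 = np.zeros_like(self.W2)
        self.db2 = np.zeros_like(self.b2)

    def params(self):
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}

    def grads(self):
        return {"W1": self.dW1, "b1": self.db1, "W2": self.dW2, "b2": self.db2}

    def forward(self, x, training):
        self._x_shape = x.shape
        self._g = x.mean(axis=(2, 3))                    # (N, C)
        self._h1 = self._g @ self.W1.T + self.b1
        self._a1 = np.maximum(self._h1, 0.0)
        bias = self._a1 @ self.W2.T + self.b2            # (N, C)
        return x + bias[:, :, None, None]

    def backward(self, dout):
        N, C, H, W = self._x_shape
        dbias = dout.sum(axis=(2, 3))                    # (N, C)
        self.dW2[...] = dbias.T @ self._a1
        self.db2[...] = dbias.sum(axis=0)
        da1 = (dbias @ self.W2) * (self._h1 > 0)
        self.dW1[...] = da1.T @ self._g
        self.db1[...] = da1.sum(axis=0)
        dg = da1 @ self.W1                               # (N, C)
        return dout + dg[:, :, None, None] / np.float32(H * W)


class ShiftMLP(Layer):
    """Two-layer perceptron mapping pooled channel statistics to a scalar
    (used as a global AP shift, in output-bin units).  Zero-initialized so it
    starts as "no shift"."""

    def __init__(self, ch: int, hidden: int = 16,
                 rng: Optional[np.random.Generator] = None,
                 lr_scale: float = 1.0):
        rng = rng or np.random.default_rng(0)
        self.lr_scale = float(lr_scale)
        self.W1 = (rng.standard_normal((hidden, ch)) * np.sqrt(2.0 / ch)).astype(_F32)
        self.b1 = np.zeros(hidden, dtype=_F32)
        self.W2 = np.zeros((1, hidden), dtype=_F32)
        self.b2 = np.zeros(1, dtype=_F32)
        self.dW1 = np.zeros_like(self.W1)
        self.db1 = np.zeros_like(self.b1)
        self.dW2 = np.zeros_like(self.W2)
        self.db2 = np.zeros_like(self.b2)

    def params(self):
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}

    def grads(self):
        return {"W1": self.dW1, "b1": self.db1, "W2": self.dW2, "b2": self.db2}

    def forward(self, g, training):
        self._g = g
        self._h1 = g @ self.W1.T + self.b1
        self._a1 = np.maximum(self._h1, 0.0)
        return (self._a1 @ self.W2.T + self.b2)[:, 0]  # (N,)

    def backward(self, ds):
        ds = ds[:, None]  # (N, 1)
        self.dW2[...] = ds.T @ self._a1
        self.db2[...] = ds.sum(axis=0)
        da1 = (ds @ self.W2) * (self._h1 > 0)
        self.dW1[...] = da1.T @ self._g
        self.db1[...] = da1.sum(axis=0)
        return da1 @ self.W1  # (N, C)


def warp_channels(v: np.ndarray, s: np.ndarray):
    """Translate along the channel axis by a per-sample fractional shift
    (linear interpolation, edge replication).  Returns the warped array and a
    cache for :func:`warp_channels_backward`."""
    N, B = v.shape[0], v.shape[1]
    c = np.arange(B)
    out = np.empty_like(v)
    cache = []
    for n in range(N):
        src = c - s[n]
        c0 = np.floor(src).astype(int)
        f = (src - c0).astype(_F32)
        c0c = np.clip(c0, 0, B - 1)
        c1c = np.clip(c0 + 1, 0, B - 1)
        v0, v1 = v[n, c0c], v[n, c1c]
        out[n] = (1.0 - f)[:, None, None] * v0 + f[:, None, None] * v1
        cache.append((c0c, c1c, f, v0, v1))
    return out, cache


def warp_channels_backward(dout: np.ndarray, v_shape, cache):
    """Gradients of the channel warp w.r.t. the input volume and the shift."""
    N, B = v_shape[0], v_shape[1]
    dv = np.zeros(v_shape, dtype=_F32)
    ds = np.zeros(N, dtype=_F32)
    for n in range(N):
        c0c, c1c, f, v0, v1 = cache[n]
        w0 = (1.0 - f)[:, None, None] * dout[n]
        w1 = f[:, None, None] * dout[n]
        np.add.at(dv[n], c0c, w0)
        np.add.at(dv[n], c1c, w1)
        ds[n] = -np.sum(dout[n] * (v1 - v0))
    return dv, ds


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout

    def iter_layers(self):
        for l in self.layers:
            if isinstance(l, Sequential):
                yield from l.iter_layers()
            else:
                yield l


class Adam:
    def __init__(self, layers: List[Layer], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.99), eps: float = 1e-8):
        self.entries = []
        for layer in layers:
            p, g = layer.params(), layer.grads()
            scale = getattr(layer, "lr_scale", 1.0)
            for name in p:
                self.entries.append((p[name], g[name],
                                     np.zeros_like(p[name]),
                                     np.zeros_like(p[name]), scale))
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v, scale in self.entries:
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= (self.lr * scale) * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(_F32)


def l1_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    loss = float(np.mean(np.abs(diff)))
    grad = np.sign(diff) / diff.size
    return loss, grad.astype(_F32)
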