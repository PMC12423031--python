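"""Minimal numpy neural-network layers with explicit backpropagation.

Design notes
------------
* Every layer caches what its backward pass needs during ``forward`` and
  accumulates parameter gradients into ``grads`` during ``backward``.
* Convolutions act along the last (time) axis of ``(batch, channels, time)``
  arrays and are evaluated in the frequency domain (rfft product), which is
  exact for linear correlation once the FFT length covers the padded signal.
* float32 is the working precision for speed; float64 is supported so
  finite-difference gradient checks can run at tight tolerances.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft
from scipy.special import erf

__all__ = [
    "Layer",
    "DepthwiseConv1d",
    "ChannelLinear",
    "BatchNormChannel",
    "ELU",
    "GELU",
    "Dropout",
    "AvgPoolTime",
    "GlobalAvgPoolTime",
    "Dense",
    "LayerNorm",
    "softmax",
    "softmax_cross_entropy",
]


class Layer:
    """Base class: parameter/gradient dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def add_param(self, name: str, value: np.ndarray) -> None:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class DepthwiseConv1d(Layer):
    """Per-channel time convolution, kernel shape (channels, k), zero padding.

    Output length is ``T + 2*pad - k + 1``; each channel is correlated with
    its own kernel (groups == channels), so channels never mix here.
    """

    def __init__(self, channels: int, kernel: int, pad: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.kernel, self.pad = kernel, pad
        scale = np.sqrt(2.0 / kernel)
        self.add_param("w", (rng.standard_normal((channels, kernel)) * scale).astype(dtype))
        self.add_param("b", np.zeros(channels, dtype=dtype))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, c, t = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        L = t + 2 * self.pad
        nfft = sfft.next_fast_len(L, real=True)
        xp_hat = sfft.rfft(xp, n=nfft, axis=-1)
        w_hat = sfft.rfft(self.params["w"], n=nfft, axis=-1)
        if training:
            self._xp_hat, self._w_hat = xp_hat, w_hat
            self._nfft, self._t = nfft, t
        y = sfft.irfft(xp_hat * np.conj(w_hat), n=nfft, axis=-1)
        t_out = L - self.kernel + 1
        y = y[..., :t_out]
        y += self.params["b"][None, :, None]
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        nfft = self._nfft
        w = self.params["w"]
        gy_hat = sfft.rfft(gy, n=nfft, axis=-1)
        # input gradient: convolution of gy with the kernel
        gx_pad = sfft.irfft(gy_hat * self._w_hat, n=nfft, axis=-1)
        gx = gx_pad[..., self.pad:self.pad + self._t]
        # kernel gradient: correlation of the padded input with gy
        prod = np.einsum("bcf,bcf->cf", self._xp_hat, np.conj(gy_hat))
        gw = sfft.irfft(prod, n=nfft, axis=-1)[:, :self.kernel]
        self.grads["w"] += gw.real.astype(w.dtype)
        self.grads["b"] += gy.sum(axis=(0, 2)).astype(w.dtype)
        self._xp_hat = self._w_hat = None
        return np.ascontiguousarray(gx, dtype=gy.dtype)


class ChannelLinear(Layer):
    """1x1 (pointwise) convolution: mixes channels at every time point."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / c_in)
        self.add_param("w", (rng.standard_normal((c_out, c_in)) * scale).astype(dtype))
        self.add_param("b", np.zeros(c_out, dtype=dtype))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, c, t = x.shape
        self._x = x
        xt = np.moveaxis(x, 1, 2).reshape(-1, c)
        y = xt @ self.params["w"].T + self.params["b"]
        return np.moveaxis(y.reshape(b, t, -1), 2, 1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, o, t = gy.shape
        c = self._x.shape[1]
        gyt = np.moveaxis(gy, 1, 2).reshape(-1, o)
        xt = np.moveaxis(self._x, 1, 2).reshape(-1, c)
        self.grads["w"] += gyt.T @ xt
        self.grads["b"] += gyt.sum(axis=0)
        gx = gyt @ self.params["w"]
        self._x = None
        return np.moveaxis(gx.reshape(b, t, c), 2, 1)


class BatchNormChannel(Layer):
    """Batch normalization per channel over (batch, time) of (B, C, T)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.add_param("gamma", np.ones(channels, dtype=dtype))
        self.add_param("beta", np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype, copy=False)
        mean = mean.astype(x.dtype, copy=False)
        scale = self.params["gamma"] * inv
        shift = self.params["beta"] - mean * scale
        if training:
            self._x, self._mean, self._inv = x, mean, inv
        y = x * scale[None, :, None]
        y += shift[None, :, None]
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        inv, mean = self._inv, self._mean
        n = gy.shape[0] * gy.shape[2]
        xhat = (self._x - mean[None, :, None]) * inv[None, :, None]
        g_gamma = np.einsum("bct,bct->c", gy, xhat)
        g_beta = gy.sum(axis=(0, 2))
        self.grads["gamma"] += g_gamma
        self.grads["beta"] += g_beta
        xhat *= (g_gamma / n).astype(gy.dtype)[None, :, None]
        gx = gy - (g_beta / n).astype(gy.dtype)[None, :, None] - xhat
        gx *= (self.params["gamma"] * inv)[None, :, None]
        self._x = self._mean = self._inv = None
        return gx.astype(gy.dtype, copy=False)


class ELU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        neg = np.minimum(x, 0.0)
        y = np.maximum(x, 0.0)
        y += np.expm1(neg)
        if training:
            self._pos, self._y = x > 0, y
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        slope = np.where(self._pos, np.asarray(1.0, dtype=gy.dtype), self._y + 1.0)
        self._pos = self._y = None
        return gy * slope


class GELU(Layer):
    """Exact Gaussian-error-linear unit (erf form)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return (0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))).astype(x.dtype)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        self._x = None
        return (gy * (cdf + x * pdf)).astype(gy.dtype)


class Dropout(Layer):
    """Inverted dropout; identity when evaluating or when rate is 0."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate, self.rng = rate, rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        u = self.rng.random(x.shape, dtype=np.float32 if x.dtype == np.float32 else np.float64)
        self._mask = (u < keep).astype(x.dtype) / np.asarray(keep, dtype=x.dtype)
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        gx = gy * self._mask
        self._mask = None
        return gx


class AvgPoolTime(Layer):
    """Non-overlapping average pooling along the last axis (tail cropped)."""

    def __init__(self, factor: int) -> None:
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        t = x.shape[-1]
        t_keep = (t // self.factor) * self.factor
        self._t = t
        xc = x[..., :t_keep]
        return xc.reshape(*x.shape[:-1], t_keep // self.factor, self.factor).mean(axis=-1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        expanded = np.repeat(gy, self.factor, axis=-1) / self.factor
        if expanded.shape[-1] < self._t:
            padw = [(0, 0)] * (gy.ndim - 1) + [(0, self._t - expanded.shape[-1])]
            expanded = np.pad(expanded, padw)
        return expanded.astype(gy.dtype)


class GlobalAvgPoolTime(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._t = x.shape[-1]
        return x.mean(axis=-1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return (np.repeat(gy[..., None], self._t, axis=-1) / self._t).astype(gy.dtype)


class Dense(Layer):
    """Affine map on the last axis of an arbitrary-rank input."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32, scale: float | None = None) -> None:
        super().__init__()
        s = np.sqrt(2.0 / (d_in + d_out)) if scale is None else scale
        self.add_param("w", (rng.standard_normal((d_out, d_in)) * s).astype(dtype))
        self.add_param("b", np.zeros(d_out, dtype=dtype))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = gy.reshape(-1, gy.shape[-1])
        self.grads["w"] += g2.T @ x2
        self.grads["b"] += g2.sum(axis=0)
        gx = gy @ self.params["w"]
        self._x = None
        return gx


class LayerNorm(Layer):
    """Normalization over the last axis with learned scale and shift."""

    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32) -> None:
        super().__init__()
        self.eps = eps
        self.add_param("gamma", np.ones(dim, dtype=dtype))
        self.add_param("beta", np.zeros(dim, dtype=dtype))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._xhat, self._inv = xhat, inv
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        d = gy.shape[-1]
        self.grads["gamma"] += (gy * xhat).reshape(-1, d).sum(axis=0)
        self.grads["beta"] += gy.reshape(-1, d).sum(axis=0)
        gz = gy * self.params["gamma"]
        gx = inv * (gz - gz.mean(axis=-1, keepdims=True)
                    - xhat * (gz * xhat).mean(axis=-1, keepdims=True))
        self._xhat = self._inv = None
        return gx.astype(gy.dtype)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient wrt the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.mean(np.log(np.maximum(p[np.arange(n), labels], 1e-300)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(logits.dtype)
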