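"""Layers with explicit forward/backward passes.

Conventions: activations are float32; image tensors are (B, C, H, T) with H
the range axis and T the temporal axis; sequence tensors are (B, C, T).
Each layer stores whatever it needs for the backward pass on itself, and
backward() *assigns* parameter gradients (one backward per forward), so no
zero_grad step exists.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Module:
    """Base class: parameter registry plus train/eval mode propagation."""

    def __init__(self) -> None:
        self.training = True
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.children: list["Module"] = []

    def parameters(self):
        """Yield (module, name) handles for every trainable array."""
        for name in self.params:
            yield self, name
        for child in self.children:
            yield from child.parameters()

    def n_parameters(self) -> int:
        return sum(module.params[name].size for module, name in self.parameters())

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for child in self.children:
            child.set_training(flag)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.children = list(layers)

    def forward(self, x):
        for layer in self.children:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.children):
            grad = layer.backward(grad)
        return grad


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    """2-D convolution via im2col; odd kernels, 'same' padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride=(1, 1),
                 rng: np.random.Generator | None = None, bias: bool = False,
                 pad: int | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.stride = tuple(stride)
        self.pad = kernel // 2 if pad is None else pad
        self.params["weight"] = _he_normal(rng, (c_out, c_in * kernel * kernel),
                                           c_in * kernel * kernel)
        if bias:
            self.params["bias"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x):
        b, c, h, t = x.shape
        k, (sh, sw), p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh = (h + 2 * p - k) // sh + 1
        ot = (t + 2 * p - k) // sw + 1
        # im2col in (C*k*k, B*OH*OT) layout so both gemms below are single
        # full-size BLAS calls rather than many small batched ones
        xpt = xp.transpose(1, 0, 2, 3)
        cols = np.empty((c, k, k, b, oh, ot), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                cols[:, i, j] = xpt[:, :, i : i + sh * oh : sh, j : j + sw * ot : sw]
        cols = cols.reshape(c * k * k, b * oh * ot)
        out = self.params["weight"] @ cols  # (cout, B*OH*OT)
        if "bias" in self.params:
            out += self.params["bias"][:, None]
        self._cache = (cols, x.shape, oh, ot)
        return np.ascontiguousarray(
            out.reshape(self.c_out, b, oh, ot).transpose(1, 0, 2, 3))

    def backward(self, grad):
        cols, xshape, oh, ot = self._cache
        b, c, h, t = xshape
        k, (sh, sw), p = self.k, self.stride, self.pad
        gmat = np.ascontiguousarray(grad.transpose(1, 0, 2, 3)).reshape(
            self.c_out, b * oh * ot)
        self.grads["weight"] = gmat @ cols.T
        if "bias" in self.params:
            self.grads["bias"] = gmat.sum(axis=1)
        gcols = (self.params["weight"].T @ gmat).reshape(c, k, k, b, oh, ot)
        gxt = np.zeros((c, b, h + 2 * p, t + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                gxt[:, :, i : i + sh * oh : sh, j : j + sw * ot : sw] += gcols[:, i, j]
        gx = gxt.transpose(1, 0, 2, 3)
        gx = gx[:, :, p : p + h, p : p + t] if p else gx
        return np.ascontiguousarray(gx)


class CausalConv1d(Module):
    """Dilated 1-D convolution, left-padded so the output is causal."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int = 1,
                 rng: np.random.Generator | None = None, bias: bool = True) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.k, self.d = c_in, c_out, kernel, dilation
        self.left = (kernel - 1) * dilation
        self.params["weight"] = _he_normal(rng, (c_out, c_in, kernel), c_in * kernel)
        if bias:
            self.params["bias"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x):
        b, c, t = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.left, 0))) if self.left else x
        # (C, B*Tp) layout turns each tap into one full-size gemm
        xpt = np.ascontiguousarray(xp.transpose(1, 0, 2)).reshape(c, b * xp.shape[2])
        w = self.params["weight"]
        tp = xp.shape[2]
        out = np.zeros((self.c_out, b, t), dtype=np.float32)
        xpt3 = xpt.reshape(c, b, tp)
        taps = []
        for i in range(self.k):
            tap = np.ascontiguousarray(xpt3[:, :, i * self.d : i * self.d + t]).reshape(
                c, b * t)
            taps.append(tap)
            out += (w[:, :, i] @ tap).reshape(self.c_out, b, t)
        if "bias" in self.params:
            out += self.params["bias"][:, None, None]
        self._cache = (taps, x.shape, tp)
        return np.ascontiguousarray(out.transpose(1, 0, 2))

    def backward(self, grad):
        taps, xshape, tp = self._cache
        b, c, t = xshape
        w = self.params["weight"]
        gmat = np.ascontiguousarray(grad.transpose(1, 0, 2)).reshape(self.c_out, b * t)
        gw = np.empty_like(w)
        gxpt = np.zeros((c, b, tp), dtype=np.float32)
        for i in range(self.k):
            gw[:, :, i] = gmat @ taps[i].T
            gxpt[:, :, i * self.d : i * self.d + t] += (w[:, :, i].T @ gmat).reshape(
                c, b, t)
        self.grads["weight"] = gw
        if "bias" in self.params:
            self.grads["bias"] = gmat.sum(axis=1)
        gx = gxpt.transpose(1, 0, 2)[:, :, self.left :] if self.left else gxpt.transpose(1, 0, 2)
        return np.ascontiguousarray(gx)


class BatchNorm(Module):
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def _shape(self, x):
        shape = [1] * x.ndim
        shape[1] = -1
        return shape

    def forward(self, x):
        axes = tuple(i for i in range(x.ndim) if i != 1)
        shape = self._shape(x)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean.astype(np.float32).reshape(shape)) * invstd.reshape(shape)
        self._cache = (xhat, invstd, axes, shape)
        return self.params["gamma"].reshape(shape) * xhat + self.params["beta"].reshape(shape)

    def backward(self, grad):
        xhat, invstd, axes, shape = self._cache
        self.grads["gamma"] = (grad * xhat).sum(axis=axes).astype(np.float32)
        self.grads["beta"] = grad.sum(axis=axes).astype(np.float32)
        gxhat = grad * self.params["gamma"].reshape(shape)
        if not self.training:
            return gxhat * invstd.reshape(shape)
        gx = (gxhat
              - gxhat.mean(axis=axes, keepdims=True)
              - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True)
              ) * invstd.reshape(shape)
        return gx.astype(np.float32, copy=False)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class Dropout(Module):
    """Inverted dropout; the RNG is shared with the owning network."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x):
        if not self.training or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class AvgPoolTime(Module):
    """Non-overlapping mean pooling along the last (temporal) axis.

    A trailing remainder shorter than the pool factor is dropped.
    """

    def __init__(self, factor: int) -> None:
        super().__init__()
        self.factor = factor

    def forward(self, x):
        f = self.factor
        if f == 1:
            self._tin = x.shape[-1]
            return x
        t_out = x.shape[-1] // f
        self._tin = x.shape[-1]
        return x[..., : t_out * f].reshape(*x.shape[:-1], t_out, f).mean(axis=-1)

    def backward(self, grad):
        f = self.factor
        if f == 1:
            return grad
        expanded = np.repeat(grad, f, axis=-1) / f
        if expanded.shape[-1] < self._tin:
            pad = [(0, 0)] * (grad.ndim - 1) + [(0, self._tin - expanded.shape[-1])]
            expanded = np.pad(expanded, pad)
        return expanded.astype(np.float32)


class MeanOverRange(Module):
    """Collapse the range axis: (B, C, H, T) -> (B, C, T)."""

    def forward(self, x):
        self._h = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return (np.repeat(grad[:, :, None, :], self._h, axis=2) / self._h).astype(np.float32)


class MeanOverTime(Module):
    """Collapse the temporal axis: (B, C, T) -> (B, C)."""

    def forward(self, x):
        self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return (np.repeat(grad[:, :, None], self._t, axis=2) / self._t).astype(np.float32)


class TakeLastStep(Module):
    """Keep only the final time step: (B, C, T) -> (B, C)."""

    def forward(self, x):
        self._shape = x.shape
        return np.ascontiguousarray(x[:, :, -1])

    def backward(self, grad):
        gx = np.zeros(self._shape, dtype=np.float32)
        gx[:, :, -1] = grad
        return gx


class CloneChannels(Module):
    """Replicate a single-channel image to n channels: (B, H, T) -> (B, n, H, T)."""

    def __init__(self, n: int = 3) -> None:
        super().__init__()
        self.n = n

    def forward(self, x):
        return np.repeat(x[:, None, :, :], self.n, axis=1).astype(np.float32)

    def backward(self, grad):
        return grad.sum(axis=1).astype(np.float32)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["weight"] = _he_normal(rng, (n_out, n_in), n_in)
        self.params["bias"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x):
        self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, grad):
        self.grads["weight"] = (grad.T @ self._x).astype(np.float32)
        self.grads["bias"] = grad.sum(axis=0).astype(np.float32)
        return (grad @ self.params["weight"]).astype(np.float32)
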