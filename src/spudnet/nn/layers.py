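"""Minimal NumPy layers with exact reverse-mode gradients.

Every layer caches what its backward pass needs during forward; backward
consumes the gradient w.r.t. its output, accumulates parameter gradients,
and returns the gradient w.r.t. its input. Shapes follow the (batch,
channels, length) convention of 1-D convolutional networks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv1d",
    "DepthwiseConv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "GlobalAvgPool1d",
    "Flatten",
    "Linear",
    "ECA",
]


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)


class Module:
    """Base class; children and parameters are registered explicitly."""

    def __init__(self):
        self._params: list[Parameter] = []
        self._children: list[Module] = []
        self.training = True

    def register(self, *items):
        for it in items:
            if isinstance(it, Parameter):
                self._params.append(it)
            elif isinstance(it, Module):
                self._children.append(it)
            elif it is not None:
                raise TypeError(f"cannot register {type(it)}")
        return items[0] if len(items) == 1 else items

    def parameters(self) -> list[Parameter]:
        out = list(self._params)
        for c in self._children:
            out.extend(c.parameters())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for c in self._children:
            c.train(mode)
        return self

    def astype(self, dtype) -> "Module":
        """Cast parameters (and buffers) in place, e.g. to float32."""
        for p in self._params:
            p.value = p.value.astype(dtype)
            p.grad = p.grad.astype(dtype)
        self._cast_buffers(dtype)
        for c in self._children:
            c.astype(dtype)
        return self

    def _cast_buffers(self, dtype) -> None:
        pass

    def eval(self) -> "Module":
        return self.train(False)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.modules = list(modules)
        for m in self.modules:
            self.register(m)

    def forward(self, x):
        for m in self.modules:
            x = m.forward(x)
        return x

    def backward(self, grad):
        for m in reversed(self.modules):
            grad = m.backward(grad)
        return grad


def _windows(x_pad: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """(N, C, L_out, k) sliding windows of a padded (N, C, L_pad) array."""
    w = sliding_window_view(x_pad, kernel, axis=2)
    return w[:, :, ::stride, :]


class Conv1d(Module):
    """Cross-correlation along the last axis; bias-free by default."""

    def __init__(self, c_in, c_out, kernel, stride=1, padding=0, bias=False, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.padding = kernel, stride, padding
        std = np.sqrt(2.0 / (c_in * kernel))
        self.W = self.register(
            Parameter(rng.normal(0.0, std, (c_out, c_in, kernel)), "conv.W")
        )
        self.b = None
        if bias:
            self.b = self.register(Parameter(np.zeros(c_out), "conv.b"))

    def forward(self, x):
        if x.shape[1] != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {x.shape[1]}")
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        win = _windows(xp, self.kernel, self.stride)
        self._win, self._in_len = win, x.shape[2]
        out = np.tensordot(win, self.W.value, axes=((1, 3), (1, 2)))
        out = np.ascontiguousarray(out.transpose(0, 2, 1))
        if self.b is not None:
            out += self.b.value[None, :, None]
        return out

    def backward(self, grad):
        win = self._win
        self.W.grad += np.tensordot(grad, win, axes=((0, 2), (0, 2)))
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 2))
        dwin = np.tensordot(grad, self.W.value, axes=(1, 0))  # N, L_out, C, k
        n, _, l_out = grad.shape
        p, l_in = self.padding, self._in_len
        dxp = np.zeros((n, self.c_in, l_in + 2 * p), dtype=grad.dtype)
        pos = np.arange(l_out) * self.stride
        for j in range(self.kernel):
            dxp[:, :, pos + j] += dwin[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, p : p + l_in] if p else dxp


class DepthwiseConv1d(Module):
    """One spatial filter per channel (grouped convolution, groups=C)."""

    def __init__(self, channels, kernel, stride=1, padding=0, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels, self.kernel = channels, kernel
        self.stride, self.padding = stride, padding
        std = np.sqrt(2.0 / kernel)
        self.W = self.register(
            Parameter(rng.normal(0.0, std, (channels, kernel)), "dwconv.W")
        )

    def forward(self, x):
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        win = _windows(xp, self.kernel, self.stride)
        self._win, self._in_len = win, x.shape[2]
        return np.einsum("nclk,ck->ncl", win, self.W.value, optimize=True)

    def backward(self, grad):
        win = self._win
        self.W.grad += np.einsum("ncl,nclk->ck", grad, win, optimize=True)
        n, _, l_out = grad.shape
        p, l_in = self.padding, self._in_len
        dxp = np.zeros((n, self.channels, l_in + 2 * p), dtype=grad.dtype)
        pos = np.arange(l_out) * self.stride
        for j in range(self.kernel):
            dxp[:, :, pos + j] += grad * self.W.value[None, :, j, None]
        return dxp[:, :, p : p + l_in] if p else dxp


class BatchNorm1d(Module):
    """Per-channel normalization with learned affine transform.

    Training mode normalizes by batch statistics and updates running
    estimates; eval mode uses the running estimates (and its backward
    treats them as constants).
    """

    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.gamma = self.register(Parameter(np.ones(channels), "bn.gamma"))
        self.beta = self.register(Parameter(np.zeros(channels), "bn.beta"))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def _cast_buffers(self, dtype) -> None:
        self.running_mean = self.running_mean.astype(dtype)
        self.running_var = self.running_var.astype(dtype)

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._xhat, self._inv = xhat, inv
        self._m = x.shape[0] * x.shape[2]
        self._batch_mode = self.training
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad):
        xhat, inv, m = self._xhat, self._inv, self._m
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        dxhat = grad * self.gamma.value[None, :, None]
        if not self._batch_mode:
            return dxhat * inv[None, :, None]
        s1 = dxhat.sum(axis=(0, 2))[None, :, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2))[None, :, None]
        return (inv[None, :, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class MaxPool1d(Module):
    def __init__(self, kernel=3, stride=2, padding=1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)), constant_values=-np.inf) if p else x
        win = _windows(xp, self.kernel, self.stride)
        self._arg = win.argmax(axis=3)
        self._in_len = x.shape[2]
        return win.max(axis=3)

    def backward(self, grad):
        n, c, l_out = grad.shape
        p, l_in = self.padding, self._in_len
        dxp = np.zeros((n, c, l_in + 2 * p), dtype=grad.dtype)
        pos = np.arange(l_out) * self.stride
        for j in range(self.kernel):
            dxp[:, :, pos + j] += grad * (self._arg == j)
        return dxp[:, :, p : p + l_in] if p else dxp


class GlobalAvgPool1d(Module):
    """(N, C, L) -> (N, C) mean over the spectral axis."""

    def forward(self, x):
        self._l = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._l, axis=2) / self._l


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Module):
    def __init__(self, n_in, n_out, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / n_in)
        self.W = self.register(Parameter(rng.normal(0.0, std, (n_in, n_out)), "fc.W"))
        self.b = self.register(Parameter(np.zeros(n_out), "fc.b")) if bias else None

    def forward(self, x):
        self._x = x
        out = x @ self.W.value
        if self.b is not None:
            out = out + self.b.value[None, :]
        return out

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        if self.b is not None:
            self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class ECA(Module):
    """Efficient channel attention for 1-D feature maps.

    Global-average-pools each channel, runs a k-tap convolution across the
    channel axis (zero padding, no bias), squashes through a logistic, and
    rescales every channel of the input by its weight in (0, 1).
    """

    def __init__(self, channels, kernel, rng=None):
        super().__init__()
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError("ECA kernel must be a positive odd integer")
        rng = rng or np.random.default_rng(0)
        self.channels, self.kernel = channels, kernel
        self.W = self.register(
            Parameter(rng.normal(0.0, 1.0 / np.sqrt(kernel), kernel), "eca.W")
        )

    def forward(self, x):
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        p = self.kernel // 2
        s = x.mean(axis=2)  # (N, C)
        sp = np.pad(s, ((0, 0), (p, p)))
        win = sliding_window_view(sp, self.kernel, axis=1)  # (N, C, k)
        z = win @ self.W.value
        a = _sigmoid(z)
        self._x, self._win, self._a = x, win, a
        return x * a[:, :, None]

    def backward(self, grad):
        x, win, a = self._x, self._win, self._a
        n, c, l = x.shape
        p = self.kernel // 2
        dx = grad * a[:, :, None]
        da = (grad * x).sum(axis=2)
        dz = da * a * (1.0 - a)
        self.W.grad += np.einsum("nc,nck->k", dz, win, optimize=True)
        dsp = np.zeros((n, c + 2 * p), dtype=grad.dtype)
        for j in range(self.kernel):
            dsp[:, j : j + c] += dz * self.W.value[j]
        ds = dsp[:, p : p + c]
        dx += ds[:, :, None] / l
        return dx
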