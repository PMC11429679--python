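"""Minimal NumPy layers with explicit forward/backward passes.

Only what the paired-sequence contact network needs: stride-1 same-padded 1D
and 2D (dilated) convolutions, batch normalization, ReLU, and width-divisible
max pooling.  Downsampling happens exclusively in pooling layers, so the
input gradient of every convolution is again a stride-1 convolution with the
channel-transposed, tap-flipped kernel — no scatter operations anywhere.

All computation is float32.  Layers cache what backward needs on forward;
``train=False`` runs inference (batch norm uses running statistics) and
still supports backward with respect to the input, which is what
input-attribution methods require.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base class: parameter-free identity."""

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, grad) triples for trainable tensors."""
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _win1d(xp: np.ndarray, k: int, d: int) -> np.ndarray:
    """(B, C, L, k) strided tap view of a padded (B, C, Lp) array."""
    span = (k - 1) * d + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, span, axis=2)
    return win[..., ::d]


class Conv1d(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        if kernel % 2 != 1:
            raise ValueError("odd kernels only (same padding)")
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel
        bound = np.sqrt(1.0 / fan_in)
        self.w = rng.uniform(-bound, bound, (c_out, c_in, kernel)).astype(F32)
        self.b = rng.uniform(-bound, bound, c_out).astype(F32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.kernel, self.dilation = kernel, dilation
        self.pad = (kernel - 1) * dilation // 2

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def forward(self, x, train=True):
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        self._xp = xp
        win = _win1d(xp, self.kernel, self.dilation)
        y = np.einsum("bclt,oct->bol", win, self.w, optimize=True)
        return y + self.b[None, :, None]

    def backward(self, grad):
        win = _win1d(self._xp, self.kernel, self.dilation)
        self.gw[...] = np.einsum("bclt,bol->oct", win, grad, optimize=True)
        self.gb[...] = grad.sum(axis=(0, 2))
        # input gradient = same-padded conv with transposed, flipped kernel
        wt = np.ascontiguousarray(self.w[:, :, ::-1].transpose(1, 0, 2))
        gp = np.pad(grad, ((0, 0), (0, 0), (self.pad, self.pad)))
        gwin = _win1d(gp, self.kernel, self.dilation)
        gx = np.einsum("bolt,cot->bcl", gwin, wt, optimize=True)
        del self._xp
        return gx.astype(F32)


def _win2d(xp: np.ndarray, k: int, d: int) -> np.ndarray:
    span = (k - 1) * d + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (span, span), axis=(2, 3))
    return win[..., ::d, ::d]


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        if kernel % 2 != 1:
            raise ValueError("odd kernels only (same padding)")
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        bound = np.sqrt(1.0 / fan_in)
        self.w = rng.uniform(-bound, bound, (c_out, c_in, kernel, kernel)).astype(F32)
        self.b = rng.uniform(-bound, bound, c_out).astype(F32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.kernel, self.dilation = kernel, dilation
        self.pad = (kernel - 1) * dilation // 2

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def forward(self, x, train=True):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp = xp
        win = _win2d(xp, self.kernel, self.dilation)
        y = np.einsum("bchwij,ocij->bohw", win, self.w, optimize=True)
        return y + self.b[None, :, None, None]

    def backward(self, grad):
        win = _win2d(self._xp, self.kernel, self.dilation)
        self.gw[...] = np.einsum("bchwij,bohw->ocij", win, grad, optimize=True)
        self.gb[...] = grad.sum(axis=(0, 2, 3))
        wt = np.ascontiguousarray(
            self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        )
        p = self.pad
        gp = np.pad(grad, ((0, 0), (0, 0), (p, p), (p, p)))
        gwin = _win2d(gp, self.kernel, self.dilation)
        gx = np.einsum("bohwij,coij->bchw", gwin, wt, optimize=True)
        del self._xp
        return gx.astype(F32)


class BatchNorm(Layer):
    """Batch normalization over all axes except channel (axis 1)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=F32)
        self.beta = np.zeros(channels, dtype=F32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [("gamma", self.gamma, self.ggamma), ("beta", self.beta, self.gbeta)]

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train=True):
        axes = (0,) + tuple(range(2, x.ndim))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        sh = self._shape(x)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
        self._cache = (xhat, inv, train, axes, x.shape)
        return (self.gamma.reshape(sh) * xhat + self.beta.reshape(sh)).astype(F32)

    def backward(self, grad):
        xhat, inv, train, axes, shape = self._cache
        sh = self._shape(grad)
        self.ggamma[...] = (grad * xhat).sum(axis=axes)
        self.gbeta[...] = grad.sum(axis=axes)
        g = grad * self.gamma.reshape(sh)
        if not train:
            return (g * inv.reshape(sh)).astype(F32)
        n = np.prod([shape[a] for a in axes])
        dxhat = g
        gx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(sh)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(sh)
        ) * inv.reshape(sh)
        return gx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(F32)

    def backward(self, grad):
        return (grad * self._mask).astype(F32)


class MaxPool1d(Layer):
    """Non-overlapping max pool; input length must be divisible by factor."""

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x, train=True):
        f = self.factor
        if f == 1:
            self._idx = None
            return x
        b, c, l = x.shape
        if l % f:
            raise ValueError(f"length {l} not divisible by pool factor {f}")
        xr = x.reshape(b, c, l // f, f)
        self._idx = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, grad):
        if self._idx is None:
            return grad
        b, c, l = self._shape
        f = self.factor
        gx = np.zeros((b, c, l // f, f), dtype=F32)
        np.put_along_axis(gx, self._idx[..., None], grad[..., None], axis=3)
        return gx.reshape(b, c, l)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for i, layer in enumerate(self.layers):
            out.extend((f"{i}.{n}", v, g) for n, v, g in layer.params())
        return out

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def parameter_count(layer: Layer) -> int:
    return int(sum(v.size for _, v, _ in layer.params()))


def get_state(layer: Layer) -> dict[str, np.ndarray]:
    """Flat state dict including batch-norm running statistics."""
    state = {}

    def walk(l: Layer, prefix: str):
        if isinstance(l, Sequential):
            for i, sub in enumerate(l.layers):
                walk(sub, f"{prefix}{i}.")
        else:
            for n, v, _ in l.params():
                state[prefix + n] = v.copy()
            if isinstance(l, BatchNorm):
                state[prefix + "running_mean"] = l.running_mean.copy()
                state[prefix + "running_var"] = l.running_var.copy()

    walk(layer, "")
    return state


def set_state(layer: Layer, state: dict[str, np.ndarray]) -> None:
    def walk(l: Layer, prefix: str):
        if isinstance(l, Sequential):
            for i, sub in enumerate(l.layers):
                walk(sub, f"{prefix}{i}.")
        else:
            for n, v, _ in l.params():
                v[...] = state[prefix + n]
            if isinstance(l, BatchNorm):
                l.running_mean[...] = state[prefix + "running_mean"]
                l.running_var[...] = state[prefix + "running_var"]

    walk(layer, "")
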