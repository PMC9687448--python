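"""Layers with explicit forward/backward passes, (N, C, H, W) float32 layout."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its accumulated gradient.

    ``decay`` marks parameters subject to the L2 penalty (conv/linear weights,
    not biases or normalization scales).
    """

    def __init__(self, value: np.ndarray, name: str = "", decay: bool = False):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.decay = decay

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    training: bool = True

    def params(self) -> list[Param]:
        return []

    def train(self, mode: bool = True) -> None:
        self.training = mode

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _same_pad(size: int, stride: int, eff_k: int) -> tuple[int, int, int]:
    """TensorFlow-style SAME padding: output = ceil(size/stride)."""
    out = -(-size // stride)
    total = max((out - 1) * stride + eff_k - size, 0)
    return out, total // 2, total - total // 2


class Conv2d(Layer):
    """2-D convolution with stride, dilation and channel groups.

    SAME padding (output spatial size = ceil(input/stride)).  Depthwise
    convolution is ``groups == in_channels``.  Implemented by an
    im2col/matmul pair; the backward pass scatters tap gradients back onto
    the padded input, one kernel tap at a time (taps never overlap for a
    fixed offset, so plain slice-add suffices).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        dilation: int = 1,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = (in_channels // groups) * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels // groups, k, k))
        self.weight = Param(w, f"{name}.weight", decay=True)
        self.bias = Param(np.zeros(out_channels), f"{name}.bias") if bias else None
        self.stride = stride
        self.dilation = dilation
        self.groups = groups
        self.k = k
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        s, d, k = self.stride, self.dilation, self.k
        eff = (k - 1) * d + 1
        win = sliding_window_view(xp, (eff, eff), axis=(2, 3))
        cols = win[:, :, ::s, ::s, ::d, ::d]
        return np.ascontiguousarray(cols[:, :, :ho, :wo])

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        s, d, k, g = self.stride, self.dilation, self.k, self.groups
        eff = (k - 1) * d + 1
        ho, pt, pb = _same_pad(h, s, eff)
        wo, pl, pr = _same_pad(w, s, eff)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        cols = self._im2col(xp, ho, wo)  # (n, c, ho, wo, k, k)
        co = self.weight.value.shape[0]
        if g == 1:
            mat = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
            wmat = self.weight.value.reshape(co, -1)
            out = (mat @ wmat.T).reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
        elif g == c and co == c:
            out = np.einsum("ncijhw,nchw->ncij", cols, np.broadcast_to(self.weight.value[:, 0][None], (n, c, k, k)))
        else:
            cg, cog = c // g, co // g
            out = np.empty((n, co, ho, wo), dtype=np.float32)
            for gi in range(g):
                m = cols[:, gi * cg : (gi + 1) * cg].transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cg * k * k)
                wm = self.weight.value[gi * cog : (gi + 1) * cog].reshape(cog, -1)
                out[:, gi * cog : (gi + 1) * cog] = (m @ wm.T).reshape(n, ho, wo, cog).transpose(0, 3, 1, 2)
        if self.bias is not None:
            out = out + self.bias.value[None, :, None, None]
        self._cache = (cols, xp.shape, x.shape, (pt, pl), (ho, wo))
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xp_shape, x_shape, (pt, pl), (ho, wo) = self._cache
        n, c, h, w = x_shape
        s, d, k, g = self.stride, self.dilation, self.k, self.groups
        co = self.weight.value.shape[0]
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        dcols = np.empty_like(cols)
        if g == 1:
            gm = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
            mat = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
            self.weight.grad += (gm.T @ mat).reshape(self.weight.value.shape)
            dmat = gm @ self.weight.value.reshape(co, -1)
            dcols[...] = dmat.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        elif g == c and co == c:
            self.weight.grad += np.einsum("ncijhw,ncij->chw", cols, grad)[:, None]
            dcols[...] = grad[:, :, :, :, None, None] * self.weight.value[:, 0][None, :, None, None]
        else:
            cg, cog = c // g, co // g
            for gi in range(g):
                gsl = grad[:, gi * cog : (gi + 1) * cog]
                csl = cols[:, gi * cg : (gi + 1) * cg]
                gm = gsl.transpose(0, 2, 3, 1).reshape(n * ho * wo, cog)
                m = csl.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cg * k * k)
                self.weight.grad[gi * cog : (gi + 1) * cog] += (gm.T @ m).reshape(cog, cg, k, k)
                dm = gm @ self.weight.value[gi * cog : (gi + 1) * cog].reshape(cog, -1)
                dcols[:, gi * cg : (gi + 1) * cg] = dm.reshape(n, ho, wo, cg, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki * d : ki * d + s * ho : s, kj * d : kj * d + s * wo : s] += dcols[:, :, :, :, ki, kj]
        return dxp[:, :, pt : pt + h, pl : pl + w]


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return (self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not self.training:
            return (g * inv[None, :, None, None]).astype(np.float32)
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = inv[None, :, None, None] * (g - gsum / n_eff - xhat * gx / n_eff)
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0).astype(np.float32)


class MaxPool2d(Layer):
    """Non-overlapping max pooling (pool = stride), right/bottom -inf padding."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.pool
        n, c, h, w = x.shape
        ho, wo = -(-h // p), -(-w // p)
        xp = np.full((n, c, ho * p, wo * p), -np.inf, dtype=np.float32)
        xp[:, :, :h, :w] = x
        tiles = xp.reshape(n, c, ho, p, wo, p).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, p * p)
        self._arg = tiles.argmax(axis=-1)
        self._shape = (n, c, h, w, ho, wo)
        return tiles.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        p = self.pool
        n, c, h, w, ho, wo = self._shape
        dtiles = np.zeros((n, c, ho, wo, p * p), dtype=np.float32)
        np.put_along_axis(dtiles, self._arg[..., None], grad[..., None], axis=-1)
        dxp = dtiles.reshape(n, c, ho, wo, p, p).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho * p, wo * p)
        return dxp[:, :, :h, :w]


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (half-pixel centers)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(np.float32)
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


class BilinearResize(Layer):
    """Resize feature maps to a fixed (H, W) by separable bilinear interpolation."""

    def __init__(self, out_hw: tuple[int, int]):
        self.out_hw = out_hw
        self._mats: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        h, w = x.shape[2:]
        key = (h, w)
        if key not in self._mats:
            self._mats[key] = (_interp_matrix(self.out_hw[0], h), _interp_matrix(self.out_hw[1], w))
        wr, wc = self._mats[key]
        self._key = key
        y = np.tensordot(x, wr, axes=([2], [1]))  # n,c,w,ho
        y = np.tensordot(y, wc, axes=([2], [1]))  # n,c,ho,wo
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        wr, wc = self._mats[self._key]
        g = np.tensordot(grad, wr, axes=([2], [0]))  # n,c,wo,hi
        g = np.tensordot(g, wc, axes=([2], [0]))  # n,c,hi,wi
        return np.ascontiguousarray(g, dtype=np.float32)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3), keepdims=True)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad / (h * w), self._shape).astype(np.float32)


class Broadcast2d(Layer):
    """Broadcast a (N, C, 1, 1) map to a fixed spatial size (image-pooling branch)."""

    def __init__(self, out_hw: tuple[int, int]):
        self.out_hw = out_hw

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c = x.shape[:2]
        return np.broadcast_to(x, (n, c) + self.out_hw).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.sum(axis=(2, 3), keepdims=True)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None, name: str = "fc"):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.weight = Param(w, f"{name}.weight", decay=True)
        self.bias = Param(np.zeros(n_out), f"{name}.bias")

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return (grad @ self.weight.value).astype(np.float32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def train(self, mode: bool = True) -> None:
        self.training = mode
        for layer in self.layers:
            layer.train(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Concat(Layer):
    """Run branches on the same input and concatenate outputs along channels."""

    def __init__(self, *branches: Layer):
        self.branches = list(branches)

    def params(self) -> list[Param]:
        return [p for b in self.branches for p in b.params()]

    def train(self, mode: bool = True) -> None:
        self.training = mode
        for b in self.branches:
            b.train(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = [b.forward(x) for b in self.branches]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        parts = np.split(grad, self._splits, axis=1)
        dx = None
        for b, g in zip(self.branches, parts):
            d = b.backward(np.ascontiguousarray(g))
            dx = d if dx is None else dx + d
        return dx
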