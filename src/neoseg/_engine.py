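"""Minimal CPU neural-network layers with explicit backpropagation.

Everything operates on float32 arrays in channels-first layout
``(batch, channels, *spatial)`` with a spatial rank of 2 or 3.

Convolutions use same-padding and are evaluated as a loop over kernel
offsets, each offset contributing one (channels_in -> channels_out) GEMM on
the shifted input.  This keeps memory bounded (no im2col matrix) while all
arithmetic still goes through BLAS.  Pooling and upsampling use
non-overlapping 2x windows via reshape tricks.

Each layer caches what its backward pass needs during ``forward``; calling
``backward`` consumes the cache and accumulates parameter gradients in-place.
"""

from __future__ import annotations

import itertools
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "Param",
    "ConvND",
    "BatchNorm",
    "ReLU",
    "Pool2",
    "Upsample2",
    "Adam",
    "softmax_channel",
    "ce_dice_loss_and_grad",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = value
        self.grad = np.zeros_like(value)


class ConvND:
    """Same-padded convolution of spatial rank 2 or 3.

    ``kernel`` is the per-axis kernel extent; odd extents give exact
    same-padding.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: Sequence[int],
        rng: np.random.Generator,
    ) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = tuple(int(k) for k in kernel)
        fan_in = in_channels * int(np.prod(self.kernel))
        scale = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU nets
        w = rng.normal(0.0, scale, size=(out_channels, in_channels) + self.kernel)
        self.weight = Param(w.astype(np.float32))
        self.bias = Param(np.zeros(out_channels, dtype=np.float32))
        self._cache = None

    @property
    def params(self) -> List[Param]:
        return [self.weight, self.bias]

    def _pad_widths(self) -> List[Tuple[int, int]]:
        return [(k // 2, k - 1 - k // 2) for k in self.kernel]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b = x.shape[0]
        spatial = x.shape[2:]
        v = int(np.prod(spatial))
        pads = [(0, 0), (0, 0)] + self._pad_widths()
        xp = np.pad(x, pads)
        w = self.weight.value
        y = np.zeros((b, self.out_channels, v), dtype=np.float32)
        offsets = list(itertools.product(*[range(k) for k in self.kernel]))
        slabs = [] if train else None
        for off in offsets:
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial)
            )
            xs = np.ascontiguousarray(xp[sl]).reshape(b, self.in_channels, v)
            w_o = w[(slice(None), slice(None)) + off]  # (out, in)
            y += np.matmul(w_o[None], xs)
            if train:
                slabs.append(xs)
        y += self.bias.value[None, :, None]
        if train:
            self._cache = (slabs, spatial, b, v)
        return y.reshape((b, self.out_channels) + spatial)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        slabs, spatial, b, v = self._cache
        self._cache = None
        dy_f = dy.reshape(b, self.out_channels, v)
        self.bias.grad += dy_f.sum(axis=(0, 2))
        w = self.weight.value
        pads = self._pad_widths()
        padded_shape = (b, self.in_channels) + tuple(
            s + p0 + p1 for s, (p0, p1) in zip(spatial, pads)
        )
        dxp = np.zeros(padded_shape, dtype=np.float32)
        offsets = list(itertools.product(*[range(k) for k in self.kernel]))
        for off, xs in zip(offsets, slabs):
            w_o = w[(slice(None), slice(None)) + off]  # (out, in)
            # parameter gradient: sum_b dY @ X^T
            self.weight.grad[(slice(None), slice(None)) + off] += np.einsum(
                "bov,biv->oi", dy_f, xs, optimize=True
            )
            # input gradient scattered back to the shifted slab
            dxs = np.matmul(w_o.T[None], dy_f).reshape((b, self.in_channels) + spatial)
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial)
            )
            dxp[sl] += dxs
        unpad = (slice(None), slice(None)) + tuple(
            slice(p0, p0 + s) for s, (p0, p1) in zip(spatial, pads)
        )
        return dxp[unpad]


class BatchNorm:
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    @staticmethod
    def _bshape(x: np.ndarray) -> tuple:
        return (1, x.shape[1]) + (1,) * (x.ndim - 2)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._bshape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        if train:
            self._cache = (xhat, inv_std, axes, shape)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, shape = self._cache
        self._cache = None
        n = dy.size / dy.shape[1]
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value.reshape(shape)
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).sum(axis=axes).reshape(shape) / n
        ) * inv_std.reshape(shape)
        return dx.astype(np.float32)


class ReLU:
    def __init__(self) -> None:
        self._mask = None

    params: List[Param] = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return dy * mask


def _window_view(x: np.ndarray) -> Tuple[np.ndarray, tuple]:
    """Reshape (B, C, 2a, 2b[, 2c]) to expose non-overlapping 2x windows."""
    b, c = x.shape[:2]
    spatial = x.shape[2:]
    newshape = (b, c) + tuple(v for s in spatial for v in (s // 2, 2))
    win_axes = tuple(3 + 2 * i for i in range(len(spatial)))
    return x.reshape(newshape), win_axes


class Pool2:
    """Non-overlapping 2x pooling, kind 'max' or 'avg'; halves every axis."""

    def __init__(self, kind: str) -> None:
        if kind not in ("max", "avg"):
            raise ValueError(f"unknown pooling kind {kind!r}")
        self.kind = kind
        self._cache = None

    params: List[Param] = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        xw, win_axes = _window_view(x)
        if self.kind == "max":
            y = xw.max(axis=win_axes)
            if train:
                self._cache = (x.shape, xw, y, win_axes)
        else:
            y = xw.mean(axis=win_axes)
            if train:
                self._cache = (x.shape, None, None, win_axes)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        in_shape, xw, y, win_axes = self._cache
        self._cache = None
        r = len(in_shape) - 2
        if self.kind == "avg":
            dxw = np.broadcast_to(
                np.expand_dims(dy, win_axes) / (2**r),
                _window_view(np.empty(in_shape, dtype=np.float32))[0].shape,
            )
            return np.ascontiguousarray(dxw).reshape(in_shape)
        y_e = np.expand_dims(y, win_axes)
        mask = xw == y_e
        mask = mask / mask.sum(axis=win_axes, keepdims=True)  # split ties evenly
        dxw = np.expand_dims(dy, win_axes) * mask
        return np.ascontiguousarray(dxw).reshape(in_shape).astype(np.float32)


class Upsample2:
    """Nearest-neighbour 2x upsampling; doubles every spatial axis."""

    def __init__(self) -> None:
        self._in_shape = None

    params: List[Param] = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        y = x
        for ax in range(2, x.ndim):
            y = np.repeat(y, 2, axis=ax)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        in_shape, self._in_shape = self._in_shape, None
        dyw, win_axes = _window_view(dy)
        return dyw.sum(axis=win_axes).astype(np.float32)


class Adam:
    """Adaptive-moment optimiser over a flat parameter list."""

    def __init__(self, params: List[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def softmax_channel(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the channel axis (axis 1)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def ce_dice_loss_and_grad(
    logits: np.ndarray, target: np.ndarray, dice_eps: float = 1.0
) -> Tuple[float, np.ndarray]:
    """Sum of voxel-wise cross-entropy and soft-Dice loss.

    ``target`` holds integer class labels shaped like the logits without the
    channel axis.  Returns the scalar loss and its gradient with respect to
    the logits.
    """
    n_classes = logits.shape[1]
    p = softmax_channel(logits)
    onehot = np.moveaxis(np.eye(n_classes, dtype=np.float32)[target], -1, 1)
    n_vox = target.size

    ce = -float((onehot * np.log(p + 1e-12)).sum()) / n_vox

    axes = (0,) + tuple(range(2, logits.ndim))
    inter = (p * onehot).sum(axis=axes)
    sums = p.sum(axis=axes) + onehot.sum(axis=axes)
    dice_per_class = (2.0 * inter + dice_eps) / (sums + dice_eps)
    dice_loss = 1.0 - float(dice_per_class.mean())

    # d(dice_loss)/dp, then chain through the softmax Jacobian
    shape = (1, n_classes) + (1,) * (logits.ndim - 2)
    d_num = 2.0 * onehot
    d_dice_dp = (
        d_num * (sums + dice_eps).reshape(shape)
        - (2.0 * inter + dice_eps).reshape(shape)
    ) / ((sums + dice_eps) ** 2).reshape(shape)
    dl_dp = -d_dice_dp / n_classes
    dl_dp += -(onehot / (p + 1e-12)) / n_vox  # cross-entropy term
    dot = (dl_dp * p).sum(axis=1, keepdims=True)
    dlogits = p * (dl_dp - dot)
    return ce + dice_loss, dlogits.astype(np.float32)
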