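"""Trainable layers with explicit forward/backward passes.

Each layer caches what its backward pass needs during a training-mode
forward call; inference-mode calls keep no caches so large volumes can be
processed within a small memory footprint.
"""

from __future__ import annotations

import numpy as np

from .functional import (
    DTYPE,
    conv3d_backward_input,
    conv3d_backward_weights,
    conv3d_forward,
    upsample2_trilinear,
    upsample2_trilinear_adjoint,
)

__all__ = ["Param", "Layer", "Conv3d", "ConvTranspose3d", "ReLU", "SENorm", "MaxPool2", "Upsample"]

_EPS = 1e-5


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv3d(Layer):
    """3D cross-correlation, stride 1, 'same' padding (kernel 3) or pointwise (kernel 1)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, name: str = ""):
        self.k = k
        self.W = Param(_he_init(rng, (cout, cin, k, k, k), cin * k**3), f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x if train else None
        return conv3d_forward(x, self.W.data, self.b.data, stride=1)

    def backward(self, gy):
        if self._x is None:
            raise RuntimeError("backward called without a training-mode forward")
        gW, gb = conv3d_backward_weights(self._x, gy, self.k, stride=1)
        self.W.grad += gW
        self.b.grad += gb
        gx = conv3d_backward_input(gy, self.W.data, self._x.shape[1:], stride=1)
        self._x = None
        return gx


class ConvTranspose3d(Layer):
    """Kernel-3, stride-2 transposed convolution that exactly doubles each axis.

    Implemented as the adjoint of a stride-2 convolution; the weight is
    stored in that convolution's layout ``(cin, cout, 3, 3, 3)``.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = ""):
        self.W = Param(_he_init(rng, (cin, cout, 3, 3, 3), cin * 27), f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x if train else None
        fine = tuple(2 * d for d in x.shape[1:])
        y = conv3d_backward_input(x, self.W.data, fine, stride=2, pad=1)
        return y + self.b.data[:, None, None, None]

    def backward(self, gy):
        if self._x is None:
            raise RuntimeError("backward called without a training-mode forward")
        gW, _ = conv3d_backward_weights(gy, self._x, 3, stride=2, pad=1)
        self.W.grad += gW
        self.b.grad += gy.sum(axis=(1, 2, 3))
        gx = conv3d_forward(gy, self.W.data, None, stride=2, pad=1)
        self._x = None
        return gx


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        y = np.maximum(x, 0)
        self._mask = x > 0 if train else None
        return y

    def backward(self, gy):
        gx = gy * self._mask
        self._mask = None
        return gx


def _sigmoid(z):
    z = np.clip(z, -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(-z))


class SENorm(Layer):
    """Squeeze-and-excitation normalization.

    Channel-wise instance normalization (zero mean, unit variance over
    spatial voxels, epsilon-stabilized) whose affine parameters are not
    free weights but functions of the layer input: a squeeze (global
    average pool) feeds a bottleneck FC + ReLU, from which two parallel FC
    expansions produce a sigmoid-gated scale gamma and an unbounded shift
    beta per channel: ``y_c = gamma_c * norm(x_c) + beta_c``.
    """

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 2, name: str = ""):
        cr = max(1, channels // reduction)
        self.channels = channels
        # squeeze input is a pooled post-ReLU mean (non-negative), so a
        # non-negative bottleneck init keeps every excitation unit active
        self.W1 = Param(np.abs(_he_init(rng, (cr, channels), channels)), f"{name}.W1")
        self.b1 = Param(np.zeros(cr), f"{name}.b1")
        self.Wg = Param(_he_init(rng, (channels, cr), cr), f"{name}.Wg")
        self.bg = Param(np.zeros(channels), f"{name}.bg")
        self.Wb = Param(np.zeros((channels, cr)), f"{name}.Wb")
        self.bb = Param(np.zeros(channels), f"{name}.bb")
        self._cache = None

    def params(self):
        return [self.W1, self.b1, self.Wg, self.bg, self.Wb, self.bb]

    def forward(self, x, train=False):
        C = x.shape[0]
        shape = x.shape
        xf = x.reshape(C, -1)
        mu = xf.mean(axis=1)
        var = xf.var(axis=1)
        istd = 1.0 / np.sqrt(var + _EPS)
        xn = (xf - mu[:, None]) * istd[:, None]
        h = np.maximum(self.W1.data @ mu + self.b1.data, 0.0)
        gamma = _sigmoid(self.Wg.data @ h + self.bg.data)
        beta = self.Wb.data @ h + self.bb.data
        y = gamma[:, None].astype(DTYPE) * xn + beta[:, None].astype(DTYPE)
        self._cache = (xn, istd, mu, h, gamma, shape) if train else None
        return y.reshape(shape).astype(DTYPE, copy=False)

    def backward(self, gy):
        if self._cache is None:
            raise RuntimeError("backward called without a training-mode forward")
        xn, istd, mu, h, gamma, shape = self._cache
        C = shape[0]
        n = xn.shape[1]
        gyf = gy.reshape(C, -1)
        ggamma = (gyf * xn).sum(axis=1)
        gbeta = gyf.sum(axis=1)
        gxn = gyf * gamma[:, None].astype(DTYPE)
        # instance-norm backward
        gx = istd[:, None].astype(DTYPE) * (
            gxn
            - gxn.mean(axis=1, keepdims=True)
            - xn * (gxn * xn).mean(axis=1, keepdims=True)
        )
        # squeeze-excitation pathway
        gzg = ggamma * gamma * (1.0 - gamma)
        self.Wg.grad += np.outer(gzg, h)
        self.bg.grad += gzg
        self.Wb.grad += np.outer(gbeta, h)
        self.bb.grad += gbeta
        gh = (self.Wg.data.T @ gzg + self.Wb.data.T @ gbeta) * (h > 0)
        self.W1.grad += np.outer(gh, mu)
        self.b1.grad += gh
        gmu = self.W1.data.T @ gh
        gx += (gmu[:, None] / n).astype(DTYPE)
        self._cache = None
        return gx.reshape(shape)


class MaxPool2(Layer):
    """2x2x2 max pooling (spatial dims must be even)."""

    def __init__(self):
        self._cache = None

    def forward(self, x, train=False):
        C, D, H, W = x.shape
        if D % 2 or H % 2 or W % 2:
            raise ValueError(f"max-pool input must have even spatial dims, got {x.shape}")
        xr = (
            x.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(C, D // 2, H // 2, W // 2, 8)
        )
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape) if train else None
        return np.ascontiguousarray(y)

    def backward(self, gy):
        idx, in_shape = self._cache
        C, D, H, W = in_shape
        g8 = np.zeros(gy.shape + (8,), dtype=DTYPE)
        np.put_along_axis(g8, idx[..., None], gy[..., None], axis=-1)
        gx = (
            g8.reshape(C, D // 2, H // 2, W // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(C, D, H, W)
        )
        self._cache = None
        return np.ascontiguousarray(gx)


class Upsample(Layer):
    """Parameter-free trilinear up-sampling by 2**levels (used by aux heads)."""

    def __init__(self, levels: int):
        self.levels = levels

    def forward(self, x, train=False):
        for _ in range(self.levels):
            x = upsample2_trilinear(x)
        return x

    def backward(self, gy):
        for _ in range(self.levels):
            gy = upsample2_trilinear_adjoint(gy)
        return gy
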