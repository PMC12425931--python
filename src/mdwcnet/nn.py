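"""Minimal explicit-gradient neural-network layers on NumPy.

Every layer implements ``forward(x, train)`` and ``backward(grad_out)``;
``backward`` accumulates parameter gradients in place and returns the
gradient with respect to the layer input.  Activations needed for the
backward pass are cached on the layer instance, which is safe because the
network graph is static and each layer instance appears exactly once in it.

All arrays are ``float32``; spatial layout is NCHW.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .errors import ConfigurationError

DTYPE = np.float32


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    # uniform +/- 1/sqrt(fan_in): the default convolution/linear initialiser
    # of mainstream deep-learning frameworks; under batch norm the weight
    # norm sets the effective learning rate, so matching the convention also
    # matches the reference training dynamics
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class PointwiseConv(Layer):
    """1x1 convolution (pure cross-channel mixing)."""

    def __init__(self, rng, in_ch: int, out_ch: int, bias: bool = False):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.w = Param(_he_init(rng, (out_ch, in_ch), in_ch))
        self.b = Param(np.zeros(out_ch)) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        self._x = x
        y = np.matmul(self.w.data, x.reshape(n, c, h * w)).reshape(n, self.out_ch, h, w)
        if self.b is not None:
            y += self.b.data[None, :, None, None]
        return y

    def backward(self, grad):
        n, _, h, w = grad.shape
        gm = grad.reshape(n, self.out_ch, h * w)
        xm = self._x.reshape(n, self.in_ch, h * w)
        self.w.grad += np.matmul(gm, xm.transpose(0, 2, 1)).sum(axis=0)
        if self.b is not None:
            self.b.grad += gm.sum(axis=(0, 2))
        gx = np.matmul(self.w.data.T, gm).reshape(self._x.shape)
        return gx


class DepthwiseConv(Layer):
    """k x k per-channel convolution, stride 1, 'same' zero padding."""

    def __init__(self, rng, channels: int, kernel: int, dilation: int = 1):
        if kernel % 2 == 0:
            raise ConfigurationError(f"kernel size must be odd, got {kernel}")
        self.channels, self.k, self.d = channels, kernel, dilation
        self.pad = dilation * (kernel // 2)
        self.w = Param(_he_init(rng, (channels, kernel, kernel), kernel * kernel))

    def params(self):
        return [self.w]

    def forward(self, x, train=True):
        p, k, d = self.pad, self.k, self.d
        n, c, h, w = x.shape
        if k == 1:  # pure per-channel scaling
            self._xp, self._hw = x, (h, w)
            return self.w.data[:, 0, 0][None, :, None, None] * x
        if p:
            xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
            xp[:, :, p : p + h, p : p + w] = x
        else:
            xp = x
        self._xp, self._hw = xp, (h, w)
        y = np.zeros((n, c, h, w), dtype=DTYPE)
        if _kernels.HAVE_NUMBA:
            _kernels.dw_fwd(xp, self.w.data, d, y)
            return y
        for i in range(k):
            for j in range(k):
                y += self.w.data[:, i, j][None, :, None, None] * xp[
                    :, :, i * d : i * d + h, j * d : j * d + w
                ]
        return y

    def backward(self, grad):
        p, k, d = self.pad, self.k, self.d
        h, w = self._hw
        xp = self._xp
        if k == 1:
            self.w.grad[:, 0, 0] += (xp * grad).sum(axis=(0, 2, 3))
            return self.w.data[:, 0, 0][None, :, None, None] * grad
        gxp = np.zeros_like(xp)
        if _kernels.HAVE_NUMBA:
            _kernels.dw_bwd(xp, self.w.data, np.ascontiguousarray(grad), d, gxp, self.w.grad)
        else:
            for i in range(k):
                for j in range(k):
                    sl = np.s_[:, :, i * d : i * d + h, j * d : j * d + w]
                    self.w.grad[:, i, j] += (xp[sl] * grad).sum(axis=(0, 2, 3))
                    gxp[sl] += self.w.data[:, i, j][None, :, None, None] * grad
        if p:
            return gxp[:, :, p : p + h, p : p + w]
        return gxp


class Conv2d(Layer):
    """Full k x k convolution, stride 1, 'same' zero padding, optional dilation."""

    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int, dilation: int = 1,
                 bias: bool = False):
        if kernel % 2 == 0:
            raise ConfigurationError(f"kernel size must be odd, got {kernel}")
        self.in_ch, self.out_ch, self.k, self.d = in_ch, out_ch, kernel, dilation
        self.pad = dilation * (kernel // 2)
        self.w = Param(_he_init(rng, (out_ch, in_ch, kernel, kernel), in_ch * kernel * kernel))
        self.b = Param(np.zeros(out_ch)) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        p, k, d = self.pad, self.k, self.d
        n, c, h, w = x.shape
        if p:
            xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
            xp[:, :, p : p + h, p : p + w] = x
        else:
            xp = x
        self._xp, self._hw = xp, (h, w)
        y = np.zeros((n, self.out_ch, h, w), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i * d : i * d + h, j * d : j * d + w].reshape(n, c, h * w)
                y += np.matmul(self.w.data[:, :, i, j], xs).reshape(n, self.out_ch, h, w)
        if self.b is not None:
            y += self.b.data[None, :, None, None]
        return y

    def backward(self, grad):
        p, k, d = self.pad, self.k, self.d
        h, w = self._hw
        n = grad.shape[0]
        xp = self._xp
        gm = grad.reshape(n, self.out_ch, h * w)
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = np.s_[:, :, i * d : i * d + h, j * d : j * d + w]
                xs = xp[sl].reshape(n, self.in_ch, h * w)
                self.w.grad[:, :, i, j] += np.matmul(gm, xs.transpose(0, 2, 1)).sum(axis=0)
                gxp[sl] += np.matmul(self.w.data[:, :, i, j].T, gm).reshape(n, self.in_ch, h, w)
        if self.b is not None:
            self.b.grad += gm.sum(axis=(0, 2))
        if p:
            return gxp[:, :, p : p + h, p : p + w]
        return gxp


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv, self._train = xhat.astype(DTYPE), inv.astype(DTYPE), train
        return self.gamma.data[None, :, None, None] * self._xhat + self.beta.data[None, :, None, None]

    def backward(self, grad):
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.data[None, :, None, None]
        if not self._train:
            return g * inv[None, :, None, None]
        n, _, h, w = grad.shape
        m = n * h * w
        s1 = g.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / m) * (m * g - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class ChannelSoftmax(Layer):
    """Softmax across the channel axis at every spatial position.

    Numerically stabilised by max subtraction.
    """

    def forward(self, x, train=True):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._y = (e / e.sum(axis=1, keepdims=True)).astype(DTYPE)
        return self._y

    def backward(self, grad):
        y = self._y
        return y * (grad - (grad * y).sum(axis=1, keepdims=True))


class AdaptiveChannelWeight(Layer):
    """Per-channel learnable scaling: ``y[:, c] = w[c] * x[:, c]``.

    Weights start at 1 (identity) and are updated by plain gradient descent
    along with every other parameter; the analytic weight gradient is the
    spatial sum of ``x * dL/dy`` per channel.
    """

    def __init__(self, channels: int):
        self.channels = channels
        self.w = Param(np.ones(channels))

    def params(self):
        return [self.w]

    def forward(self, x, train=True):
        if x.shape[1] != self.channels:
            raise ConfigurationError(
                f"adaptive weights of length {self.channels} applied to {x.shape[1]} channels"
            )
        self._x = x
        return self.w.data[None, :, None, None] * x

    def backward(self, grad):
        self.w.grad += (self._x * grad).sum(axis=(0, 2, 3))
        return self.w.data[None, :, None, None] * grad


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; ties resolve to the first window position."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ConfigurationError(f"max-pool needs even spatial dims, got {h}x{w}")
        self._shape = x.shape
        if _kernels.HAVE_NUMBA:
            y = np.empty((n, c, h // 2, w // 2), dtype=DTYPE)
            self._idx = np.empty((n, c, h // 2, w // 2), dtype=np.int8)
            _kernels.pool2_fwd(np.ascontiguousarray(x), y, self._idx)
            return y
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xf = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        self._idx = xf.argmax(axis=-1).astype(np.int8)
        return np.take_along_axis(xf, self._idx[..., None].astype(np.intp), axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._shape
        if _kernels.HAVE_NUMBA:
            gx = np.zeros((n, c, h, w), dtype=DTYPE)
            _kernels.pool2_bwd(np.ascontiguousarray(grad), self._idx, gx)
            return gx
        gf = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(gf, self._idx[..., None].astype(np.intp), grad[..., None], axis=-1)
        return gf.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class UpsampleBilinear2x(Layer):
    """Bilinear 2x upsampling (half-pixel centres, edges clamped).

    Separable with fixed taps: output row ``2i`` mixes input rows ``i-1`` and
    ``i`` with weights 1/4 and 3/4; row ``2i+1`` mixes rows ``i`` and ``i+1``
    with weights 3/4 and 1/4.  The backward pass is the exact transpose.
    """

    @staticmethod
    def _up_axis(x, axis):
        lo = np.take(x, [0], axis=axis)
        shift_up = np.concatenate([lo, np.delete(x, -1, axis=axis)], axis=axis)  # x[i-1]
        hi = np.take(x, [-1], axis=axis)
        shift_dn = np.concatenate([np.delete(x, 0, axis=axis), hi], axis=axis)  # x[i+1]
        a = 0.75 * x + 0.25 * shift_up
        b = 0.75 * x + 0.25 * shift_dn
        out_shape = list(x.shape)
        out_shape[axis] *= 2
        y = np.empty(out_shape, dtype=DTYPE)
        sl_even = [slice(None)] * x.ndim
        sl_even[axis] = slice(0, None, 2)
        sl_odd = [slice(None)] * x.ndim
        sl_odd[axis] = slice(1, None, 2)
        y[tuple(sl_even)] = a
        y[tuple(sl_odd)] = b
        return y

    @staticmethod
    def _down_axis(g, axis):
        sl_even = [slice(None)] * g.ndim
        sl_even[axis] = slice(0, None, 2)
        sl_odd = [slice(None)] * g.ndim
        sl_odd[axis] = slice(1, None, 2)
        ga = g[tuple(sl_even)]
        gb = g[tuple(sl_odd)]
        gx = 0.75 * (ga + gb)
        # transpose of the clamped i-1 shift: gx[i-1] += 0.25*ga[i], gx[0] += 0.25*ga[0]
        shift = np.concatenate([np.delete(ga, 0, axis=axis), np.zeros_like(np.take(ga, [0], axis=axis))], axis=axis)
        gx += 0.25 * shift
        first = [slice(None)] * g.ndim
        first[axis] = slice(0, 1)
        gx[tuple(first)] += 0.25 * np.take(ga, [0], axis=axis)
        # transpose of the clamped i+1 shift: gx[i+1] += 0.25*gb[i], gx[-1] += 0.25*gb[-1]
        shift = np.concatenate([np.zeros_like(np.take(gb, [0], axis=axis)), np.delete(gb, -1, axis=axis)], axis=axis)
        gx += 0.25 * shift
        last = [slice(None)] * g.ndim
        last[axis] = slice(-1, None)
        gx[tuple(last)] += 0.25 * np.take(gb, [-1], axis=axis)
        return gx.astype(DTYPE)

    def forward(self, x, train=True):
        if _kernels.HAVE_NUMBA:
            n, c, h, w = x.shape
            y = np.empty((n, c, 2 * h, 2 * w), dtype=DTYPE)
            _kernels.up2_fwd(np.ascontiguousarray(x, dtype=DTYPE), y)
            return y
        return self._up_axis(self._up_axis(x, 2), 3)

    def backward(self, grad):
        if _kernels.HAVE_NUMBA:
            n, c, h, w = grad.shape
            gx = np.zeros((n, c, h // 2, w // 2), dtype=DTYPE)
            _kernels.up2_bwd(np.ascontiguousarray(grad, dtype=DTYPE), gx)
            return gx
        return self._down_axis(self._down_axis(grad, 3), 2)


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._shape).astype(DTYPE)


class GlobalMaxPool(Layer):
    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xf = x.reshape(n, c, h * w)
        self._idx = xf.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xf, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._shape
        gf = np.zeros((n, c, h * w), dtype=DTYPE)
        np.put_along_axis(gf, self._idx[..., None], grad[..., None], axis=-1)
        return gf.reshape(self._shape)


class Linear(Layer):
    def __init__(self, rng, in_features: int, out_features: int, bias: bool = True):
        self.w = Param(_he_init(rng, (out_features, in_features), in_features))
        self.b = Param(np.zeros(out_features)) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        self._x = x
        y = x @ self.w.data.T
        if self.b is not None:
            y += self.b.data
        return y

    def backward(self, grad):
        self.w.grad += grad.T @ self._x
        if self.b is not None:
            self.b.grad += grad.sum(axis=0)
        return grad @ self.w.data


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class SGD:
    """Stochastic gradient descent with classical momentum.

    ``v <- mu * v + g``, ``p <- p - lr * v``; the learning rate may be changed
    between steps (step-decay schedules).
    """

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._vel = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        for p, v in zip(self.params, self._vel):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
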