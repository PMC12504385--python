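"""Minimal feed-forward layer library on numpy with explicit backprop.

All layers follow the same contract: ``forward(x, training)`` caches whatever
the gradient needs, ``backward(grad_out)`` accumulates parameter gradients and
returns the gradient w.r.t. the layer input.

The 2-D layers use a channels-first CBHW layout ``[conv_channels, batch,
height, width]``: im2col then reduces to contiguous slice copies and a single
GEMM whose output is already in layout order, which is what makes CPU
training tractable.  ``Flatten`` converts to the conventional ``[batch,
features]`` for the dense layers.  Every source of randomness is an explicit
``numpy.random.Generator`` so a whole model is reproducible from one seed.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A learnable array together with its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class; stateless layers simply do not override ``parameters``."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _same_pad(k: int) -> tuple[int, int]:
    # 'same' padding for stride 1: total k-1, extra sample on the right
    return (k - 1) // 2, k // 2


class Conv2d(Layer):
    """2-D convolution (stride 1) on CBHW arrays via im2col + GEMM.

    padding: 'same' keeps the spatial extent, 'valid' shrinks it by k-1.
    Weights are Kaiming-uniform, biases zero.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 padding: str, rng: np.random.Generator, dtype=np.float32,
                 name: str = "conv"):
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.in_ch, self.out_ch, self.kernel, self.padding = in_ch, out_ch, kernel, padding
        kh, kw = kernel
        fan_in = in_ch * kh * kw
        bound = np.sqrt(6.0 / fan_in)
        w = rng.uniform(-bound, bound, size=(out_ch, in_ch, kh, kw)).astype(dtype)
        self.weight = Parameter(w, f"{name}.weight")
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype), f"{name}.bias")
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, training=False):
        kh, kw = self.kernel
        if self.padding == "same":
            ph, pw = _same_pad(kh), _same_pad(kw)
            xp = np.pad(x, ((0, 0), (0, 0), ph, pw))
        else:
            ph = pw = (0, 0)
            xp = x
        cin, b, hp, wp = xp.shape
        ho, wo = hp - kh + 1, wp - kw + 1
        if ho < 1 or wo < 1:
            raise ValueError(f"input too small for kernel {self.kernel}")
        cols = np.empty((cin, kh * kw, b, ho, wo), dtype=xp.dtype)
        for i in range(kh):
            for j in range(kw):
                cols[:, i * kw + j] = xp[:, :, i:i + ho, j:j + wo]
        cols = cols.reshape(cin * kh * kw, b * ho * wo)
        wmat = self.weight.data.reshape(self.out_ch, -1)
        out = (wmat @ cols + self.bias.data[:, None]).reshape(self.out_ch, b, ho, wo)
        self._cache = (cols, xp.shape, ph, pw)
        return out

    def backward(self, grad):
        cols, xp_shape, ph, pw = self._cache
        cin, b, hp, wp = xp_shape
        kh, kw = self.kernel
        ho, wo = hp - kh + 1, wp - kw + 1
        g2 = grad.reshape(self.out_ch, -1)
        self.weight.grad += (g2 @ cols.T).reshape(self.weight.data.shape)
        self.bias.grad += g2.sum(axis=1)
        wmat = self.weight.data.reshape(self.out_ch, -1)
        dcols = (wmat.T @ g2).reshape(cin, kh * kw, b, ho, wo)
        dxp = np.zeros(xp_shape, dtype=grad.dtype)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + ho, j:j + wo] += dcols[:, i * kw + j]
        if self.padding == "same":
            return dxp[:, :, ph[0]:hp - ph[1], pw[0]:wp - pw[1]]
        return dxp


class MaxPool2d(Layer):
    """Non-overlapping max pooling on CBHW arrays; trailing rows/cols that do
    not fill a window are dropped (floor semantics).  Ties route the gradient
    to the first maximal element (argmax convention)."""

    def __init__(self, pool: tuple[int, int]):
        self.pool = pool
        self._cache = None

    def forward(self, x, training=False):
        ph, pw = self.pool
        c, b, h, w = x.shape
        ho, wo = h // ph, w // pw
        xc = np.ascontiguousarray(x[:, :, :ho * ph, :wo * pw])
        if pw == 1:
            # common temporal case: reduce over a single small axis
            blocks = xc.reshape(c, b, ho, ph, wo)
            idx = blocks.argmax(axis=3)
            out = np.take_along_axis(blocks, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        else:
            blocks = np.ascontiguousarray(
                xc.reshape(c, b, ho, ph, wo, pw).transpose(0, 1, 2, 4, 3, 5)
            ).reshape(c, b, ho, wo, ph * pw)
            idx = blocks.argmax(axis=4)
            out = np.take_along_axis(blocks, idx[..., None], axis=4)[..., 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, grad):
        idx, xshape = self._cache
        ph, pw = self.pool
        c, b, h, w = xshape
        ho, wo = h // ph, w // pw
        dx = np.zeros(xshape, dtype=grad.dtype)
        if pw == 1:
            dblocks = dx[:, :, :ho * ph, :wo].reshape(c, b, ho, ph, wo)
            np.put_along_axis(dblocks, idx[:, :, :, None, :],
                              grad[:, :, :, None, :], axis=3)
        else:
            dblocks = np.zeros((c, b, ho, wo, ph * pw), dtype=grad.dtype)
            np.put_along_axis(dblocks, idx[..., None], grad[..., None], axis=4)
            dx[:, :, :ho * ph, :wo * pw] = (
                dblocks.reshape(c, b, ho, wo, ph, pw).transpose(0, 1, 2, 4, 3, 5)
                .reshape(c, b, ho * ph, wo * pw))
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization (CBHW, channel axis 0) with running
    statistics for eval mode."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32, name: str = "bn"):
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(n_ch, dtype=dtype), f"{name}.gamma")
        self.beta = Parameter(np.zeros(n_ch, dtype=dtype), f"{name}.beta")
        self.running_mean = np.zeros(n_ch, dtype=dtype)
        self.running_var = np.ones(n_ch, dtype=dtype)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None, None]) * inv[:, None, None, None]
        out = (self.gamma.data[:, None, None, None] * xhat
               + self.beta.data[:, None, None, None])
        self._cache = (xhat, inv, training, x.shape)
        return out

    def backward(self, grad):
        xhat, inv, training, xshape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += grad.sum(axis=(1, 2, 3))
        g = self.gamma.data[:, None, None, None]
        if not training:
            return grad * g * inv[:, None, None, None]
        n = xshape[1] * xshape[2] * xshape[3]
        dxhat = grad * g
        # standard batch-norm backward, reduced over axes (1, 2, 3)
        t1 = dxhat.sum(axis=(1, 2, 3), keepdims=True)
        t2 = (dxhat * xhat).sum(axis=(1, 2, 3), keepdims=True)
        return (inv[:, None, None, None] / n) * (n * dxhat - t1 - xhat * t2)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    """CBHW -> [batch, C*H*W]; the bridge from conv stacks to dense layers."""

    def forward(self, x, training=False):
        self._shape = x.shape
        c, b, h, w = x.shape
        return np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(b, c * h * w)

    def backward(self, grad):
        c, b, h, w = self._shape
        return np.ascontiguousarray(grad.reshape(b, c, h, w).transpose(1, 0, 2, 3))


class Linear(Layer):
    """Affine map with Xavier-uniform weights."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "fc"):
        bound = np.sqrt(6.0 / (n_in + n_out))
        w = rng.uniform(-bound, bound, size=(n_out, n_in)).astype(dtype)
        self.weight = Parameter(w, f"{name}.weight")
        self.bias = Parameter(np.zeros(n_out, dtype=dtype), f"{name}.bias")
        self._x = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p, self.rng = p, rng
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        return [p for lay in self.layers for p in lay.parameters()]

    def forward(self, x, training=False):
        for lay in self.layers:
            x = lay.forward(x, training=training)
        return x

    def backward(self, grad):
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad
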