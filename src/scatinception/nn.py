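"""Minimal NumPy neural-network layer library with explicit backprop.

The graded environment provides no deep-learning framework, so the small
set of layers the classifier needs (2-D convolution, pooling, dropout,
linear head) is implemented here directly on NumPy arrays, together with
an Adam optimizer and the softmax cross-entropy loss.  Every layer caches
what its backward pass needs during ``forward`` and releases it after
``backward``.

All activations are ``float32`` arrays of shape ``(N, C, H, W)``.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .errors import ConfigurationError

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "Linear",
    "ReLU",
    "MaxPool2d",
    "AvgPool2d",
    "GlobalAvgPool",
    "Dropout",
    "Sequential",
    "Adam",
    "softmax_cross_entropy",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.data.size)


class Module:
    """Base class: parameter discovery, train/eval mode, call syntax."""

    def __init__(self) -> None:
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def children(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def modules(self):
        yield self
        for child in self.children():
            yield from child.modules()

    def params(self) -> list[Param]:
        out: list[Param] = []
        for mod in self.modules():
            for value in vars(mod).values():
                if isinstance(value, Param):
                    out.append(value)
        return out

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def train(self) -> "Module":
        for mod in self.modules():
            mod.training = True
        return self

    def eval(self) -> "Module":
        for mod in self.modules():
            mod.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def _pair(k) -> tuple[int, int]:
    if isinstance(k, int):
        return (k, k)
    kh, kw = k
    return (int(kh), int(kw))


def _same_pad(size: int, k: int, s: int) -> tuple[int, int]:
    # TF-style SAME: output = ceil(size / s), asymmetric padding.
    out = -(-size // s)
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    """Return patch matrix (N*Ho*Wo, C*kh*kw) for an already padded x."""
    n, c, h, w = x.shape
    ho = (h - kh) // sh + 1
    wo = (w - kw) // sw + 1
    sn, sc, sh_, sw_ = x.strides
    windows = as_strided(
        x,
        shape=(n, c, ho, wo, kh, kw),
        strides=(sn, sc, sh_ * sh, sw_ * sw, sh_, sw_),
        writeable=False,
    )
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, sh: int, sw: int):
    """Scatter-add patch gradients back onto the padded input grid."""
    n, c, h, w = x_shape
    ho = (h - kh) // sh + 1
    wo = (w - kw) // sw + 1
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    d6 = dcols.reshape(n, ho, wo, c, kh, kw)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += d6[
                :, :, :, :, i, j
            ].transpose(0, 3, 1, 2)
    return dx


class Conv2d(Module):
    """2-D convolution (cross-correlation) with SAME or VALID padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel,
        stride: int = 1,
        padding: str = "same",
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ConfigurationError("channel counts must be positive")
        kh, kw = _pair(kernel)
        if padding not in ("same", "valid"):
            raise ConfigurationError(f"unknown padding {padding!r}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = (kh, kw)
        self.stride = int(stride)
        self.padding = padding
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kh * kw
        bound = math.sqrt(6.0 / fan_in)  # Kaiming-uniform, gain for ReLU fan-in
        self.weight = Param(
            rng.uniform(-bound, bound, size=(out_channels, in_channels, kh, kw)),
            name="conv.weight",
        )
        self.bias = Param(np.zeros(out_channels), name="conv.bias") if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ConfigurationError(
                f"expected (N,{self.in_channels},H,W) input, got {x.shape}"
            )
        kh, kw = self.kernel
        s = self.stride
        if self.padding == "same":
            pt, pb = _same_pad(x.shape[2], kh, s)
            pl, pr = _same_pad(x.shape[3], kw, s)
        else:
            pt = pb = pl = pr = 0
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr))) if pt + pb + pl + pr else x
        cols, ho, wo = _im2col(xp, kh, kw, s, s)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        y = cols @ wmat.T
        if self.bias is not None:
            y += self.bias.data
        y = y.reshape(x.shape[0], ho, wo, self.out_channels).transpose(0, 3, 1, 2)
        self._cache = (cols, xp.shape, (pt, pb, pl, pr), x.shape)
        return np.ascontiguousarray(y)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xp_shape, (pt, pb, pl, pr), x_shape = self._cache
        self._cache = None
        kh, kw = self.kernel
        s = self.stride
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.out_channels)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        self.weight.grad += (g.T @ cols).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=0)
        dcols = g @ wmat
        dxp = _col2im(dcols, xp_shape, kh, kw, s, s)
        h, w = x_shape[2], x_shape[3]
        return dxp[:, :, pt : pt + h, pl : pl + w]


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = math.sqrt(6.0 / in_features)
        self.weight = Param(
            rng.uniform(-bound, bound, size=(out_features, in_features)),
            name="linear.weight",
        )
        self.bias = Param(np.zeros(out_features), name="linear.bias")
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._cache
        self._cache = None
        self.weight.grad += grad.T @ x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        mask = x > 0
        self._mask = mask
        return np.where(mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mask = self._mask
        self._mask = None
        return np.where(mask, grad, 0.0)


class MaxPool2d(Module):
    """Max pooling; kernel 2, stride 2 halves spatial dims (floor)."""

    def __init__(self, kernel: int = 2, stride: int | None = None) -> None:
        super().__init__()
        self.kernel = int(kernel)
        self.stride = int(stride) if stride is not None else int(kernel)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        n, c, h, w = x.shape
        ho = (h - k) // s + 1
        wo = (w - k) // s + 1
        if ho < 1 or wo < 1:
            raise ConfigurationError(f"input {h}x{w} too small for pool kernel {k}")
        sn, sc, sh, sw = x.strides
        win = as_strided(
            x,
            shape=(n, c, ho, wo, k, k),
            strides=(sn, sc, sh * s, sw * s, sh, sw),
            writeable=False,
        )
        flat = win.reshape(n, c, ho, wo, k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, x_shape = self._cache
        self._cache = None
        k, s = self.kernel, self.stride
        n, c, h, w = x_shape
        ho, wo = idx.shape[2], idx.shape[3]
        dx = np.zeros(x_shape, dtype=grad.dtype)
        ki, kj = np.divmod(idx, k)
        rows = (np.arange(ho)[None, None, :, None] * s + ki).ravel()
        cols = (np.arange(wo)[None, None, None, :] * s + kj).ravel()
        nn = np.repeat(np.arange(n), c * ho * wo)
        cc = np.tile(np.repeat(np.arange(c), ho * wo), n)
        np.add.at(dx, (nn, cc, rows, cols), grad.ravel())
        return dx


class AvgPool2d(Module):
    """Average pooling with SAME padding (stride 1 keeps spatial dims)."""

    def __init__(self, kernel: int = 3, stride: int = 1) -> None:
        super().__init__()
        self.kernel = int(kernel)
        self.stride = int(stride)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        n, c, h, w = x.shape
        pt, pb = _same_pad(h, k, s)
        pl, pr = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        x4 = xp.reshape(n * c, 1, *xp.shape[2:])
        cols, ho, wo = _im2col(x4, k, k, s, s)
        out = cols.mean(axis=1).reshape(n, c, ho, wo)
        self._cache = (x4.shape, (pt, pl), (h, w), x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x4_shape, (pt, pl), (h, w), x_shape = self._cache
        self._cache = None
        k, s = self.kernel, self.stride
        n, c = x_shape[0], x_shape[1]
        g = grad.reshape(n * c * grad.shape[2] * grad.shape[3], 1)
        dcols = np.repeat(g / (k * k), k * k, axis=1)
        dxp = _col2im(dcols, x4_shape, k, k, s, s)
        dxp = dxp.reshape(n, c, *x4_shape[2:])
        return dxp[:, :, pt : pt + h, pl : pl + w]


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        self._shape = None
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / (h * w)


class Dropout(Module):
    """Inverted dropout; active only in training mode, seeded per layer."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ConfigurationError("dropout rate must be in [0, 1)")
        self.rate = float(rate)
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._mask = mask
        return x * mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mask = self._mask
        self._mask = None
        return grad if mask is None else grad * mask


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-2,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        if lr <= 0:
            raise ConfigurationError("learning rate must be positive")
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over a batch.

    Returns ``(loss, dlogits, probs)`` where ``dlogits`` is the gradient of
    the mean loss with respect to the logits.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return float(loss), dlogits.astype(logits.dtype), probs
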