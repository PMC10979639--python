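"""Spatial convolutional attention (SCAT).

The operator learns a per-position attention distribution from a feature
map and reweights the map element-wise: a 1x1 convolution reduces the
channel dimensionality, a second 1x1 convolution produces attention
logits, the logits are softmax-normalized, and the resulting weights are
multiplied into the feature map.

The softmax axis is configurable: ``"spatial"`` (default) normalizes over
the H*W positions of each attention channel, ``"channel"`` normalizes
over channels at each position.  After the softmax the weights are
rescaled by the number of elements on the normalization axis so that a
uniform attention map leaves the input unchanged — this makes the
zero-logit limit an exact identity and keeps activation magnitudes
stable during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError
from .nn import Conv2d, Module, ReLU

__all__ = ["FeatureMap", "ScatParams", "SCAT", "spatial_softmax", "scat_forward"]

#: A feature map is a float array of shape (C, H, W) or batched (N, C, H, W).
FeatureMap = np.ndarray


def validate_feature_map(x: np.ndarray) -> np.ndarray:
    """Coerce to a batched (N, C, H, W) float array, enforcing invariants."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4:
        raise InputError(f"feature map must be (C,H,W) or (N,C,H,W), got {x.shape}")
    if min(x.shape[1:]) < 1:
        raise InputError("channels, height and width must all be >= 1")
    if not np.all(np.isfinite(x)):
        raise InputError("feature map contains non-finite values")
    return x


def spatial_softmax(logits: np.ndarray, axis: str = "spatial") -> np.ndarray:
    """Softmax-normalize attention logits into attention weights.

    For ``axis="spatial"`` the weights of each attention channel sum to 1
    over all height*width positions; for ``axis="channel"`` the weights at
    each position sum to 1 over channels.  The result is invariant to
    adding a constant to all logits on the normalization axis.

    Parameters
    ----------
    logits:
        Array of shape ``(..., C, H, W)`` (at least 3-D).
    """
    logits = np.asarray(logits, dtype=np.float64)
    if logits.ndim < 3:
        raise InputError("logits must have (..., C, H, W) layout")
    if logits.size == 0:
        raise InputError("logits must contain at least one position")
    if not np.all(np.isfinite(logits)):
        raise InputError("logits contain non-finite values")
    if axis == "spatial":
        axes: tuple[int, ...] = (-2, -1)
    elif axis == "channel":
        axes = (-3,)
    else:
        raise ConfigurationError(f"unknown attention axis {axis!r}")
    z = logits - logits.max(axis=axes, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axes, keepdims=True)


@dataclass
class ScatParams:
    """Weights of the two 1x1 convolutions of a SCAT operator.

    ``reduce_weight`` maps ``channels -> reduced``; ``attn_weight`` maps
    ``reduced -> attention channels``.  ``reduced = max(1,
    channels // reduction_ratio)``.
    """

    channels: int
    reduction_ratio: int = 4
    attn_channels: int = 1
    axis: str = "spatial"
    reduce_weight: np.ndarray = field(default=None, repr=False)
    reduce_bias: np.ndarray = field(default=None, repr=False)
    attn_weight: np.ndarray = field(default=None, repr=False)
    attn_bias: np.ndarray = field(default=None, repr=False)

    @property
    def reduced_channels(self) -> int:
        return max(1, self.channels // self.reduction_ratio)


class SCAT(Module):
    """The SCAT attention module with explicit forward/backward passes."""

    def __init__(
        self,
        channels: int,
        reduction_ratio: int = 4,
        attn_channels: int = 1,
        axis: str = "spatial",
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        if channels < 1:
            raise ConfigurationError("channels must be positive")
        if reduction_ratio < 1:
            raise ConfigurationError("reduction_ratio must be a positive integer")
        if axis not in ("spatial", "channel"):
            raise ConfigurationError(f"unknown attention axis {axis!r}")
        self.channels = channels
        self.axis = axis
        reduced = max(1, channels // reduction_ratio)
        n_attn = attn_channels if axis == "spatial" else channels
        self.attn_channels = n_attn
        self.reduce = Conv2d(channels, reduced, 1, rng=rng)
        self.act = ReLU()
        self.attn = Conv2d(reduced, n_attn, 1, rng=rng)
        self._cache = None

    # -- attention -----------------------------------------------------

    def attention(self, x: np.ndarray) -> np.ndarray:
        """Normalized attention weights for ``x`` (no caching)."""
        logits = self.attn.forward(self.act.forward(self.reduce.forward(x)))
        return spatial_softmax(logits, self.axis)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ConfigurationError(
                f"SCAT built for {self.channels} channels, input has {x.shape[1]}"
            )
        logits = self.attn.forward(self.act.forward(self.reduce.forward(x)))
        s = spatial_softmax(logits, self.axis).astype(x.dtype)
        scale = x.shape[2] * x.shape[3] if self.axis == "spatial" else x.shape[1]
        w = scale * s
        self._cache = (x, s, scale)
        return x * w

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, s, scale = self._cache
        self._cache = None
        w = scale * s
        dx = grad * w  # direct branch
        # dL/dw summed over broadcast channels, then through softmax.
        if self.axis == "spatial":
            if s.shape[1] == 1:
                dw = (grad * x).sum(axis=1, keepdims=True)
            else:
                dw = grad * x
            ds = scale * dw
            dot = (ds * s).sum(axis=(2, 3), keepdims=True)
        else:
            dw = grad * x
            ds = scale * dw
            dot = (ds * s).sum(axis=1, keepdims=True)
        dlogits = s * (ds - dot)
        dx += self.reduce.backward(
            self.act.backward(self.attn.backward(dlogits.astype(grad.dtype)))
        )
        return dx

    # -- parameter import/export --------------------------------------

    def export_params(self) -> ScatParams:
        return ScatParams(
            channels=self.channels,
            attn_channels=self.attn_channels,
            axis=self.axis,
            reduce_weight=self.reduce.weight.data.copy(),
            reduce_bias=self.reduce.bias.data.copy(),
            attn_weight=self.attn.weight.data.copy(),
            attn_bias=self.attn.bias.data.copy(),
        )

    def load_params(self, p: ScatParams) -> None:
        self.reduce.weight.data[...] = p.reduce_weight
        self.reduce.bias.data[...] = p.reduce_bias
        self.attn.weight.data[...] = p.attn_weight
        self.attn.bias.data[...] = p.attn_bias


def scat_forward(x: FeatureMap, scat: SCAT) -> FeatureMap:
    """Apply a SCAT operator to a feature map.

    Accepts a single ``(C, H, W)`` map or a batch; the output has exactly
    the input's shape.  Raises :class:`ConfigurationError` on a channel
    mismatch.
    """
    squeeze = np.asarray(x).ndim == 3
    xb = validate_feature_map(x)
    if xb.shape[1] != scat.channels:
        raise ConfigurationError(
            f"feature map has {xb.shape[1]} channels, SCAT expects {scat.channels}"
        )
    y = scat.forward(xb)
    scat._cache = None
    return y[0] if squeeze else y
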