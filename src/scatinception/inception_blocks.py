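"""Inception unit variants: SCAT-A, SCAT-B, C, D, E.

Each unit runs several convolution branches with different kernel menus
in parallel on the same input and concatenates their outputs along the
channel axis.  Variants A and B additionally pass the concatenated map
through a SCAT attention operator.  The internal branch composition
follows the inception-v3 conventions: A/B use 1x1 / small-kernel / 5x5 /
pool-projection branches, C factorizes its kernels into 1x3 followed by
3x1, D is a stride-2 grid-reduction unit, and E is an expanded filter
bank.  Exact per-branch widths are configurable through
:class:`BlockSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .nn import AvgPool2d, Conv2d, MaxPool2d, Module, ReLU, Sequential
from .scat_core import SCAT

__all__ = ["Variant", "BlockSpec", "InceptionBlock", "build_block", "block_forward"]

VARIANTS = ("SCAT_A", "SCAT_B", "C", "D", "E")
SCAT_VARIANTS = ("SCAT_A", "SCAT_B")
#: Variants constrained to the 5-branch width.
FIVE_BRANCH_VARIANTS = ("SCAT_A", "SCAT_B", "C", "E")

Variant = str


def default_branch_channels(variant: Variant, in_channels: int) -> list[int]:
    """Default per-branch widths: each branch ~ in_channels/4."""
    c = max(1, in_channels // 4)
    if variant == "D":
        return [c * 2, c * 2]  # two conv branches; pool branch passes through
    return [c, c, c, c, c]


@dataclass
class BlockSpec:
    """Declarative description of one inception unit."""

    variant: Variant
    in_channels: int
    branch_channels: list[int] | None = None
    reduction_ratio: int = 4
    attn_axis: str = "spatial"
    attn_channels: int = 1

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if self.in_channels < 1:
            raise ConfigurationError("in_channels must be positive")
        if self.branch_channels is None:
            self.branch_channels = default_branch_channels(
                self.variant, self.in_channels
            )
        if any(c < 1 for c in self.branch_channels):
            raise ConfigurationError("branch widths must be positive")
        n = len(self.branch_channels)
        if self.variant in FIVE_BRANCH_VARIANTS and n != 5:
            raise ConfigurationError(
                f"variant {self.variant} requires 5 branches, got {n}"
            )
        if self.variant == "D" and n != 2:
            raise ConfigurationError(
                "variant D takes 2 conv-branch widths (pool branch is implicit)"
            )

    @property
    def has_scat(self) -> bool:
        return self.variant in SCAT_VARIANTS

    @property
    def downsamples(self) -> bool:
        return self.variant == "D"

    @property
    def out_channels(self) -> int:
        extra = self.in_channels if self.variant == "D" else 0  # pool passthrough
        return sum(self.branch_channels) + extra


def _conv(cin: int, cout: int, kernel, rng, stride: int = 1) -> Sequential:
    return Sequential(Conv2d(cin, cout, kernel, stride=stride, rng=rng), ReLU())


def _branches(spec: BlockSpec, rng) -> list[Module]:
    cin = spec.in_channels
    bc = spec.branch_channels
    v = spec.variant
    if v == "SCAT_A":
        return [
            _conv(cin, bc[0], 1, rng),
            Sequential(_conv(cin, bc[1], 1, rng), _conv(bc[1], bc[1], 3, rng)),
            Sequential(_conv(cin, bc[2], 1, rng), _conv(bc[2], bc[2], 5, rng)),
            Sequential(
                _conv(cin, bc[3], 1, rng),
                _conv(bc[3], bc[3], 3, rng),
                _conv(bc[3], bc[3], 3, rng),
            ),
            Sequential(AvgPool2d(3, 1), _conv(cin, bc[4], 1, rng)),
        ]
    if v == "SCAT_B":
        return [
            _conv(cin, bc[0], 1, rng),
            Sequential(_conv(cin, bc[1], 1, rng), _conv(bc[1], bc[1], (1, 3), rng)),
            Sequential(_conv(cin, bc[2], 1, rng), _conv(bc[2], bc[2], (3, 1), rng)),
            Sequential(_conv(cin, bc[3], 1, rng), _conv(bc[3], bc[3], 3, rng)),
            Sequential(AvgPool2d(3, 1), _conv(cin, bc[4], 1, rng)),
        ]
    if v == "C":
        # Asymmetric factorization: n x n realized as 1x3 then 3x1 stacks.
        return [
            _conv(cin, bc[0], 1, rng),
            Sequential(
                _conv(cin, bc[1], 1, rng),
                _conv(bc[1], bc[1], (1, 3), rng),
                _conv(bc[1], bc[1], (3, 1), rng),
            ),
            Sequential(
                _conv(cin, bc[2], 1, rng),
                _conv(bc[2], bc[2], (3, 1), rng),
                _conv(bc[2], bc[2], (1, 3), rng),
            ),
            Sequential(
                _conv(cin, bc[3], 1, rng),
                _conv(bc[3], bc[3], (1, 3), rng),
                _conv(bc[3], bc[3], (3, 1), rng),
                _conv(bc[3], bc[3], (1, 3), rng),
                _conv(bc[3], bc[3], (3, 1), rng),
            ),
            Sequential(AvgPool2d(3, 1), _conv(cin, bc[4], 1, rng)),
        ]
    if v == "D":
        return [
            Sequential(_conv(cin, bc[0], 1, rng), _conv(bc[0], bc[0], 3, rng, stride=2)),
            Sequential(
                _conv(cin, bc[1], 1, rng),
                _conv(bc[1], bc[1], 3, rng),
                _conv(bc[1], bc[1], 3, rng, stride=2),
            ),
            MaxPool2d(2, 2),
        ]
    # E: expanded filter bank
    return [
        _conv(cin, bc[0], 1, rng),
        Sequential(_conv(cin, bc[1], 1, rng), _conv(bc[1], bc[1], (1, 3), rng)),
        Sequential(_conv(cin, bc[2], 1, rng), _conv(bc[2], bc[2], (3, 1), rng)),
        Sequential(_conv(cin, bc[3], 1, rng), _conv(bc[3], bc[3], 5, rng)),
        Sequential(AvgPool2d(3, 1), _conv(cin, bc[4], 1, rng)),
    ]


class InceptionBlock(Module):
    """Parallel branches, channel concatenation, optional SCAT."""

    def __init__(self, spec: BlockSpec, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        self.branches = _branches(spec, rng)
        self.scat: SCAT | None = None
        if spec.has_scat:
            self.scat = SCAT(
                spec.out_channels,
                reduction_ratio=spec.reduction_ratio,
                attn_channels=spec.attn_channels,
                axis=spec.attn_axis,
                rng=rng,
            )
        self._split: list[int] | None = None
        self._crop: tuple[int, int] | None = None

    @property
    def out_channels(self) -> int:
        return self.spec.out_channels

    @property
    def downsamples(self) -> bool:
        return self.spec.downsamples

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.spec.in_channels:
            raise ConfigurationError(
                f"block expects {self.spec.in_channels} channels, got {x.shape[1]}"
            )
        self._crop = None
        if self.downsamples:
            # Crop to even spatial dims so every branch lands on floor(H/2).
            h2, w2 = x.shape[2] // 2 * 2, x.shape[3] // 2 * 2
            if (h2, w2) != x.shape[2:]:
                self._crop = (x.shape[2], x.shape[3])
                x = np.ascontiguousarray(x[:, :, :h2, :w2])
        outs = [b.forward(x) for b in self.branches]
        self._split = [o.shape[1] for o in outs]
        y = np.concatenate(outs, axis=1)
        if self.scat is not None:
            y = self.scat.forward(y)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.scat is not None:
            grad = self.scat.backward(grad)
        edges = np.cumsum(self._split)[:-1]
        parts = np.split(grad, edges, axis=1)
        dx = None
        for branch, g in zip(self.branches, parts):
            d = branch.backward(np.ascontiguousarray(g))
            dx = d if dx is None else dx + d
        if self._crop is not None:
            h, w = self._crop
            full = np.zeros((dx.shape[0], dx.shape[1], h, w), dtype=dx.dtype)
            full[:, :, : dx.shape[2], : dx.shape[3]] = dx
            dx = full
        return dx


def build_block(spec: BlockSpec, rng: np.random.Generator | None = None) -> InceptionBlock:
    """Construct a forward-applicable inception unit from its spec."""
    return InceptionBlock(spec, rng=rng)


def block_forward(block: InceptionBlock, x: np.ndarray) -> np.ndarray:
    """Apply a block to a (N, C, H, W) or (C, H, W) feature map."""
    squeeze = np.asarray(x).ndim == 3
    xb = np.asarray(x, dtype=np.float32)
    if squeeze:
        xb = xb[None]
    y = block.forward(xb)
    return y[0] if squeeze else y
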