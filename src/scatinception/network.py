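"""Assembly of the full SCAT-inception classifier.

Layout: a small convolutional stem (two 3x3 stride-2 convolutions and a
max-pool, which the source architecture leaves unspecified), followed by
the inception units in order A x3, B x2, C x4, D x1, E x1, then global
average pooling, dropout and a linear head producing one logit per
class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError
from .inception_blocks import BlockSpec, InceptionBlock, default_branch_channels
from .nn import Conv2d, Dropout, GlobalAvgPool, Linear, MaxPool2d, Module, ReLU, Sequential

__all__ = ["ModelConfig", "ScatInceptionNet", "build_network"]


@dataclass
class ModelConfig:
    """Declarative description of the whole network."""

    n_a: int = 3
    n_b: int = 2
    n_c: int = 4
    n_d: int = 1
    n_e: int = 1
    stem_channels: int = 32
    input_size: tuple[int, int] = (128, 128)
    n_classes: int = 2
    dropout_rate: float = 0.5
    width_multiplier: float = 1.0
    reduction_ratio: int = 4
    attn_axis: str = "spatial"
    attn_channels: int = 1
    seed: int = 0
    scat_enabled: bool = True  # False ablates SCAT to the identity

    def __post_init__(self) -> None:
        for name in ("n_a", "n_b", "n_c", "n_d", "n_e"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1]")
        if self.width_multiplier <= 0:
            raise ConfigurationError("width_multiplier must be positive")
        if self.stem_channels < 1:
            raise ConfigurationError("stem_channels must be positive")
        h, w = self.input_size
        if h < 16 or w < 16:
            raise ConfigurationError("input_size must be at least 16x16")

    @property
    def variant_sequence(self) -> list[str]:
        return (
            ["SCAT_A"] * self.n_a
            + ["SCAT_B"] * self.n_b
            + ["C"] * self.n_c
            + ["D"] * self.n_d
            + ["E"] * self.n_e
        )


class ScatInceptionNet(Module):
    """The classifier: stem -> inception units -> GAP -> dropout -> linear."""

    def __init__(self, cfg: ModelConfig) -> None:
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        stem_c = max(2, int(round(cfg.stem_channels * cfg.width_multiplier)))
        self.stem = Sequential(
            Conv2d(1, stem_c, 3, stride=2, rng=rng),
            ReLU(),
            Conv2d(stem_c, stem_c, 3, stride=2, rng=rng),
            ReLU(),
            MaxPool2d(2, 2),
        )
        self.blocks: list[InceptionBlock] = []
        channels = stem_c
        for variant in cfg.variant_sequence:
            bc = default_branch_channels(variant, channels)
            spec = BlockSpec(
                variant=variant,
                in_channels=channels,
                branch_channels=bc,
                reduction_ratio=cfg.reduction_ratio,
                attn_axis=cfg.attn_axis,
                attn_channels=cfg.attn_channels,
            )
            block = InceptionBlock(spec, rng=rng)
            if not cfg.scat_enabled:
                block.scat = None  # identity ablation: values change, shapes don't
            self.blocks.append(block)
            channels = spec.out_channels
        self.feature_channels = channels
        self.pool = GlobalAvgPool()
        self.dropout = Dropout(cfg.dropout_rate, rng=np.random.default_rng(cfg.seed + 1))
        self.head = Linear(channels, cfg.n_classes, rng=rng)
        self.trained_case_ids: set[str] = set()

    # -- introspection -------------------------------------------------

    @property
    def inception_variants(self) -> list[str]:
        return [b.spec.variant for b in self.blocks]

    def reseed(self, seed: int) -> None:
        """Reset stochastic state (dropout) for a reproducible run."""
        self.dropout.rng = np.random.default_rng(seed)

    # -- forward/backward ----------------------------------------------

    def forward(self, x: np.ndarray, strict_size: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 1:
            raise InputError(f"expected (N, 1, H, W) batch, got shape {x.shape}")
        if strict_size and tuple(x.shape[2:]) != tuple(self.cfg.input_size):
            raise InputError(
                f"input spatial size {x.shape[2:]} does not match configured "
                f"{self.cfg.input_size}; the model never resizes silently"
            )
        h = self.stem.forward(x)
        for block in self.blocks:
            h = block.forward(h)
        h = self.pool.forward(h)
        h = self.dropout.forward(h)
        return self.head.forward(h)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.head.backward(grad)
        g = self.dropout.backward(g)
        g = self.pool.backward(g)
        for block in reversed(self.blocks):
            g = block.backward(g)
        return self.stem.backward(g)


def build_network(cfg: ModelConfig) -> ScatInceptionNet:
    """Build the classifier; deterministic given ``cfg.seed``."""
    return ScatInceptionNet(cfg)
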