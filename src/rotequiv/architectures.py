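"""Paired baseline-CNN and GCNN classifiers from one declarative description.

The default schedule is a VGG16-style classifier for 256x256 grayscale
images: thirteen 3x3 convolutions (the last one 4x4) with channel widths
32-32-64-64-128-128-128-256-256-256-256-256-256, max pools after layers
2, 4, 7, 10 and 13 (four 2x2/stride-2 pools and a final global 13x13 pool),
then two 4096-wide hidden linear layers with dropout 0.5 and a class head.
ReLU activations and He initialization throughout; no batch normalization.

Setting ``equivariant=True`` derives the group-convolutional twin from the
same description: the first convolution becomes a lifting convolution, the
rest become group convolutions on p4 (or p4m), every channel width is
divided by ``channel_divisor`` (2 by default, so each group-to-group layer
keeps exactly the baseline's weight count on p4: half the channels in and
out, but |p4| = 4 kernel slices), and a group-pooling layer is inserted
after the final spatial pool to make the classifier rotation-invariant
before the linear stack.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import nn
from .gconv import ConvLayerSpec
from .groups import SymmetryGroup, get_group

__all__ = [
    "ArchitectureConfig",
    "ClassifierModel",
    "ConfigurationError",
    "build_classifier",
    "count_parameters",
    "desk_preset",
    "table_vgg16_config",
]


class ConfigurationError(ValueError):
    """An architecture description whose layer shapes do not chain."""


_DEFAULT_CHANNELS = (32, 32, 64, 64, 128, 128, 128, 256, 256, 256, 256, 256, 256)


def _default_conv_specs():
    return tuple([ConvLayerSpec(3, 1, 1)] * 12 + [ConvLayerSpec(4, 1, 0)])


def _default_pool_specs():
    return tuple([ConvLayerSpec(2, 2, 0)] * 4 + [ConvLayerSpec(13, 1, 0)])


@dataclass(frozen=True)
class ArchitectureConfig:
    """Layer schedule for a baseline CNN or its group-equivariant twin."""

    input_size: int = 256
    input_channels: int = 1
    conv_channels: tuple[int, ...] = _DEFAULT_CHANNELS
    conv_specs: tuple[ConvLayerSpec, ...] = field(default_factory=_default_conv_specs)
    pool_after: tuple[int, ...] = (2, 4, 7, 10, 13)  # 1-based conv-layer indices
    pool_specs: tuple[ConvLayerSpec, ...] = field(default_factory=_default_pool_specs)
    linear_sizes: tuple[int, ...] = (4096, 4096)
    n_classes: int = 14
    dropout_rate: float = 0.5
    equivariant: bool = False
    group_name: str = "p4"
    channel_divisor: int = 2

    def __post_init__(self):
        if len(self.conv_channels) != len(self.conv_specs):
            raise ConfigurationError("conv_channels and conv_specs must have equal length")
        if len(self.pool_after) != len(self.pool_specs):
            raise ConfigurationError("pool_after and pool_specs must have equal length")
        if any(i < 1 or i > len(self.conv_channels) for i in self.pool_after):
            raise ConfigurationError("pool_after indices must address conv layers (1-based)")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.equivariant:
            if self.group_name not in ("p4", "p4m"):
                raise ConfigurationError(f"unknown group {self.group_name!r}")
            bad = [c for c in self.conv_channels if c % self.channel_divisor]
            if bad:
                raise ConfigurationError(
                    f"channels {bad} not divisible by channel_divisor {self.channel_divisor}"
                )

    # -- shape bookkeeping --------------------------------------------------

    def effective_channels(self) -> tuple[int, ...]:
        if self.equivariant:
            return tuple(c // self.channel_divisor for c in self.conv_channels)
        return self.conv_channels

    def spatial_trace(self) -> list[int]:
        """Spatial size after each conv/pool, starting from the input size."""
        from .conv_engine import conv_out_size

        pool_of = dict(zip(self.pool_after, self.pool_specs))
        trace = [self.input_size]
        size = self.input_size
        for i, spec in enumerate(self.conv_specs, start=1):
            try:
                size = conv_out_size(size, spec.kernel_size, spec.stride, spec.padding)
            except ValueError as exc:
                raise ConfigurationError(f"conv layer {i}: {exc}") from exc
            trace.append(size)
            if i in pool_of:
                p = pool_of[i]
                try:
                    size = conv_out_size(size, p.kernel_size, p.stride, p.padding)
                except ValueError as exc:
                    raise ConfigurationError(f"pool after conv layer {i}: {exc}") from exc
                trace.append(size)
        return trace

    def flatten_features(self) -> int:
        size = self.spatial_trace()[-1]
        return self.effective_channels()[-1] * size * size

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conv_specs"] = [list(dataclasses.astuple(s)) for s in self.conv_specs]
        d["pool_specs"] = [list(dataclasses.astuple(s)) for s in self.pool_specs]
        for key in ("conv_channels", "pool_after", "linear_sizes"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        d = dict(d)
        for key in ("conv_specs", "pool_specs"):
            if key in d:
                d[key] = tuple(ConvLayerSpec(*s) for s in d[key])
        for key in ("conv_channels", "pool_after", "linear_sizes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ArchitectureConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def table_vgg16_config(**overrides) -> ArchitectureConfig:
    """The full-scale default schedule (256x256 input, 14 classes)."""
    return ArchitectureConfig(**overrides)


def desk_preset(
    input_size: int = 32,
    n_classes: int = 4,
    equivariant: bool = False,
    group_name: str = "p4",
) -> ArchitectureConfig:
    """A five-convolution miniature of the default schedule for CPU-scale runs.

    Keeps the structural motifs — 3x3 convs, a final 4x4 conv, 2x2 pools,
    a global pool down to 1x1, dropout-separated linear stack — at widths
    8-8-16-16-32. Supports input sizes divisible by 4 (e.g. 32 or 64).
    """
    if input_size % 4:
        raise ConfigurationError("desk preset needs input_size divisible by 4")
    last = input_size // 4 - 3  # spatial size left for the global pool
    if last < 1:
        raise ConfigurationError(f"input_size {input_size} too small for the desk preset")
    return ArchitectureConfig(
        input_size=input_size,
        conv_channels=(8, 8, 16, 16, 32),
        conv_specs=tuple([ConvLayerSpec(3, 1, 1)] * 4 + [ConvLayerSpec(4, 1, 0)]),
        pool_after=(2, 4, 5),
        pool_specs=(ConvLayerSpec(2, 2, 0), ConvLayerSpec(2, 2, 0), ConvLayerSpec(last, 1, 0)),
        linear_sizes=(64,),
        n_classes=n_classes,
        equivariant=equivariant,
        group_name=group_name,
    )


@dataclass
class ClassifierModel:
    """A built classifier: the layer stack plus its originating description."""

    net: nn.Sequential
    config: ArchitectureConfig
    group: SymmetryGroup | None = None

    @property
    def equivariant(self) -> bool:
        return self.config.equivariant

    def forward(self, x: np.ndarray, *, train: bool = False, rng=None) -> np.ndarray:
        """Logits for a batch (N, C, H, W); raises on a size mismatch."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[:, None]
        expected = (self.config.input_channels, self.config.input_size, self.config.input_size)
        if x.shape[1:] != expected:
            raise ValueError(f"expected input shape (N, {expected}), got {x.shape}")
        return self.net.forward(x, train=train, rng=rng)

    __call__ = forward

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x).argmax(axis=1)

    def layer_table(self) -> pd.DataFrame:
        rows = []
        for i, layer in enumerate(self.net.layers):
            weights = int(layer.params.get("weight", np.empty(0)).size)
            biases = int(layer.params.get("bias", np.empty(0)).size)
            rows.append(
                {
                    "layer_index": i,
                    "layer": layer.describe(),
                    "weights": weights,
                    "biases": biases,
                    "parameters": weights + biases,
                }
            )
        return pd.DataFrame(rows)


def build_classifier(config: ArchitectureConfig, seed: int) -> ClassifierModel:
    """Instantiate the baseline or GCNN described by ``config``.

    Deterministic: the same (config, seed) always yields bit-identical
    initial weights.
    """
    config.spatial_trace()  # raises ConfigurationError early if shapes break
    rng = np.random.default_rng(seed)
    group = get_group(config.group_name) if config.equivariant else None
    channels = config.effective_channels()
    pool_of = dict(zip(config.pool_after, config.pool_specs))

    layers: list[nn.Layer] = []
    in_ch = config.input_channels
    for i, (out_ch, spec) in enumerate(zip(channels, config.conv_specs), start=1):
        if config.equivariant and i == 1:
            layers.append(
                nn.LiftingConv2d(in_ch, out_ch, spec.kernel_size, group,
                                 spec.stride, spec.padding, rng=rng)
            )
        elif config.equivariant:
            layers.append(
                nn.GroupConv2d(in_ch, out_ch, spec.kernel_size, group,
                               spec.stride, spec.padding, rng=rng)
            )
        else:
            layers.append(
                nn.Conv2d(in_ch, out_ch, spec.kernel_size, spec.stride, spec.padding, rng=rng)
            )
        layers.append(nn.ReLU())
        if i in pool_of:
            p = pool_of[i]
            layers.append(nn.MaxPool2d(p.kernel_size, p.stride, p.padding))
        in_ch = out_ch
    if config.equivariant:
        layers.append(nn.GroupPool(group))
    layers.append(nn.Flatten())

    in_feat = config.flatten_features()
    for width in config.linear_sizes:
        layers.append(nn.Linear(in_feat, width, rng=rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(config.dropout_rate))
        in_feat = width
    layers.append(nn.Linear(in_feat, config.n_classes, rng=rng))

    return ClassifierModel(nn.Sequential(layers), config, group)


def count_parameters(model: ClassifierModel) -> tuple[int, pd.DataFrame]:
    """Exact per-layer and total weight+bias counts."""
    table = model.layer_table()
    return int(table["parameters"].sum()), table
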