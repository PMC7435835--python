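"""The 1D deep CNN apnea classifier: architecture description and builder.

The reference architecture stacks ``n_feature_layers`` identical
feature-extraction blocks — conv(45 filters, kernel 32, 'same' padding) →
batch norm → ReLU → max-pool(2, stride 2) → dropout(0.5) — over a
6000-sample input, flattens, then applies ``n_class_layers`` identical
classification blocks — FC-512 → batch norm → ReLU → dropout(0.5) — and a
2-unit softmax head.  With 10 feature layers the flattened vector has
5*45 = 225 features and the model holds ~1.5 million parameters.

``shape_table`` and ``count_parameters`` are closed-form and independent of
the numerical engine, so the architecture arithmetic can be audited without
building a model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn

__all__ = [
    "ModelConfig", "LayerShape", "ConfigurationError",
    "pooled_length", "shape_table", "count_parameters", "build_model",
    "architecture_descriptor", "save_checkpoint", "load_checkpoint",
]


class ConfigurationError(ValueError):
    """An architecture configuration that cannot produce a valid model."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults are the reference network."""

    n_feature_layers: int = 10
    n_filters: int = 45
    kernel_size: int = 32
    pool_size: int = 2
    pool_stride: int = 2
    dropout_rate: float = 0.5
    n_class_layers: int = 4
    fc_units: int = 512
    n_outputs: int = 2
    input_length: int = 6000
    bn_momentum: float = 0.99
    bn_eps: float = 1e-3

    def __post_init__(self):
        if self.n_feature_layers < 0:
            raise ConfigurationError("n_feature_layers must be >= 0")
        if self.n_feature_layers and self.input_length < 2 ** self.n_feature_layers:
            raise ConfigurationError(
                f"input length {self.input_length} collapses to an empty "
                f"feature map after {self.n_feature_layers} poolings")
        if self.n_filters < 1 or self.kernel_size < 1 or self.n_outputs < 1:
            raise ConfigurationError("filters, kernel and outputs must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must be in [0, 1)")

    @classmethod
    def reduced(cls, **overrides) -> "ModelConfig":
        """A desk-scale configuration for CPU-bound experiments.

        Same block structure as the reference network but 4 feature layers
        of 16 filters and 2 classification layers of 128 units, sized so a
        full training run on a synthetic cohort takes minutes on one core.
        """
        kw = dict(n_feature_layers=4, n_filters=16,
                  n_class_layers=2, fc_units=128)
        kw.update(overrides)
        return cls(**kw)

    @property
    def flatten_width(self) -> int:
        return pooled_length(self.input_length, self.n_feature_layers) * \
            self.n_filters


@dataclass(frozen=True)
class LayerShape:
    """Output shape of one layer: (length, channels) or a flat width."""

    layer_name: str
    length: int
    channels: int

    def __post_init__(self):
        if self.length < 1 or self.channels < 1:
            raise ConfigurationError(
                f"{self.layer_name}: degenerate shape "
                f"({self.length}, {self.channels})")

    @property
    def shape(self) -> tuple:
        return (self.length, self.channels)


def pooled_length(n: int, layers: int) -> int:
    """Length after ``layers`` rounds of pool-2/stride-2 (floor each time)."""
    if n < 1:
        raise ValueError("length must be >= 1")
    if layers < 0:
        raise ValueError("layers must be >= 0")
    for i in range(layers):
        n //= 2
        if n == 0:
            raise ConfigurationError(
                f"feature map empty after {i + 1} pooling layers")
    return n


def shape_table(cfg: ModelConfig) -> list[LayerShape]:
    """Per-layer output shapes, one row per layer as in a model summary."""
    rows = [LayerShape("input", cfg.input_length, 1)]
    length = cfg.input_length
    for i in range(1, cfg.n_feature_layers + 1):
        rows.append(LayerShape(f"conv_{i}", length, cfg.n_filters))
        rows.append(LayerShape(f"batch_norm_{i}", length, cfg.n_filters))
        rows.append(LayerShape(f"activation_{i}", length, cfg.n_filters))
        length //= cfg.pool_size
        if length == 0:
            raise ConfigurationError(f"feature map empty at pooling layer {i}")
        rows.append(LayerShape(f"max_pool_{i}", length, cfg.n_filters))
        rows.append(LayerShape(f"dropout_{i}", length, cfg.n_filters))
    flat = length * (cfg.n_filters if cfg.n_feature_layers else 1)
    rows.append(LayerShape("flatten", flat, 1))
    for j in range(1, cfg.n_class_layers + 1):
        rows.append(LayerShape(f"fc_{j}", cfg.fc_units, 1))
        rows.append(LayerShape(f"fc_batch_norm_{j}", cfg.fc_units, 1))
        rows.append(LayerShape(f"fc_activation_{j}", cfg.fc_units, 1))
        rows.append(LayerShape(f"fc_dropout_{j}", cfg.fc_units, 1))
    rows.append(LayerShape("output", cfg.n_outputs, 1))
    return rows


def count_parameters(cfg: ModelConfig, trainable_only: bool = False) -> int:
    """Closed-form parameter count of the configured architecture.

    Counts convolution weights+biases, batch-normalization parameters
    (scale and shift, plus the moving mean/variance unless
    ``trainable_only``), fully connected weights+biases and the output head.
    """
    bn_per_channel = 2 if trainable_only else 4
    total = 0
    in_ch = 1
    for _ in range(cfg.n_feature_layers):
        total += (cfg.kernel_size * in_ch + 1) * cfg.n_filters
        total += bn_per_channel * cfg.n_filters
        in_ch = cfg.n_filters
    width = cfg.flatten_width if cfg.n_feature_layers else cfg.input_length
    for _ in range(cfg.n_class_layers):
        total += (width + 1) * cfg.fc_units
        total += bn_per_channel * cfg.fc_units
        width = cfg.fc_units
    total += (width + 1) * cfg.n_outputs
    return total


def build_model(cfg: ModelConfig, seed: int, dtype=np.float32) -> nn.Network:
    """Instantiate the network with He-normal weights drawn from ``seed``."""
    if not isinstance(seed, (int, np.integer)):
        raise ConfigurationError(f"seed must be an integer, got {seed!r}")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_ch = 1
    for _ in range(cfg.n_feature_layers):
        layers.append(nn.Conv1D(in_ch, cfg.n_filters, cfg.kernel_size,
                                rng, dtype=dtype))
        layers.append(nn.BatchNorm(cfg.n_filters, cfg.bn_momentum,
                                   cfg.bn_eps, dtype=dtype))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool1D(cfg.pool_size, cfg.pool_stride))
        layers.append(nn.Dropout(cfg.dropout_rate))
        in_ch = cfg.n_filters
    layers.append(nn.Flatten())
    width = cfg.flatten_width if cfg.n_feature_layers else cfg.input_length
    for _ in range(cfg.n_class_layers):
        layers.append(nn.Dense(width, cfg.fc_units, rng, dtype=dtype))
        layers.append(nn.BatchNorm(cfg.fc_units, cfg.bn_momentum,
                                   cfg.bn_eps, dtype=dtype))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(cfg.dropout_rate))
        width = cfg.fc_units
    layers.append(nn.Dense(width, cfg.n_outputs, rng, dtype=dtype))
    return nn.Network(layers)


def architecture_descriptor(cfg: ModelConfig) -> str:
    """Framework-neutral JSON description of the architecture."""
    return json.dumps({
        "config": asdict(cfg),
        "n_parameters": count_parameters(cfg),
        "n_trainable": count_parameters(cfg, trainable_only=True),
        "shapes": [{"layer": r.layer_name, "length": r.length,
                    "channels": r.channels} for r in shape_table(cfg)],
    }, indent=2)


def save_checkpoint(path, cfg: ModelConfig, state: dict) -> None:
    """Write weights (.npz) plus the JSON architecture descriptor."""
    from pathlib import Path
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **state)
    path.with_suffix(".json").write_text(architecture_descriptor(cfg))


def load_checkpoint(path) -> tuple[ModelConfig, dict]:
    """Read a checkpoint written by :func:`save_checkpoint`."""
    from pathlib import Path
    path = Path(path)
    desc = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig(**desc["config"])
    with np.load(path.with_suffix(".npz")) as z:
        state = {k: z[k] for k in z.files}
    return cfg, state
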