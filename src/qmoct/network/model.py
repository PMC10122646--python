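"""The dispersion-profile regression network.

A VGG-style stack of alpha-gated residual convolution blocks over the
depth axis of an FFT stack (the 50 spectral fragments enter as input
channels), followed by a fully connected head with dropout and layer
normalisation and a sigmoid output of one value per depth pixel.  The
default configuration mirrors the full-scale architecture (five blocks,
64..512 filters, 14336 FC units); reduced configurations are used for
desk-scale training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .layers import (
    ConvBlock,
    Dense,
    Dropout,
    Flatten,
    Layer,
    LayerNorm,
    Param,
    Sigmoid,
)

__all__ = ["ModelConfig", "QmRegressor", "build_model", "smoke_config"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``block_filters`` / ``convs_per_block`` describe the convolutional
    blocks (each halves the depth axis by average pooling);
    ``alpha_init`` initialises the learnable residual gate of every block.
    """

    input_channels: int = 50
    input_length: int = 1024
    block_filters: tuple[int, ...] = (64, 128, 256, 512, 512)
    convs_per_block: tuple[int, ...] = (2, 2, 3, 3, 3)
    kernel_size: int = 3
    fc_units: int = 14336
    dropout_rate: float = 0.1
    output_length: int = 1024
    alpha_init: float = 0.5

    def __post_init__(self) -> None:
        if len(self.block_filters) != len(self.convs_per_block):
            raise ValueError("block_filters and convs_per_block lengths differ")
        if self.fc_units <= 0 or self.output_length <= 0:
            raise ValueError("fc_units and output_length must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.input_length % (2 ** len(self.block_filters)):
            raise ValueError(
                "input_length must be divisible by 2^n_blocks for pooling"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        for key in ("block_filters", "convs_per_block"):
            d[key] = tuple(d[key])
        return cls(**d)


def smoke_config() -> ModelConfig:
    """Small configuration for desk-scale (CPU, minutes) training runs."""
    return ModelConfig(
        block_filters=(8, 16),
        convs_per_block=(1, 1),
        kernel_size=5,
        fc_units=64,
        dropout_rate=0.1,
    )


class QmRegressor:
    """FFT stack -> dispersion profile regressor (numpy implementation)."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        self.blocks: list[Layer] = []
        c = config.input_channels
        length = config.input_length
        for filters, n_convs in zip(config.block_filters, config.convs_per_block):
            self.blocks.append(
                ConvBlock(c, filters, n_convs, config.kernel_size, rng,
                          alpha_init=config.alpha_init)
            )
            c = filters
            length //= 2
        self.flatten = Flatten()
        self.fc = Dense(c * length, config.fc_units, rng)
        self.dropout = Dropout(config.dropout_rate, np.random.default_rng(seed + 1))
        self.norm = LayerNorm(config.fc_units)
        self.head = Dense(config.fc_units, config.output_length, rng)
        self.out_act = Sigmoid()
        self._layers: list[Layer] = [
            *self.blocks, self.flatten, self.fc, self.dropout, self.norm,
            self.head, self.out_act,
        ]

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        expected = (self.config.input_channels, self.config.input_length)
        if x.shape[1:] != expected:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model input {expected}"
            )
        for layer in self._layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self._layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self._layers:
            out += layer.params()
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    # -- inference ---------------------------------------------------------
    def predict(self, stacks: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Profiles in (0, 1) for an array of stacks (n, channels, length)."""
        stacks = np.asarray(stacks, dtype=np.float32)
        single = stacks.ndim == 2
        if single:
            stacks = stacks[None]
        out = np.concatenate([
            self.forward(stacks[i: i + batch_size], training=False)
            for i in range(0, len(stacks), batch_size)
        ])
        return out[0] if single else out

    # -- serialisation -----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        i = 0
        for layer in self._layers:
            for bn in _batchnorms(layer):
                state[f"bn_{i}_mean"] = bn.running_mean
                state[f"bn_{i}_var"] = bn.running_var
                i += 1
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            value = np.asarray(state[f"param_{i}"], dtype=np.float32)
            if value.shape != p.value.shape:
                raise ValueError("checkpoint does not match the model architecture")
            p.value = value
            p.grad = np.zeros_like(value)
        i = 0
        for layer in self._layers:
            for bn in _batchnorms(layer):
                bn.running_mean = np.asarray(state[f"bn_{i}_mean"], dtype=np.float32)
                bn.running_var = np.asarray(state[f"bn_{i}_var"], dtype=np.float32)
                i += 1


def _batchnorms(layer: Layer):
    from .layers import BatchNorm1d, ConvBlock

    if isinstance(layer, ConvBlock):
        return [bn for _, bn, _ in layer.stages]
    if isinstance(layer, BatchNorm1d):
        return [layer]
    return []


def build_model(config: ModelConfig | None = None, seed: int = 0) -> QmRegressor:
    """Construct an initialised regressor; same seed, same initial weights."""
    return QmRegressor(config or ModelConfig(), seed=seed)
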