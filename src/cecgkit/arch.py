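"""The 1-D CNN architecture family for cECG classification.

The classifier family is parameterized by depth: 3 to 8 "basic blocks",
each block being convolution -> ReLU -> batch normalization, followed by
a size-2 max-pooling layer.  The first convolution uses filters one
second long (``round(fs * 1 s)`` taps, i.e. 300 at 300 Hz) and every
subsequent convolution halves the filter length, so the filters keep a
constant temporal resolution relative to their (pooled) input.  The
8-block variant is the one exception: the pooling layer after block 7 is
removed and block 8 reuses block 7's filter length, with pooling applied
after block 8 instead.  All convolutions use 10 filters, stride 1 and
length-preserving symmetric padding; the head is flatten -> 20% dropout
-> dense -> softmax.

Sweeping the depth from 3 to 8 therefore yields exactly six variants per
segment length, the model-comparison grid used throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .errors import ConfigurationError, InvalidParameterError

__all__ = [
    "ArchitectureSpec",
    "build_spec",
    "activation",
    "batch_normalize",
    "softmax",
    "build_network",
    "stage_lengths",
]

MIN_BLOCKS, MAX_BLOCKS = 3, 8


@dataclass(frozen=True)
class ArchitectureSpec:
    """Complete structural description of one CNN variant."""

    n_blocks: int
    input_len: int
    fs: float
    n_classes: int
    filters_per_layer: int = 10
    filter_lengths: tuple[int, ...] = ()
    conv_stride: int = 1
    pool_after_block: tuple[bool, ...] = ()
    pool_size: int = 2
    bn_epsilon: float = 1e-3
    bn_momentum: float = 0.9
    dropout_rate: float = 0.2
    activation: str = "relu"

    @property
    def stage_output_lengths(self) -> tuple[int, ...]:
        """Temporal length after each block (convolutions preserve length)."""
        return tuple(stage_lengths(self.input_len, self.pool_after_block, self.pool_size))

    @property
    def flattened_len(self) -> int:
        return self.filters_per_layer * self.stage_output_lengths[-1]

    def n_parameters(self) -> int:
        """Trainable parameter count in closed form.

        Per block: kernel*in_ch*filters + filters (conv) plus 2*filters
        (BN gamma/beta); head: flattened*classes + classes.
        """
        total = 0
        in_ch = 1
        for k in self.filter_lengths:
            total += k * in_ch * self.filters_per_layer + self.filters_per_layer
            total += 2 * self.filters_per_layer
            in_ch = self.filters_per_layer
        total += self.flattened_len * self.n_classes + self.n_classes
        return total

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "ArchitectureSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        d["filter_lengths"] = tuple(d["filter_lengths"])
        d["pool_after_block"] = tuple(d["pool_after_block"])
        return cls(**d)


def stage_lengths(input_len: int, pool_after_block, pool_size: int = 2) -> list[int]:
    """Temporal length after each block's (optional) pooling stage."""
    lengths = []
    cur = input_len
    for pooled in pool_after_block:
        if pooled:
            cur = cur // pool_size
        lengths.append(cur)
    return lengths


def build_spec(n_blocks: int, input_len: int, fs: float, n_classes: int = 3,
               filters_per_layer: int = 10) -> ArchitectureSpec:
    """Build the depth-``n_blocks`` member of the architecture family.

    Filter lengths start at ``round(fs * 1 s)`` and halve (floor) per
    block; pooling follows every block, except that the 8-block variant
    skips the pool after block 7 and repeats block 7's filter length in
    block 8.
    """
    if not MIN_BLOCKS <= n_blocks <= MAX_BLOCKS:
        raise InvalidParameterError(
            f"n_blocks must lie in [{MIN_BLOCKS}, {MAX_BLOCKS}], got {n_blocks}"
        )
    filter_lengths = [int(round(fs))]
    for r in range(1, n_blocks):
        if n_blocks == MAX_BLOCKS and r == MAX_BLOCKS - 1:
            filter_lengths.append(filter_lengths[-1])  # block 8 repeats block 7
        else:
            filter_lengths.append(filter_lengths[-1] // 2)
    pool_after = [True] * n_blocks
    if n_blocks == MAX_BLOCKS:
        pool_after[MAX_BLOCKS - 2] = False  # no pool after block 7

    spec = ArchitectureSpec(
        n_blocks=n_blocks,
        input_len=input_len,
        fs=fs,
        n_classes=n_classes,
        filters_per_layer=filters_per_layer,
        filter_lengths=tuple(filter_lengths),
        pool_after_block=tuple(pool_after),
    )
    if spec.stage_output_lengths[-1] < 1:
        raise ConfigurationError(
            f"input_len {input_len} collapses to zero after {sum(pool_after)} poolings"
        )
    return spec


def activation(x):
    """ReLU activation, max(0, x); idempotent and non-negative."""
    return nn.relu(np.asarray(x))


def batch_normalize(batch: np.ndarray, gamma: float = 1.0, beta: float = 0.0,
                    epsilon: float = 1e-3) -> np.ndarray:
    """Normalize a batch to its own statistics: gamma*(x-mu)/sqrt(var+eps)+beta.

    ``batch`` is an array whose first axis indexes batch members; the
    variance is the biased (population) variance of the whole batch.
    """
    x = np.asarray(batch, dtype=float)
    if x.shape[0] < 2:
        raise InvalidParameterError("batch size must be >= 2")
    if epsilon < 0:
        raise InvalidParameterError("epsilon must be >= 0")
    mu = x.mean()
    var = x.var()
    return gamma * (x - mu) / np.sqrt(var + epsilon) + beta


def softmax(logits) -> np.ndarray:
    """Stable softmax over the last axis; see :func:`cecgkit.nn.softmax`."""
    return nn.softmax(np.asarray(logits, dtype=float), axis=-1)


def build_network(spec: ArchitectureSpec, rng: np.random.Generator,
                  dtype=np.float32) -> nn.Sequential:
    """Instantiate a trainable network from an architecture spec."""
    if spec.conv_stride != 1:
        raise ConfigurationError("only stride-1 convolutions are supported")
    layers: list[nn.Layer] = []
    in_ch = 1
    for r in range(spec.n_blocks):
        conv = nn.Conv1D(in_ch, spec.filters_per_layer, spec.filter_lengths[r],
                         rng=rng, dtype=dtype)
        if r == 0:
            conv.needs_input_grad = False
        layers.append(conv)
        layers.append(nn.ReLU())
        layers.append(nn.BatchNorm(spec.filters_per_layer, epsilon=spec.bn_epsilon,
                                   momentum=spec.bn_momentum, dtype=dtype))
        if spec.pool_after_block[r]:
            layers.append(nn.MaxPool())
        in_ch = spec.filters_per_layer
    layers.append(nn.Flatten())
    layers.append(nn.Dropout(spec.dropout_rate))
    layers.append(nn.Dense(spec.flattened_len, spec.n_classes, rng=rng, dtype=dtype))
    return nn.Sequential(layers, rng=rng)
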