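"""Baseline and compressed 1-D CNN architectures with channel attention.

The baseline network stacks four convolutional layers (60/40/20/10 feature
maps, length-5 kernels, batch norm + activation each), max-pools between the
third and fourth layers, applies dropout on the last convolutional layer and
classifies through a 2-way fully connected head with softmax.  The
compressed variant keeps three smaller layers (20/10/5), pools between the
second and third, and optionally inserts a squeeze–excitation (SE) or
attention-as-activation (ATAC) module on one layer's output (by default the
second).  Compression brings the learnable-parameter count from 17,992 down
to 1,680 (SE) / 1,706 (ATAC) — a ~91% reduction.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _layers as L
from ._layers import activation  # noqa: F401  (re-exported functional op)
from .core import ValidationError

BASELINE_CHANNELS = (60, 40, 20, 10)
COMPRESSED_CHANNELS = (20, 10, 5)

ACTIVATIONS = ("relu", "swish", "sine")
ATTENTIONS = ("none", "se", "atac")


@dataclass
class ConvSpec:
    """Shape contract of one convolutional layer."""

    in_channels: int
    out_channels: int
    filter_length: int = 5
    has_batchnorm: bool = True

    def __post_init__(self) -> None:
        if self.filter_length < 1 or self.out_channels < 1 or self.in_channels < 1:
            raise ValidationError("conv spec dimensions must be >= 1")


@dataclass
class ModelConfig:
    """Full architecture description.

    ``variant`` selects the conv stack (baseline: 60/40/20/10; compressed:
    20/10/5); ``attention`` inserts an SE or ATAC module on the output of the
    1-based ``attention_layer_index``-th conv layer with bottleneck width
    ``floor(C / reduction_ratio)``.  The pool (size 2, stride 2) sits before
    the last conv layer; dropout (0.5) acts on the last conv layer's output.
    """

    variant: str = "compressed"
    activation: str = "relu"
    attention: str = "none"
    attention_layer_index: int = 2
    reduction_ratio: int = 3
    kernel_size: int = 5
    input_length: int = 30
    dropout: float = 0.5
    pool_size: int = 2
    pool_stride: int = 2
    n_classes: int = 2
    conv_channels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("baseline", "compressed"):
            raise ValidationError(f"unknown variant {self.variant!r}")
        if self.activation not in ACTIVATIONS:
            raise ValidationError(f"unknown activation {self.activation!r}")
        if self.attention not in ATTENTIONS:
            raise ValidationError(f"unknown attention {self.attention!r}")
        if self.reduction_ratio < 1:
            raise ValidationError("reduction_ratio must be >= 1")
        if self.conv_channels is not None:
            self.conv_channels = tuple(int(c) for c in self.conv_channels)
        if self.attention != "none" and not (
            1 <= self.attention_layer_index <= len(self.channels)
        ):
            raise ValidationError(
                f"attention_layer_index {self.attention_layer_index} does not address a conv layer"
            )

    @property
    def channels(self) -> tuple[int, ...]:
        if self.conv_channels is not None:
            return self.conv_channels
        return BASELINE_CHANNELS if self.variant == "baseline" else COMPRESSED_CHANNELS

    @property
    def pool_after(self) -> int:
        """1-based index of the conv layer after which pooling is applied."""
        return len(self.channels) - 1

    @property
    def pooled_length(self) -> int:
        return self.input_length // self.pool_stride

    def strip_attention(self) -> "ModelConfig":
        """The ablated twin: identical backbone, no attention module."""
        d = asdict(self)
        d["attention"] = "none"
        return ModelConfig(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["conv_channels"] is not None:
            d["conv_channels"] = list(d["conv_channels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def conv1d_forward(x: np.ndarray, spec: ConvSpec, weights: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """Length-preserving 1-D neural convolution.

    ``y[o, n] = b[o] + sum_c sum_m x[c, n-m] w[o, c, M-1-m]`` with zero
    padding, so output length equals input length.  ``x`` may be ``(C, L)``
    or batched ``(N, C, L)``; ``weights`` is ``(C_out, C_in, M)``.
    """
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (spec.out_channels, spec.in_channels, spec.filter_length):
        raise ValidationError(
            f"weight shape {weights.shape} does not match spec "
            f"({spec.out_channels}, {spec.in_channels}, {spec.filter_length})"
        )
    layer = L.Conv1D(spec.in_channels, spec.out_channels, spec.filter_length)
    layer.w = weights
    layer.b = np.asarray(biases, dtype=np.float64)
    out = layer.forward(x)
    return out[0] if squeeze else out


def se_forward(x: np.ndarray, w1, b1, w2, b2) -> np.ndarray:
    """Squeeze–excitation: per-channel sigmoid gate from global average pooling."""
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    c = x.shape[1]
    w1 = np.asarray(w1, dtype=np.float64).reshape(-1, c)
    layer = L.SEAttention(c, 1)
    layer.hidden = w1.shape[0]
    layer.w1, layer.b1 = w1, np.asarray(b1, dtype=np.float64)
    layer.w2, layer.b2 = np.asarray(w2, dtype=np.float64).reshape(c, -1), np.asarray(b2, dtype=np.float64)
    out = layer.forward(x)
    return out[0] if squeeze else out


def atac_forward(x: np.ndarray, module: L.ATACAttention) -> np.ndarray:
    """Apply an ATAC gating module (inference mode) to a feature map."""
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    out = module.forward(x, training=False)
    return out[0] if squeeze else out


class TrainedModel:
    """A built network: ordered layer stack + config (+ history once fitted).

    ``forward`` returns logits; ``predict_proba`` applies the softmax head.
    ``conv_block_ends`` holds, per conv layer, the index of the last stage of
    its block (after activation and any attention module) — the feature maps
    explainability methods attach to.
    """

    def __init__(self, config: ModelConfig, layers: list[L.Layer], conv_block_ends: list[int]):
        self.config = config
        self.layers = layers
        self.conv_block_ends = conv_block_ends
        self.history = None

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float64)
        if out.ndim == 1:
            out = out[None, None, :]
        elif out.ndim == 2:
            out = out[:, None, :]
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def backward(self, dlogits: np.ndarray, stop_after: int = -1) -> np.ndarray:
        """Backpropagate; returns the gradient w.r.t. the output of layer
        ``stop_after`` (or w.r.t. the network input when ``stop_after`` is -1)."""
        grad = dlogits
        for i in range(len(self.layers) - 1, stop_after, -1):
            grad = self.layers[i].backward(grad)
        return grad

    def forward_from(self, layer_index: int, a: np.ndarray, training: bool = False) -> np.ndarray:
        """Run the tail of the network on a feature map captured at
        ``layer_index`` (exclusive)."""
        out = a
        for layer in self.layers[layer_index + 1 :]:
            out = layer.forward(out, training)
        return out

    def forward_capture(self, x: np.ndarray, layer_index: int, training: bool = False):
        """Forward pass returning ``(logits, feature_map_at_layer_index)``."""
        out = np.asarray(x, dtype=np.float64)
        if out.ndim == 1:
            out = out[None, None, :]
        elif out.ndim == 2:
            out = out[:, None, :]
        captured = None
        for i, layer in enumerate(self.layers):
            out = layer.forward(out, training)
            if i == layer_index:
                captured = out
        return out, captured

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.forward(x, training=False)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    # -- parameter plumbing -------------------------------------------------
    def param_items(self):
        for i, layer in enumerate(self.layers):
            for name in layer.params():
                yield i, name

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def get_flat_params(self) -> np.ndarray:
        return np.concatenate(
            [layer.params()[n].ravel() for i, layer in enumerate(self.layers) for n in layer.params()]
            or [np.empty(0)]
        )

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        """Single-file archive of parameter/buffer arrays plus the JSON config."""
        arrays: dict[str, np.ndarray] = {"__config__": np.array(json.dumps(self.config.to_dict()))}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params().items():
                arrays[f"L{i}:{name}"] = arr
            for name, arr in layer.buffers().items():
                arrays[f"L{i}:buf:{name}"] = arr
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as data:
            cfg = ModelConfig.from_dict(json.loads(str(data["__config__"])))
            model = build_model(cfg, seed=0)
            for i, layer in enumerate(model.layers):
                for name in layer.params():
                    layer.params()[name][...] = data[f"L{i}:{name}"]
                for name in layer.buffers():
                    layer.buffers()[name][...] = data[f"L{i}:buf:{name}"]
        return model


def _make_attention(cfg: ModelConfig, c: int, rng: np.random.Generator) -> L.Layer | None:
    if cfg.attention == "se":
        return L.SEAttention(c, cfg.reduction_ratio, rng)
    if cfg.attention == "atac":
        return L.ATACAttention(c, cfg.reduction_ratio, rng)
    return None


def build_model(cfg: ModelConfig, seed: int = 0) -> TrainedModel:
    """Instantiate the network described by ``cfg`` with seeded Glorot init."""
    rng = np.random.default_rng(seed)
    layers: list[L.Layer] = []
    block_ends: list[int] = []
    channels = cfg.channels
    c_in, length = 1, cfg.input_length
    for idx, c_out in enumerate(channels, start=1):
        layers.append(L.Conv1D(c_in, c_out, cfg.kernel_size, rng))
        layers.append(L.BatchNorm1D(c_out))
        layers.append(L.Activation(cfg.activation))
        if cfg.attention != "none" and idx == cfg.attention_layer_index:
            att = _make_attention(cfg, c_out, rng)
            if att is not None:
                layers.append(att)
        block_ends.append(len(layers) - 1)
        if idx == cfg.pool_after:
            layers.append(L.MaxPool1D(cfg.pool_size, cfg.pool_stride))
            length //= cfg.pool_stride
        if idx == len(channels) and cfg.dropout > 0:
            layers.append(L.Dropout(cfg.dropout))
        c_in = c_out
    layers.append(L.Flatten())
    layers.append(L.Dense(channels[-1] * length, cfg.n_classes, rng))
    model = TrainedModel(cfg, layers, block_ends)
    # dropout gets its own child stream so parameter init is mask-independent
    for layer in layers:
        if isinstance(layer, L.Dropout):
            layer.rng = np.random.default_rng(rng.integers(0, 2**31))
    return model


def count_learnables(cfg: ModelConfig) -> tuple[int, int]:
    """Closed-form learnable-parameter count: ``(exact, truncated_to_hundreds)``.

    Conv layer: ``C_in*M*C + C``; batch norm: ``2C``; fully connected head:
    ``in*out + out``; SE: two biased FC layers through the ``floor(C/r)``
    bottleneck; ATAC: two biased point-wise convs plus their batch norms.
    """
    total = 0
    c_in = 1
    channels = cfg.channels
    for idx, c in enumerate(channels, start=1):
        total += c_in * cfg.kernel_size * c + c  # conv weights + biases
        total += 2 * c  # batch-norm scale + offset
        if cfg.attention != "none" and idx == cfg.attention_layer_index:
            h = max(1, c // cfg.reduction_ratio)
            if cfg.attention == "se":
                total += (c * h + h) + (h * c + c)
            else:  # atac
                total += (c * h + h) + 2 * h  # pw conv 1 + its BN
                total += (h * c + c) + 2 * c  # pw conv 2 + its BN
        c_in = c
    total += channels[-1] * cfg.pooled_length * cfg.n_classes + cfg.n_classes
    return total, 100 * (total // 100)


def compression_percent(compressed_cfg: ModelConfig, baseline_cfg: ModelConfig | None = None) -> float:
    """Parameter reduction of a compressed config relative to the baseline, in %."""
    if baseline_cfg is None:
        baseline_cfg = ModelConfig(variant="baseline", activation=compressed_cfg.activation)
    exact_c, _ = count_learnables(compressed_cfg)
    exact_b, _ = count_learnables(baseline_cfg)
    return 100.0 * (1.0 - exact_c / exact_b)
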