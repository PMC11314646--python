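"""Grad-CAM saliency over RR windows.

Gradient-weighted class activation mapping for 1-D inputs: the gradient of
the target class score with respect to a convolutional layer's feature maps
is averaged over positions to give one weight per channel; the weighted sum
of the maps is rectified, linearly interpolated back to the 30-interval
input grid, and max-normalized to [0, 1].  Alongside it, the first
difference of the RR series gives the natural irregularity trace to compare
the network's focus against.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RRWindow, ValidationError
from .model_zoo import TrainedModel


@dataclass
class SaliencyTrace:
    """Per-interval importance in [0, 1] for one window and target class."""

    importance: np.ndarray  # length = window length, max-normalized
    target_class: int
    conv_layer: int  # 1-based conv-block index the map was taken from

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=np.float64)


def grad_cam(model: TrainedModel, window: RRWindow, target_class: int,
             conv_layer: int | None = None) -> SaliencyTrace:
    """Class-activation saliency for one window.

    ``conv_layer`` is the 1-based conv-block index (default: the final conv
    layer).  The map is computed from the block's output feature maps (after
    activation and any attention module), in inference mode.
    """
    n_blocks = len(model.conv_block_ends)
    if conv_layer is None:
        conv_layer = n_blocks
    if not 1 <= conv_layer <= n_blocks:
        raise ValidationError(f"conv_layer must be in 1..{n_blocks}, got {conv_layer}")
    if target_class not in range(model.config.n_classes):
        raise ValidationError(f"target_class {target_class} out of range")
    capture_idx = model.conv_block_ends[conv_layer - 1]
    x = window.values[None, None, :]
    logits, fmap = model.forward_capture(x, capture_idx, training=False)
    seed = np.zeros_like(logits)
    seed[0, target_class] = 1.0
    grad = model.backward(seed, stop_after=capture_idx)  # d score / d feature map
    weights = grad[0].mean(axis=1)  # (C,) positionwise mean per channel
    cam = np.maximum(weights @ fmap[0], 0.0)  # rectified weighted sum, (L_layer,)
    w = len(window.values)
    if len(cam) != w:
        src = np.linspace(0.0, 1.0, num=len(cam))
        dst = np.linspace(0.0, 1.0, num=w)
        cam = np.interp(dst, src, cam)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return SaliencyTrace(importance=cam, target_class=target_class, conv_layer=conv_layer)


def rr_derivative(window: RRWindow) -> np.ndarray:
    """First difference of the interval series: ``out[i] = v[i+1] - v[i]``."""
    return np.diff(window.values)


def saliency_table(model: TrainedModel, window: RRWindow, target_class: int | None = None
                   ) -> "pd.DataFrame":
    """Per-beat table of (saliency, RR value, RR derivative) for export/plotting."""
    import pandas as pd

    if target_class is None:
        target_class = int(model.predict(window.values[None, None, :])[0])
    trace = grad_cam(model, window, target_class)
    deriv = np.concatenate([rr_derivative(window), [np.nan]])
    return pd.DataFrame({
        "beat_index": np.arange(len(window.values)),
        "saliency": trace.importance,
        "rr_value": window.values,
        "rr_derivative": deriv,
    })


def plot_saliency(model: TrainedModel, window: RRWindow, target_class: int | None = None,
                  ax=None):
    """Optional matplotlib view: RR series colored by saliency plus the derivative."""
    import matplotlib.pyplot as plt

    table = saliency_table(model, window, target_class)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    sc = ax.scatter(table["beat_index"], table["rr_value"], c=table["saliency"],
                    cmap="viridis", vmin=0, vmax=1)
    ax.plot(table["beat_index"], table["rr_value"], lw=0.5, color="gray", alpha=0.6)
    ax.set_xlabel("beat index")
    ax.set_ylabel("RR interval (s)")
    plt.colorbar(sc, ax=ax, label="saliency")
    return ax
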