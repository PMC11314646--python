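"""Synthetic RR-interval window generator.

Emulates the statistical contrast the detector exploits: non-AF rhythm is
regular — a stable mean RR with slow (respiratory-scale) sinusoidal
modulation and small jitter — while AF is irregularly irregular — serially
independent beat-to-beat noise an order of magnitude larger, with occasional
long pauses.  Parameters are loosely physiological (RR in the 0.6–1.0 s
range) but are not fitted to any database; the generator exists to exercise
the pipeline end-to-end with no downloads.

The ``hard`` preset additionally gives 10% of non-AF windows a short
irregular burst, so that a window's overall standard deviation alone no
longer separates the classes — the regime where attention to *where* the
irregularity occurs should pay off.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AF, NON_AF, RRWindow, ValidationError


@dataclass
class SynthConfig:
    """Generator settings; defaults define the package's study conditions."""

    n_windows: int = 1000  # per class
    window_length: int = 30
    # non-AF: regular rhythm
    non_af_mean: float = 0.85  # s
    non_af_sine_amp: float = 0.03  # s, slow modulation amplitude
    non_af_sine_period: float = 12.0  # beats
    non_af_jitter_sd: float = 0.02  # s
    # AF: irregularly irregular
    af_mean: float = 0.70  # s
    af_noise_sd: float = 0.13  # s, serially independent
    af_pause_prob: float = 0.05  # per beat
    af_pause_extra: float = 0.40  # s added on a pause
    # hard preset: fraction of non-AF windows carrying an irregular burst
    burst_fraction: float = 0.10
    burst_length: int = 5  # beats
    noise_multiplier: float = 1.0  # scales all noise terms
    floor: float = 0.25  # s, minimum interval
    seed: int = 0
    windows_per_record: int = 10

    def validate(self) -> None:
        if self.n_windows < 0:
            raise ValidationError("n_windows must be >= 0")
        if self.window_length < 2:
            raise ValidationError("window_length must be >= 2")
        for name in ("non_af_sine_amp", "non_af_jitter_sd", "af_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.af_pause_prob <= 1 or not 0 <= self.burst_fraction <= 1:
            raise ValidationError("probabilities must be in [0, 1]")
        if self.floor <= 0 or self.non_af_mean <= self.floor or self.af_mean <= self.floor:
            raise ValidationError("means must exceed the interval floor")
        if self.noise_multiplier < 0 or self.windows_per_record < 1:
            raise ValidationError("invalid noise_multiplier or windows_per_record")


def _non_af_window(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    w = cfg.window_length
    phase = rng.uniform(0, 2 * np.pi)
    beats = np.arange(w)
    vals = (
        cfg.non_af_mean
        + cfg.non_af_sine_amp * cfg.noise_multiplier * np.sin(2 * np.pi * beats / cfg.non_af_sine_period + phase)
        + rng.normal(0.0, cfg.non_af_jitter_sd * cfg.noise_multiplier, size=w)
    )
    return np.maximum(vals, cfg.floor)


def _af_window(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    w = cfg.window_length
    vals = cfg.af_mean + rng.normal(0.0, cfg.af_noise_sd * cfg.noise_multiplier, size=w)
    pauses = rng.random(w) < cfg.af_pause_prob
    vals[pauses] += cfg.af_pause_extra
    return np.maximum(vals, cfg.floor)


def _emit(values: np.ndarray, label: int, cfg: SynthConfig, k: int) -> RRWindow:
    rec = f"syn{label}{k // cfg.windows_per_record:04d}"
    return RRWindow(values=values, label=label, record_id=rec,
                    window_index=k % cfg.windows_per_record)


def synth_windows(cfg: SynthConfig | None = None, **overrides) -> list[RRWindow]:
    """Generate ``n_windows`` regular (non-AF) and irregular (AF) windows each.

    Deterministic under ``cfg.seed``; all intervals are clipped to the floor
    (0.25 s) so every window satisfies the positivity invariant.
    """
    cfg = _resolve(cfg, overrides)
    rng = np.random.default_rng(cfg.seed)
    out: list[RRWindow] = []
    for k in range(cfg.n_windows):
        out.append(_emit(_non_af_window(cfg, rng), NON_AF, cfg, k))
    for k in range(cfg.n_windows):
        out.append(_emit(_af_window(cfg, rng), AF, cfg, k))
    return out


def synth_hard_preset(cfg: SynthConfig | None = None, **overrides) -> list[RRWindow]:
    """Like :func:`synth_windows`, but a fraction of non-AF windows carry a
    short AF-like burst, defeating plain variance thresholds."""
    cfg = _resolve(cfg, overrides)
    rng = np.random.default_rng(cfg.seed)
    out: list[RRWindow] = []
    n_burst = int(round(cfg.burst_fraction * cfg.n_windows))
    burst_at = set(rng.choice(cfg.n_windows, size=n_burst, replace=False).tolist()) if n_burst else set()
    for k in range(cfg.n_windows):
        vals = _non_af_window(cfg, rng)
        if k in burst_at:
            # the burst is an AF-like run: AF mean + AF noise, with one pause,
            # so the window's overall SD lands in the AF range even though
            # 25 of its 30 intervals are regular
            start = int(rng.integers(0, cfg.window_length - cfg.burst_length + 1))
            burst = cfg.af_mean + rng.normal(0.0, cfg.af_noise_sd * cfg.noise_multiplier,
                                             size=cfg.burst_length)
            burst[rng.integers(0, cfg.burst_length)] += cfg.af_pause_extra
            vals[start : start + cfg.burst_length] = np.maximum(burst, cfg.floor)
        out.append(_emit(vals, NON_AF, cfg, k))
    for k in range(cfg.n_windows):
        out.append(_emit(_af_window(cfg, rng), AF, cfg, k))
    return out


def _resolve(cfg: SynthConfig | None, overrides: dict) -> SynthConfig:
    if cfg is None:
        cfg = SynthConfig(**overrides)
    elif overrides:
        raise ValidationError("pass either a SynthConfig or keyword overrides, not both")
    cfg.validate()
    return cfg


def sd_threshold_accuracy(windows: list[RRWindow]) -> float:
    """Accuracy of the naive detector: AF iff within-window SD exceeds the
    midpoint of the two class-mean SDs.  A reference point showing which
    presets a time-invariant feature can and cannot solve."""
    sds = np.array([w.values.std() for w in windows])
    labels = np.array([w.label for w in windows])
    if labels.min() == labels.max():
        raise ValidationError("need both classes to place a threshold")
    thr = 0.5 * (sds[labels == NON_AF].mean() + sds[labels == AF].mean())
    return float(((sds > thr) == labels).mean())
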