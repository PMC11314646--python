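"""Core domain types shared across the package.

The raw view of an annotated recording is a :class:`BeatSeries` (beat times
plus rhythm segments); the model input is an :class:`RRWindow` of 30
consecutive inter-beat intervals with a binary AF / non-AF label.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: class labels used throughout: 0 = non-AF, 1 = AF
NON_AF = 0
AF = 1
EXCLUDE = "exclude"

#: default model input length (number of intervals per window)
WINDOW_LENGTH = 30


class FormatError(ValueError):
    """Raised when an on-disk resource cannot be decoded."""


class ValidationError(ValueError):
    """Raised when in-memory data violates a structural invariant."""


class BalanceError(ValueError):
    """Raised when class balancing is impossible (a class is absent)."""


@dataclass
class BeatSeries:
    """Beat times and rhythm segments for one record.

    Parameters
    ----------
    record_id : str
        Identifier of the source record.
    sampling_rate : float
        Sampling frequency in Hz; beat times are ``beat_samples / sampling_rate``.
    beat_samples : ndarray of int
        Strictly increasing sample indices of detected beats (R peaks for
        ECG, pulse peaks for PPG).
    rhythm_segments : list of (float, float, str)
        Ordered, non-overlapping ``(start_s, end_s, label)`` half-open time
        intervals carrying the annotator's rhythm label verbatim
        (e.g. ``"(AFIB"``, ``"(N"``).
    """

    record_id: str
    sampling_rate: float
    beat_samples: np.ndarray
    rhythm_segments: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beat_samples = np.asarray(self.beat_samples, dtype=np.int64)
        if self.sampling_rate <= 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.beat_samples.ndim != 1:
            raise ValidationError("beat_samples must be a 1-D index array")
        if len(self.beat_samples) > 1 and np.any(np.diff(self.beat_samples) <= 0):
            raise ValidationError(f"beat samples of record {self.record_id!r} are not strictly increasing")
        prev_end = -np.inf
        for start, end, label in self.rhythm_segments:
            if not start < end:
                raise ValidationError(f"segment {label!r} has start {start} >= end {end}")
            if start < prev_end:
                raise ValidationError(f"segment {label!r} overlaps the previous segment")
            prev_end = end

    @property
    def beat_times(self) -> np.ndarray:
        """Beat times in seconds."""
        return self.beat_samples / self.sampling_rate

    @property
    def n_beats(self) -> int:
        return len(self.beat_samples)


@dataclass(eq=False)
class Episode:
    """A run of consecutive RR intervals under a single rhythm class."""

    record_id: str
    class_label: int  # NON_AF or AF
    intervals: np.ndarray  # seconds, all > 0

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=np.float64)
        if self.intervals.size and np.any(self.intervals <= 0):
            raise ValidationError(f"episode in {self.record_id!r} has non-positive intervals")

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other) -> bool:
        return (isinstance(other, Episode)
                and (self.record_id, self.class_label) == (other.record_id, other.class_label)
                and np.array_equal(self.intervals, other.intervals))


@dataclass(eq=False)
class RRWindow:
    """One fixed-length window of inter-beat intervals with its label."""

    values: np.ndarray  # seconds, length = window length
    label: int  # 0 non-AF, 1 AF
    record_id: str = ""
    window_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValidationError("window values must be 1-D")
        if np.any(self.values <= 0):
            raise ValidationError(
                f"window {self.window_index} of {self.record_id!r} has non-positive intervals"
            )
        if self.label not in (NON_AF, AF):
            raise ValidationError(f"label must be 0 or 1, got {self.label}")

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other) -> bool:
        return (isinstance(other, RRWindow)
                and (self.label, self.record_id, self.window_index)
                == (other.label, other.record_id, other.window_index)
                and np.array_equal(self.values, other.values))


def windows_to_arrays(windows: list[RRWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into ``(X, y)`` with ``X`` of shape ``(n, 1, W)``."""
    if not windows:
        raise ValidationError("empty window list")
    X = np.stack([w.values for w in windows])[:, None, :]
    y = np.array([w.label for w in windows], dtype=np.int64)
    return X, y
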