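"""From annotated beat streams to balanced, labeled 30-interval datasets.

The pipeline: compute RR intervals from beat times; cut them into rhythm
episodes using the annotator's segments (AF vs non-AF, others excluded);
slice each episode into consecutive non-overlapping windows of 30 intervals
(episodes shorter than 30 intervals are excluded); split 76%/24% into train
and test; and balance each side 50/50 by removing the excess from the
larger class.  An interval belongs to an episode only if both of its beats
fall inside one rhythm segment — intervals spanning a segment boundary are
dropped, so no window mixes rhythms.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import AF, EXCLUDE, NON_AF, BalanceError, BeatSeries, Episode, RRWindow, ValidationError

#: default rhythm-label maps; labels carried verbatim from the annotations.
#: AF-database convention: "(N" covers all non-AF rhythms; atrial flutter and
#: junctional rhythm are excluded.
AFDB_CLASS_MAP: dict[str, object] = {"(AFIB": AF, "(N": NON_AF, "(AFL": EXCLUDE, "(J": EXCLUDE}
#: arrhythmia-database convention: only sinus-rhythm and AF episodes are used.
ADB_CLASS_MAP: dict[str, object] = {"(AFIB": AF, "(N": NON_AF}

CLASS_MAPS = {"afdb": AFDB_CLASS_MAP, "adb": ADB_CLASS_MAP}


def rr_from_beats(beat_times: np.ndarray) -> np.ndarray:
    """Consecutive inter-beat differences: ``out[i] = t[i+1] - t[i]``."""
    beat_times = np.asarray(beat_times, dtype=np.float64)
    if beat_times.ndim != 1:
        raise ValidationError("beat_times must be 1-D")
    if len(beat_times) > 1 and np.any(np.diff(beat_times) <= 0):
        raise ValidationError("beat times are not strictly increasing")
    return np.diff(beat_times)


def episodes_from_segments(series: BeatSeries, class_map: dict[str, object]) -> list[Episode]:
    """Cut a record's RR intervals into class-labeled rhythm episodes.

    An interval joins an episode iff both of its beats lie in one segment
    (containment is ``start <= t < end``); segments mapped to ``exclude``
    and labels absent from the map (warned about) yield nothing.
    """
    times = series.beat_times
    episodes: list[Episode] = []
    warned: set[str] = set()
    for start, end, label in series.rhythm_segments:
        if label not in class_map:
            if label not in warned:
                warnings.warn(f"rhythm label {label!r} not in class map; excluding", stacklevel=2)
                warned.add(label)
            continue
        cls = class_map[label]
        if cls == EXCLUDE:
            continue
        inside = np.flatnonzero((times >= start) & (times < end))
        if len(inside) < 2:
            continue
        # beats inside one segment are consecutive; intervals between them
        intervals = np.diff(times[inside])
        episodes.append(Episode(record_id=series.record_id, class_label=int(cls), intervals=intervals))
    return episodes


def windowize(episode: Episode, w: int = 30, stride: int | None = None) -> list[RRWindow]:
    """Consecutive blocks of ``w`` intervals from the episode start.

    The trailing remainder shorter than ``w`` is discarded; an episode with
    fewer than ``w`` intervals yields no windows.  ``stride`` defaults to
    ``w`` (non-overlapping).
    """
    if w < 2:
        raise ValidationError("window length must be >= 2")
    stride = w if stride is None else stride
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    out: list[RRWindow] = []
    vals = episode.intervals
    k = 0
    for start in range(0, len(vals) - w + 1, stride):
        out.append(
            RRWindow(values=vals[start : start + w], label=episode.class_label,
                     record_id=episode.record_id, window_index=k)
        )
        k += 1
    return out


def windows_from_series(series: BeatSeries, class_map: dict[str, object], w: int = 30,
                        stride: int | None = None) -> list[RRWindow]:
    """Episode extraction + windowing for one record, with per-record window numbering."""
    out: list[RRWindow] = []
    for ep in episodes_from_segments(series, class_map):
        for win in windowize(ep, w, stride):
            win.window_index = len(out)
            out.append(win)
    return out


def balance_classes(windows: list[RRWindow], seed: int = 0) -> list[RRWindow]:
    """Equalize class counts by removing a uniform random excess from the larger class.

    Survivors keep their input order; the result has ``min(n0, n1)`` windows
    per class.  Idempotent on balanced input.
    """
    idx0 = [i for i, w in enumerate(windows) if w.label == NON_AF]
    idx1 = [i for i, w in enumerate(windows) if w.label == AF]
    for name, idx in (("non-AF", idx0), ("AF", idx1)):
        if not idx:
            raise BalanceError(f"cannot balance: class {name} is absent")
    n = min(len(idx0), len(idx1))
    rng = np.random.default_rng(seed)
    keep = set(idx0) | set(idx1)
    larger = idx0 if len(idx0) > len(idx1) else idx1
    if len(larger) > n:
        drop = rng.choice(len(larger), size=len(larger) - n, replace=False)
        keep -= {larger[i] for i in drop}
    return [w for i, w in enumerate(windows) if i in keep]


@dataclass
class DatasetSplit:
    """Train/test partition of a window dataset."""

    train: list[RRWindow]
    test: list[RRWindow]
    split_fraction: float
    seed: int
    train_records: list[str] = field(default_factory=list)
    test_records: list[str] = field(default_factory=list)


def split_dataset(windows: list[RRWindow], fraction: float = 0.76, seed: int = 0,
                  by_record: bool = True, balance: bool = True) -> DatasetSplit:
    """Split windows into train/test at ``fraction`` and balance each side.

    With ``by_record`` (the default, preventing within-patient leakage),
    records are shuffled and assigned whole to one side so that the train
    window share is as close as possible to ``fraction``; otherwise windows
    are shuffled individually and cut at ``round(fraction * n)``.
    Balancing (50/50 removal from the larger class) is applied per side
    after splitting unless ``balance`` is False.
    """
    if not 0 < fraction < 1:
        raise ValidationError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if by_record:
        records = sorted({w.record_id for w in windows})
        if len(records) < 2:
            raise ValidationError("record-level splitting needs at least 2 records")
        order = [records[i] for i in rng.permutation(len(records))]
        counts = {r: 0 for r in records}
        for w in windows:
            counts[w.record_id] += 1
        n = len(windows)
        cum = np.cumsum([counts[r] for r in order])
        # prefix of the shuffled records whose window share is closest to fraction
        cut = int(np.argmin(np.abs(cum / n - fraction))) + 1
        cut = min(max(cut, 1), len(order) - 1)  # both sides non-empty
        train_records = set(order[:cut])
        train = [w for w in windows if w.record_id in train_records]
        test = [w for w in windows if w.record_id not in train_records]
        tr_list, te_list = sorted(train_records), sorted(set(order[cut:]))
    else:
        perm = rng.permutation(len(windows))
        cut = int(round(fraction * len(windows)))
        train_idx = set(perm[:cut].tolist())
        train = [w for i, w in enumerate(windows) if i in train_idx]
        test = [w for i, w in enumerate(windows) if i not in train_idx]
        tr_list = sorted({w.record_id for w in train})
        te_list = sorted({w.record_id for w in test})
    if balance:
        train = balance_classes(train, seed=seed)
        test = balance_classes(test, seed=seed + 1)
    return DatasetSplit(train=train, test=test, split_fraction=fraction, seed=seed,
                        train_records=tr_list, test_records=te_list)
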