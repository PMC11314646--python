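"""Windowing, episode extraction, balancing and splitting rules."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attnaf.core import AF, EXCLUDE, NON_AF, BalanceError, BeatSeries, Episode, ValidationError
from attnaf.preprocess import (AFDB_CLASS_MAP, balance_classes, episodes_from_segments,
                               rr_from_beats, split_dataset, windowize)
from conftest import make_window


# -- rr_from_beats -----------------------------------------------------------

def test_single_beat_yields_no_intervals():
    assert rr_from_beats(np.array([0.0])).size == 0
    assert rr_from_beats(np.array([])).size == 0


def test_uniform_beats():
    assert np.allclose(rr_from_beats(np.array([0.0, 1.0, 2.0, 3.0])), [1, 1, 1])


def test_intervals_from_samples():
    times = np.array([100, 300, 550]) / 250.0
    assert np.allclose(rr_from_beats(times), [0.8, 1.0])


def test_non_increasing_beats_rejected():
    with pytest.raises(ValidationError):
        rr_from_beats(np.array([0.0, 1.0, 1.0]))


# -- episodes_from_segments --------------------------------------------------

def _series(beat_times, segments, fs=250.0):
    return BeatSeries("t", fs, np.round(np.asarray(beat_times) * fs).astype(np.int64), segments)


def test_single_segment_episode():
    times = 0.8 * np.arange(1, 41)
    series = _series(times, [(0.0, 40.0, "(AFIB")])
    (ep,) = episodes_from_segments(series, AFDB_CLASS_MAP)
    assert ep.class_label == AF
    assert len(ep) == 39


def test_boundary_interval_dropped():
    # beats 1..6 in an AF segment, beats 7..12 in a non-AF segment
    times = np.arange(1, 13, dtype=float)
    series = _series(times, [(0.5, 6.5, "(AFIB"), (6.5, 12.5, "(N")])
    eps = episodes_from_segments(series, AFDB_CLASS_MAP)
    assert [(e.class_label, len(e)) for e in eps] == [(AF, 5), (NON_AF, 5)]
    # conservation: drops only at the boundary
    assert sum(len(e) for e in eps) == series.n_beats - 2


def test_excluded_rhythms_yield_no_episode():
    times = np.arange(1, 41, dtype=float)
    series = _series(times, [(0.0, 41.0, "(AFL")])
    assert episodes_from_segments(series, AFDB_CLASS_MAP) == []


def test_unmapped_label_warns_and_excludes():
    times = np.arange(1, 41, dtype=float)
    series = _series(times, [(0.0, 41.0, "(SBR")])
    with pytest.warns(UserWarning, match=r"\(SBR"):
        assert episodes_from_segments(series, AFDB_CLASS_MAP) == []


def test_interval_conservation_on_random_segmentations(rng):
    """Total intervals across episodes never exceeds n_beats - 1."""
    for _ in range(20):
        n = int(rng.integers(2, 120))
        times = np.cumsum(rng.uniform(0.4, 1.2, size=n))
        cuts = np.sort(rng.uniform(0, times[-1] + 1, size=int(rng.integers(1, 5))))
        bounds = np.concatenate([[0.0], cuts, [times[-1] + 1]])
        labels = ["(AFIB", "(N", "(AFL"]
        segments = [(bounds[i], bounds[i + 1], labels[i % 3])
                    for i in range(len(bounds) - 1) if bounds[i] < bounds[i + 1]]
        eps = episodes_from_segments(BeatSeries("f", 1.0, np.round(times * 1000).astype(int),
                                                [(s * 1000, e * 1000, l) for s, e, l in segments]),
                                     AFDB_CLASS_MAP)
        assert sum(len(e) for e in eps) <= n - 1


# -- windowize ---------------------------------------------------------------

def _episode(n, label=AF):
    return Episode("e", label, np.full(n, 0.8))


def test_short_episode_excluded():
    assert windowize(_episode(29)) == []


def test_exact_length_episode_one_window():
    (w,) = windowize(_episode(30))
    assert len(w) == 30
    assert w.label == AF


def test_remainder_discarded():
    eps = Episode("e", NON_AF, np.linspace(0.5, 1.5, 95))
    wins = windowize(eps)
    assert len(wins) == 3
    assert np.array_equal(wins[0].values, eps.intervals[:30])
    assert np.array_equal(wins[2].values, eps.intervals[60:90])


@settings(deadline=None, derandomize=True, max_examples=60)
@given(n=st.integers(min_value=0, max_value=500), w=st.integers(min_value=2, max_value=60))
def test_window_count_is_floor_n_over_w(n, w):
    assert len(windowize(_episode(max(n, 0)), w=w)) == n // w


# -- balance_classes ---------------------------------------------------------

def test_balanced_input_unchanged(uniform_windows):
    assert balance_classes(uniform_windows, seed=0) == uniform_windows


def test_excess_removed_from_larger_class():
    wins = [make_window([0.8] * 30, label=AF, window_index=i) for i in range(8)]
    wins += [make_window([0.9] * 30, label=NON_AF, window_index=i) for i in range(5)]
    out = balance_classes(wins, seed=3)
    labels = [w.label for w in out]
    assert labels.count(AF) == labels.count(NON_AF) == 5
    # survivor order preserved
    af_idx = [w.window_index for w in out if w.label == AF]
    assert af_idx == sorted(af_idx)


def test_missing_class_raises():
    wins = [make_window([0.8] * 30, label=AF) for _ in range(3)]
    with pytest.raises(BalanceError, match="non-AF"):
        balance_classes(wins, seed=0)


def test_balance_size_and_idempotence(rng):
    for _ in range(10):
        n0, n1 = int(rng.integers(1, 40)), int(rng.integers(1, 40))
        wins = [make_window([0.8] * 30, label=NON_AF, window_index=i) for i in range(n0)]
        wins += [make_window([0.7] * 30, label=AF, window_index=i) for i in range(n1)]
        out = balance_classes(wins, seed=int(rng.integers(1 << 30)))
        assert len(out) == 2 * min(n0, n1)
        assert balance_classes(out, seed=0) == out


# -- split_dataset -----------------------------------------------------------

def _one_window_per_record(n=100):
    out = []
    for i in range(n):
        out.append(make_window([0.8] * 30, label=i % 2, record_id=f"r{i:03d}"))
    return out


def test_76_24_split_with_one_record_per_window():
    split = split_dataset(_one_window_per_record(100), fraction=0.76, seed=0,
                          by_record=True, balance=False)
    assert len(split.train) == 76
    assert len(split.test) == 24


def test_two_records_half_split():
    wins = [make_window([0.8] * 30, label=k, record_id=r)
            for r in ("a", "b") for k in (0, 1)]
    split = split_dataset(wins, fraction=0.5, seed=1, by_record=True)
    assert split.train_records != split.test_records
    assert len(split.train_records) == len(split.test_records) == 1


def test_record_split_disjoint_over_seeds():
    wins = _one_window_per_record(40)
    for seed in range(100):
        split = split_dataset(wins, seed=seed, by_record=True, balance=False)
        assert not set(split.train_records) & set(split.test_records)
        assert len(split.train) + len(split.test) == len(wins)


def test_window_split_partitions_input():
    wins = _one_window_per_record(37)
    split = split_dataset(wins, fraction=0.76, seed=5, by_record=False, balance=False)
    assert len(split.train) == round(0.76 * 37)
    ids = sorted((w.record_id, w.window_index) for w in split.train + split.test)
    assert ids == sorted((w.record_id, w.window_index) for w in wins)


def test_split_sides_are_balanced():
    wins = _one_window_per_record(100)
    # skew the labels: 70 non-AF, 30 AF
    for i, w in enumerate(wins):
        w.label = NON_AF if i < 70 else AF
    split = split_dataset(wins, seed=2, by_record=True, balance=True)
    for side in (split.train, split.test):
        labels = [w.label for w in side]
        assert labels.count(AF) == labels.count(NON_AF)


def test_bad_fraction_and_too_few_records():
    wins = _one_window_per_record(4)
    with pytest.raises(ValidationError):
        split_dataset(wins, fraction=1.5)
    solo = [make_window([0.8] * 30, label=0, record_id="only") for _ in range(4)]
    with pytest.raises(ValidationError):
        split_dataset(solo, by_record=True)
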