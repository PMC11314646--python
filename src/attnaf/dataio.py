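"""Reading and writing beat annotations, window tables and checkpoints.

Beat/rhythm annotations use the MIT (WFDB) annotation file format — the
format of PhysioNet ``.atr`` files: a stream of 16-bit little-endian words,
each carrying a 6-bit annotation code and a 10-bit time increment in
samples, with SKIP escapes for long gaps and AUX words carrying rhythm
strings such as ``"(AFIB"``.  The subset implemented here (beat codes,
rhythm marks, SKIP/NUM/SUB/CHN, AUX, EOF) is what beat-interval analysis
needs; a writer producing the same subset supports synthetic fixtures.

Window tables are plain delimited text with a one-line header
(``record_id,window_index,label,i01..i30``), written with 12 significant
digits so a round-trip is lossless to well below 1e-9 seconds.
"""
from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AF, NON_AF, BeatSeries, FormatError, RRWindow, ValidationError
from .model_zoo import TrainedModel

# MIT annotation pseudo-codes
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63
_RHYTHM = 28  # '+' rhythm change, aux holds the label

#: standard WFDB beat annotation codes (NORMAL, LBBB, RBBB, PVC, APC, ...)
BEAT_CODES = frozenset({1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 35, 38})


def _parse_annotation_stream(raw: bytes) -> list[tuple[int, int, str | None]]:
    """Decode (sample, code, aux) triples from an MIT annotation byte stream."""
    if len(raw) % 2:
        raise FormatError("annotation stream has odd byte length")
    events: list[tuple[int, int, str | None]] = []
    t = 0
    i = 0
    pending_skip = 0
    saw_eof = False
    while i + 2 <= len(raw):
        (word,) = struct.unpack_from("<H", raw, i)
        i += 2
        code, tfield = word >> 10, word & 0x3FF
        if word == 0:
            saw_eof = True
            break
        if code == _SKIP:
            if i + 4 > len(raw):
                raise FormatError("truncated SKIP escape")
            hi, lo = struct.unpack_from("<HH", raw, i)
            i += 4
            skip = (hi << 16) | lo
            if skip >= 1 << 31:  # sign-extend 32-bit
                skip -= 1 << 32
            pending_skip += skip
        elif code == _AUX:
            if i + tfield > len(raw):
                raise FormatError("truncated AUX data")
            aux = raw[i : i + tfield].rstrip(b"\x00").decode("latin-1")
            i += tfield + (tfield & 1)  # aux data is null-padded to even length
            if not events:
                raise FormatError("AUX word with no preceding annotation")
            s, c, _ = events[-1]
            events[-1] = (s, c, aux)
        elif code in (_NUM, _SUB, _CHN):
            continue  # field modifiers; no time advance
        else:
            t += tfield + pending_skip
            pending_skip = 0
            events.append((t, code, None))
    if not saw_eof:
        raise FormatError("annotation stream ends without EOF word")
    return events


def read_beat_annotations(path, sampling_rate: float) -> BeatSeries:
    """Read an MIT-format annotation file into a :class:`BeatSeries`.

    Beat times are ``sample_index / sampling_rate``.  Rhythm segments are
    reconstructed from rhythm-change marks: each label holds from its mark
    until the next mark (half-open), the last until just past the final
    annotation.
    """
    path = Path(path)
    events = _parse_annotation_stream(path.read_bytes())
    beats = [s for s, code, _ in events if code in BEAT_CODES]
    marks = [(s, aux) for s, code, aux in events if code == _RHYTHM and aux]
    segments: list[tuple[float, float, str]] = []
    if marks:
        end_sample = max(s for s, _, _ in events) + 1
        bounds = [s for s, _ in marks] + [end_sample]
        for (s, aux), nxt in zip(marks, bounds[1:]):
            if nxt > s:
                segments.append((s / sampling_rate, nxt / sampling_rate, aux))
    return BeatSeries(
        record_id=path.stem,
        sampling_rate=sampling_rate,
        beat_samples=np.asarray(beats, dtype=np.int64),
        rhythm_segments=segments,
    )


def write_beat_annotations(series: BeatSeries, path, beat_code: int = 1) -> None:
    """Write a :class:`BeatSeries` as an MIT-format annotation file."""
    fs = series.sampling_rate
    items: list[tuple[int, int, int, str | None]] = []  # (sample, order, code, aux)
    for start, _end, label in series.rhythm_segments:
        items.append((int(round(start * fs)), 0, _RHYTHM, label))
    for s in series.beat_samples:
        items.append((int(s), 1, beat_code, None))
    items.sort(key=lambda it: (it[0], it[1]))
    out = bytearray()
    prev = 0
    for sample, _order, code, aux in items:
        delta = sample - prev
        prev = sample
        if not 0 <= delta <= 1023:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
        if aux is not None:
            data = aux.encode("latin-1")
            out += struct.pack("<H", (_AUX << 10) | len(data))
            out += data
            if len(data) & 1:
                out += b"\x00"
    out += struct.pack("<H", 0)  # EOF
    Path(path).write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# window tables

def _interval_columns(width: int) -> list[str]:
    return [f"i{k:02d}" for k in range(1, width + 1)]


def write_window_table(windows: list[RRWindow], path, window_length: int = 30) -> None:
    """Write labeled windows as delimited text with a one-line header."""
    if windows:
        width = len(windows[0].values)
        for k, w in enumerate(windows):
            if len(w.values) != width:
                raise ValidationError(f"row {k} has {len(w.values)} values, expected {width}")
    else:
        width = window_length
    cols = _interval_columns(width)
    frame = pd.DataFrame(
        [
            {"record_id": w.record_id, "window_index": w.window_index, "label": w.label,
             **dict(zip(cols, w.values))}
            for w in windows
        ],
        columns=["record_id", "window_index", "label", *cols],
    )
    frame.to_csv(path, index=False, float_format="%.12g")


def read_window_table(path) -> list[RRWindow]:
    """Read a window table written by :func:`write_window_table`."""
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse window table {path}: {exc}") from exc
    cols = [c for c in frame.columns if c.startswith("i") and c[1:].isdigit()]
    required = {"record_id", "window_index", "label"}
    if not required.issubset(frame.columns) or not cols:
        raise FormatError(f"window table {path} is missing required columns")
    windows: list[RRWindow] = []
    for k, row in frame.iterrows():
        values = row[cols].to_numpy(dtype=np.float64)
        if np.any(~np.isfinite(values)):
            raise ValidationError(f"row {k} has missing or non-finite interval values")
        label = int(row["label"])
        if label not in (NON_AF, AF):
            raise ValidationError(f"row {k} has label {label}, expected 0 or 1")
        windows.append(
            RRWindow(values=values, label=label,
                     record_id=str(row["record_id"]), window_index=int(row["window_index"]))
        )
    return windows


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model: TrainedModel, path) -> None:
    """Single-file archive of parameter arrays plus the JSON model config."""
    model.save(path)


def load_checkpoint(path) -> TrainedModel:
    return TrainedModel.load(path)
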