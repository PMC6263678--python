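"""Readers and writers for WAV audio and intensity-sequence CSV datasets.

The canonical on-disk form of a labeled dataset is a long-format CSV with
header ``event_id,label,index,volts`` (one row per intensity sample).  A
wide dialect — ``event_id,label,v0,v1,...`` with ragged rows — is accepted
on read only.  CSV round-trips are lossless: volts are written with
shortest-round-trip precision.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .datamodel import (
    CLASS_NAMES,
    SENSOR_RATE_HZ,
    FormatError,
    IntensitySequence,
    LabeledDataset,
    LengthStats,
    LengthSummary,
    ValidationError,
    Waveform,
)

_LONG_HEADER = ["event_id", "label", "index", "volts"]

# peak amplitude per integer PCM dtype (two's complement full scale)
_PCM_SCALE = {np.dtype("int16"): 32768.0, np.dtype("int32"): 2147483648.0}


def read_wav(path: str | Path) -> Waveform:
    """Read a PCM WAV file as a mono :class:`Waveform` in [-1, 1].

    Multi-channel audio is averaged to mono.  The header-declared sample
    rate is authoritative.  Unreadable, compressed or non-WAV files raise
    :class:`FormatError` naming the path.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises ValueError for non-PCM/non-WAV
        raise FormatError(f"cannot read {path} as PCM WAV: {exc}") from exc
    data = np.atleast_1d(data)
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        samples = (data.astype(float) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(float) / _PCM_SCALE[data.dtype]
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(float)
    else:
        raise FormatError(f"cannot read {path}: unsupported sample dtype {data.dtype}")
    if samples.ndim > 1:
        samples = samples.mean(axis=1)
    samples = np.clip(samples, -1.0, 1.0)
    return Waveform(samples=samples, sample_rate=int(rate), source_id=path.stem)


def write_wav(wave: Waveform, path: str | Path) -> Path:
    """Write a waveform as 16-bit PCM WAV (utility for tests and synthesis)."""
    path = Path(path)
    pcm = np.clip(np.round(wave.samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, wave.sample_rate, pcm)
    return path


def _validate_volts(value: float, row_num: int) -> float:
    if not (0.0 <= value <= 5.0):
        raise ValidationError(
            f"row {row_num}: intensity {value} outside the 0-5 V sensor range"
        )
    return value


def read_intensity_csv(path: str | Path,
                       rate_hz: float = SENSOR_RATE_HZ) -> LabeledDataset:
    """Read a labeled dataset from CSV (long canonical or wide dialect).

    Values outside [0, 5] or unknown labels raise :class:`ValidationError`
    with the offending row number.  Event order and within-event value
    order follow the file.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a CSV header")
        header = [h.strip().lower() for h in header]
        if header[:4] == _LONG_HEADER:
            return _read_long(reader, path, rate_hz)
        if header[:2] == ["event_id", "label"]:
            return _read_wide(reader, path, rate_hz)
        raise FormatError(
            f"{path}: unrecognized header {header!r}; expected "
            f"'event_id,label,index,volts' (long) or 'event_id,label,...' (wide)"
        )


def _read_long(reader, path: Path, rate_hz: float) -> LabeledDataset:
    order: list[str] = []
    values: dict[str, list[float]] = {}
    labels: dict[str, str] = {}
    for row_num, row in enumerate(reader, start=2):
        if not row:
            continue
        try:
            event_id, label, _index, volts = row[0], row[1], int(row[2]), float(row[3])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path} row {row_num}: malformed row {row!r}") from exc
        label = label.strip().lower()
        if label not in CLASS_NAMES:
            raise ValidationError(
                f"{path} row {row_num}: unknown label {label!r}"
            )
        _validate_volts(volts, row_num)
        if event_id not in values:
            order.append(event_id)
            values[event_id] = []
            labels[event_id] = label
        values[event_id].append(volts)
    seqs = [
        IntensitySequence(values=np.array(values[eid]), rate_hz=rate_hz,
                          label=labels[eid], event_id=eid)
        for eid in order
    ]
    return LabeledDataset(sequences=seqs)


def _read_wide(reader, path: Path, rate_hz: float) -> LabeledDataset:
    seqs = []
    for row_num, row in enumerate(reader, start=2):
        if not row:
            continue
        event_id, label = row[0], row[1].strip().lower()
        if label not in CLASS_NAMES:
            raise ValidationError(f"{path} row {row_num}: unknown label {label!r}")
        vals = [_validate_volts(float(v), row_num) for v in row[2:] if v != ""]
        seqs.append(IntensitySequence(values=np.array(vals), rate_hz=rate_hz,
                                      label=label, event_id=event_id))
    return LabeledDataset(sequences=seqs)


def write_intensity_csv(dataset: LabeledDataset, path: str | Path) -> Path:
    """Write a dataset in the canonical long CSV format (lossless)."""
    if len(dataset) == 0:
        raise ValidationError("refusing to write an empty dataset")
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LONG_HEADER)
        for seq in dataset:
            for i, v in enumerate(seq.values):
                writer.writerow([seq.event_id, seq.label, i, repr(float(v))])
    return path


def summarize_lengths(dataset: LabeledDataset) -> LengthSummary:
    """Per-class min/max/mean/median of event lengths (sample counts).

    Median of an even count is the mean of the two central values.  A class
    with no events maps to ``None`` in the summary.
    """
    if len(dataset) == 0:
        raise ValidationError("cannot summarize an empty dataset")
    per_class: dict[str, LengthStats | None] = {}
    for name, group in dataset.by_class().items():
        if not group:
            per_class[name] = None
            continue
        lengths = np.array([len(s) for s in group])
        per_class[name] = LengthStats(
            minimum=int(lengths.min()),
            maximum=int(lengths.max()),
            mean=float(lengths.mean()),
            median=float(np.median(lengths)),
        )
    return LengthSummary(per_class=per_class)


def split_dataset(dataset: LabeledDataset, train_fraction: float,
                  seed: int) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified, seeded train/test split.

    Per class, ``round(train_fraction * count)`` events go to the training
    set after a seeded shuffle.  The two halves are disjoint and exhaustive;
    the same seed always yields the same membership.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train: list[IntensitySequence] = []
    test: list[IntensitySequence] = []
    for name, group in dataset.by_class().items():
        if not group:
            continue
        if len(group) < 2:
            raise ValidationError(
                f"class {name!r} has fewer than 2 events; cannot stratify"
            )
        idx = rng.permutation(len(group))
        n_train = int(round(train_fraction * len(group)))
        n_train = min(max(n_train, 1), len(group) - 1)  # both halves non-empty
        chosen = set(idx[:n_train].tolist())
        for i, seq in enumerate(group):
            (train if i in chosen else test).append(seq)
    return (
        LabeledDataset(train, dataset.class_names, split_seed=seed),
        LabeledDataset(test, dataset.class_names, split_seed=seed),
    )


def length_summary_to_csv(summary: LengthSummary, path: str | Path) -> Path:
    """Export a length summary as CSV (class, minimum, maximum, mean, median)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["class", "minimum", "maximum", "mean", "median"])
        writer.writeheader()
        for row in summary.to_rows():
            writer.writerow(row)
    return path
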