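"""Core domain types for intensity-based vocalization analysis.

The pipeline revolves around two representations of a single vocalization
event: a :class:`Waveform` (PCM audio, amplitudes in [-1, 1]) and an
:class:`IntensitySequence` (the noise sensor's per-frame peak-to-peak output
in volts, 0-5 V at a nominal 138 frames per second).  Events carry one of
four class labels: barking, growling, howling, whining.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical class order used everywhere a class index is needed.
CLASS_NAMES: tuple[str, ...] = ("barking", "growling", "howling", "whining")

#: Nominal sensor output rate, frames (intensity samples) per second.
SENSOR_RATE_HZ: float = 138.0

#: Sensor voltage range (GND to VCC).
V_MIN, V_MAX = 0.0, 5.0


class BarklineError(Exception):
    """Base class for errors raised by this package."""


class FormatError(BarklineError):
    """An input file could not be parsed in the expected format."""


class ValidationError(BarklineError):
    """Input data violates a domain invariant (range, label, shape)."""


@dataclass(frozen=True)
class Waveform:
    """A mono PCM audio clip with amplitudes normalized to [-1, 1].

    Parameters
    ----------
    samples
        Amplitude sequence, values in [-1, 1].
    sample_rate
        Sampling rate in Hz (positive).
    source_id
        Free-text identifier (file stem, synthetic event id, ...).
    """

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValidationError("Waveform samples must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if samples.size and (samples.min() < -1.0 - 1e-9 or samples.max() > 1.0 + 1e-9):
            raise ValidationError("Waveform amplitudes must lie in [-1, 1]")

    @property
    def duration_seconds(self) -> float:
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class IntensitySequence:
    """One vocalization event as sensor intensity (volts) over time.

    ``values`` are the per-frame peak-to-peak voltages in [0, 5];
    ``rate_hz`` is the nominal frame rate (138 by default); ``label`` is one
    of the four class names or ``None`` for unlabeled data.
    """

    values: np.ndarray
    rate_hz: float = SENSOR_RATE_HZ
    label: str | None = None
    event_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 1:
            raise ValidationError("IntensitySequence needs at least one value")
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be positive")
        if values.min() < V_MIN - 1e-9 or values.max() > V_MAX + 1e-9:
            raise ValidationError(
                f"intensity values must lie in [{V_MIN}, {V_MAX}] "
                f"(got range [{values.min():.3f}, {values.max():.3f}])"
            )
        if self.label is not None and self.label not in CLASS_NAMES:
            raise ValidationError(
                f"unknown label {self.label!r}; expected one of {CLASS_NAMES}"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class LabeledDataset:
    """A collection of labeled intensity sequences.

    Invariant: every sequence label is a member of ``class_names``.
    ``split_seed`` records the seed used by :func:`barkline.io.split_dataset`
    when this dataset is one half of a train/test split.
    """

    sequences: list[IntensitySequence]
    class_names: tuple[str, ...] = CLASS_NAMES
    split_seed: int | None = None

    def __post_init__(self) -> None:
        for seq in self.sequences:
            if seq.label not in self.class_names:
                raise ValidationError(
                    f"sequence {seq.event_id!r} has label {seq.label!r} "
                    f"not in {self.class_names}"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def by_class(self) -> dict[str, list[IntensitySequence]]:
        """Sequences grouped by label, keyed in class order."""
        groups: dict[str, list[IntensitySequence]] = {c: [] for c in self.class_names}
        for seq in self.sequences:
            groups[seq.label].append(seq)
        return groups

    def class_counts(self) -> dict[str, int]:
        """Event count per class; values sum to ``len(self)``."""
        return {c: len(g) for c, g in self.by_class().items()}

    def total_values(self) -> int:
        """Total number of intensity samples across all events."""
        return sum(len(s) for s in self.sequences)

    def values_per_class(self) -> dict[str, int]:
        """Total intensity-sample count per class."""
        return {c: sum(len(s) for s in g) for c, g in self.by_class().items()}


@dataclass(frozen=True)
class LengthStats:
    """Order statistics of event lengths (sample counts) for one class."""

    minimum: int
    maximum: int
    mean: float
    median: float

    def __post_init__(self) -> None:
        if not (self.minimum <= self.median <= self.maximum):
            raise ValidationError("median must lie between minimum and maximum")
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValidationError("mean must lie between minimum and maximum")


@dataclass
class LengthSummary:
    """Per-class length statistics; a class with no events maps to ``None``."""

    per_class: dict[str, LengthStats | None]

    def to_rows(self) -> list[dict]:
        rows = []
        for name, stats in self.per_class.items():
            if stats is None:
                rows.append({"class": name, "minimum": None, "maximum": None,
                             "mean": None, "median": None})
            else:
                rows.append({"class": name, "minimum": stats.minimum,
                             "maximum": stats.maximum, "mean": stats.mean,
                             "median": stats.median})
        return rows
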