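"""Noise-sensor simulation: framing, 10-bit peak-to-peak ADC quantization,
dB conversion, and the RMSE similarity analysis between sound-derived
intensity and simulated intensity level.

The simulated device mimics an LM-393-style noise sensor: the microphone
voltage (0-5 V, biased at mid-scale) is quantized by a 10-bit ADC, and for
each of 138 frames per second the sensor reports the peak-to-peak code
range converted back to volts.  Only the intensity envelope survives this
reduction — that is the whole point of the resource-efficiency argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datamodel import (
    CLASS_NAMES,
    IntensitySequence,
    LabeledDataset,
    ValidationError,
    Waveform,
)
from .preprocess import resize_to_length


@dataclass(frozen=True)
class ADCSpec:
    """ADC and framing parameters of the simulated noise sensor.

    Defaults: 10-bit resolution (1024 levels), 0-5 V range (GND to VCC),
    138 frames per second.
    """

    resolution_bits: int = 10
    v_low: float = 0.0
    v_high: float = 5.0
    frame_rate_hz: float = 138.0

    def __post_init__(self) -> None:
        if self.resolution_bits < 1:
            raise ValidationError("resolution_bits must be >= 1")
        if self.v_high <= self.v_low:
            raise ValidationError("v_high must exceed v_low")
        if self.frame_rate_hz <= 0:
            raise ValidationError("frame_rate_hz must be positive")

    @property
    def n_levels(self) -> int:
        return 2 ** self.resolution_bits

    @property
    def max_code(self) -> int:
        return self.n_levels - 1

    @property
    def lsb_volts(self) -> float:
        """Voltage step of one ADC code (5/1023 V by default)."""
        return (self.v_high - self.v_low) / self.max_code


def frame_waveform(wave: Waveform, spec: ADCSpec = ADCSpec()) -> list[np.ndarray]:
    """Partition a waveform into non-overlapping frames at the sensor rate.

    Frame ``i`` covers sample indices ``[floor(i*sr/fr), floor((i+1)*sr/fr))``;
    the trailing partial frame is discarded, so the frame count is
    ``floor(n * fr / sr)``.
    """
    n = len(wave)
    if n == 0:
        raise ValidationError("empty waveform")
    sr, fr = wave.sample_rate, spec.frame_rate_hz
    if sr < fr:
        raise ValidationError("waveform sample rate below the sensor frame rate")
    n_frames = int(np.floor(n * fr / sr))
    if n_frames < 1:
        raise ValidationError("event too short: waveform shorter than one frame")
    bounds = np.floor(np.arange(n_frames + 1) * sr / fr).astype(int)
    return [wave.samples[bounds[i]:bounds[i + 1]] for i in range(n_frames)]


def quantize(frame: np.ndarray, spec: ADCSpec = ADCSpec()) -> np.ndarray:
    """Map amplitudes in [-1, 1] to integer ADC codes in [0, 2^bits - 1].

    Amplitude 0 sits at the mid-scale bias; codes are rounded half-up to
    the nearest level.
    """
    volts = spec.v_low + (np.asarray(frame, dtype=float) + 1.0) / 2.0 * (
        spec.v_high - spec.v_low)
    codes = np.floor(
        (volts - spec.v_low) / (spec.v_high - spec.v_low) * spec.max_code + 0.5)
    return np.clip(codes, 0, spec.max_code).astype(np.int64)


def peak_to_peak_level(frame: np.ndarray, spec: ADCSpec = ADCSpec()) -> float:
    """Peak-to-peak voltage of one frame after ADC quantization.

    Returns ``(max code - min code) * LSB`` — always a nonnegative integer
    multiple of one LSB, at most the full range.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValidationError("empty frame")
    codes = quantize(frame, spec)
    return float((codes.max() - codes.min()) * spec.lsb_volts)


def waveform_to_intensity(wave: Waveform, spec: ADCSpec = ADCSpec(),
                          label: str | None = None) -> IntensitySequence:
    """Full sensing path: frame the audio, report per-frame peak-to-peak volts."""
    frames = frame_waveform(wave, spec)
    values = np.array([peak_to_peak_level(f, spec) for f in frames])
    return IntensitySequence(values=values, rate_hz=spec.frame_rate_hz,
                             label=label, event_id=wave.source_id)


def to_db(values: np.ndarray, v_ref: float | None = None,
          spec: ADCSpec = ADCSpec()) -> np.ndarray:
    """Convert nonnegative voltages to dB re ``v_ref``.

    The default reference is one LSB, so the quietest nonzero reading maps
    to 0 dB.  Zeros are floored at one LSB before the log.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValidationError("dB conversion requires nonnegative voltages")
    floor = spec.lsb_volts
    if v_ref is None:
        v_ref = floor
    if v_ref <= 0:
        raise ValidationError("v_ref must be positive")
    return 20.0 * np.log10(np.maximum(values, floor) / v_ref)


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean square error between two equal-length sequences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(
            f"length mismatch ({a.size} vs {b.size}); resample with "
            "align_lengths first")
    if a.size < 1:
        raise ValidationError("rmse needs at least one sample")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def align_lengths(a: np.ndarray, b: np.ndarray,
                  target_length: int) -> tuple[np.ndarray, np.ndarray]:
    """Resample two sequences to a common length via cubic convolution."""
    if target_length < 2:
        raise ValidationError("target_length must be at least 2")
    return (resize_to_length(a, target_length),
            resize_to_length(b, target_length))


@dataclass
class RmseMatrix:
    """Mean RMSE between intensity envelopes of each class pair.

    Rows index the sound-derived (reference) class, columns the simulated
    (sensor) class.  Diagonal dominance — same-class error below cross-class
    error — is the signature that the cheap sensor preserves class identity.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    scale: str = "db"

    def diagonal_dominant(self) -> bool:
        """True if every diagonal entry is below its off-diagonal row mean."""
        v = self.values
        n = len(self.labels)
        for i in range(n):
            off = np.delete(v[i], i)
            if not v[i, i] < off.mean():
                return False
        return True

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd
        path = Path(path)
        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path)
        return path


def rmse_matrix(sound_derived: LabeledDataset, sensor_sim: LabeledDataset,
                target_length: int = 128, scale: str = "db",
                spec: ADCSpec = ADCSpec()) -> RmseMatrix:
    """Class-pair mean RMSE between two intensity datasets.

    Every event is resampled to ``target_length``; sequences are compared in
    dB (default) or volts.  Entry (i, j) averages the RMSE between
    sound-derived events of class i and simulated events of class j.
    Same-class entries pair matched event ids when both datasets carry the
    same ids (the same recordings pushed through both paths); otherwise,
    and for all cross-class entries, the mean over the cross product is used.
    """
    if scale not in ("db", "volts"):
        raise ValidationError("scale must be 'db' or 'volts'")
    labels = tuple(sound_derived.class_names)

    def prep(ds: LabeledDataset) -> dict[str, dict[str, np.ndarray]]:
        out: dict[str, dict[str, np.ndarray]] = {}
        for name, group in ds.by_class().items():
            if not group:
                raise ValidationError(f"class {name!r} has no events")
            events = {}
            for seq in group:
                v = resize_to_length(seq.values, target_length)
                if scale == "db":
                    v = to_db(np.clip(v, 0.0, None), spec=spec)
                events[seq.event_id] = v
            out[name] = events
        return out

    ref = prep(sound_derived)
    sim = prep(sensor_sim)
    n = len(labels)
    values = np.zeros((n, n))
    for i, ci in enumerate(labels):
        A = ref[ci]
        for j, cj in enumerate(labels):
            B = sim[cj]
            if i == j and set(A) == set(B) and len(A) == len(B):
                pair_errs = [rmse(A[k], B[k]) for k in A]
            else:
                Am = np.stack(list(A.values()))
                Bm = np.stack(list(B.values()))
                diff = Am[:, None, :] - Bm[None, :, :]
                pair_errs = np.sqrt((diff ** 2).mean(axis=2)).ravel()
            values[i, j] = float(np.mean(pair_errs))
    return RmseMatrix(labels=labels, values=values, scale=scale)
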