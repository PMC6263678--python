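"""Sequence preprocessing: 0-1 normalization, cubic-convolution resizing,
fixed-width padding, and assembly of model-ready arrays.

The resampler is a 1-D cubic convolution (Keys kernel, parameter ``a``,
default -0.5): each output sample is a weighted sum of the four nearest
input samples, with replicated boundaries.  When shrinking, the kernel is
widened by the inverse scale so it acts as an anti-aliasing low-pass filter.
Cubic convolution reproduces constant and linear sequences exactly and
leaves integer-aligned samples untouched, which is what makes it safe as a
length-augmentation step: it adds samples without reshaping the envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import CLASS_NAMES, LabeledDataset, ValidationError


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs for the preprocessing stage.

    ``interpolation_factor`` stretches every event's length (default 3);
    ``max_dim`` is the maximum pre-interpolation event length the model
    accepts (default 647), so the model input width is
    ``round(max_dim * interpolation_factor)``; ``pad_value`` fills the
    right-hand tail (default 0, the normalized floor); ``kernel_a`` is the
    cubic kernel sharpness (default -0.5).
    """

    interpolation_factor: float = 3.0
    max_dim: int = 647
    pad_value: float = 0.0
    kernel_a: float = -0.5

    def __post_init__(self) -> None:
        if self.interpolation_factor <= 0:
            raise ValidationError("interpolation_factor must be positive")
        if self.max_dim < 2:
            raise ValidationError("max_dim must be at least 2")

    @property
    def model_input_length(self) -> int:
        return int(round(self.max_dim * self.interpolation_factor))


def normalize01(values: np.ndarray) -> np.ndarray:
    """Affine rescaling of a sequence to span [0, 1] using its own extrema.

    A constant sequence has a degenerate range; it is mapped to all zeros
    and a warning is emitted so silent clips survive the pipeline.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("normalize01 needs at least 2 samples")
    lo, hi = values.min(), values.max()
    if hi == lo:
        warnings.warn("constant sequence: 0-1 normalization is degenerate, "
                      "returning zeros", stacklevel=2)
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def _keys_kernel(s: np.ndarray, a: float) -> np.ndarray:
    """Keys piecewise-cubic interpolation kernel with sharpness ``a``."""
    s = np.abs(s)
    out = np.zeros_like(s)
    near = s <= 1.0
    far = (s > 1.0) & (s < 2.0)
    out[near] = (a + 2.0) * s[near] ** 3 - (a + 3.0) * s[near] ** 2 + 1.0
    out[far] = a * s[far] ** 3 - 5.0 * a * s[far] ** 2 + 8.0 * a * s[far] - 4.0 * a
    return out


def _resize_grid(values: np.ndarray, x: np.ndarray, scale: float,
                 kernel_a: float) -> np.ndarray:
    """Cubic-convolution resample of ``values`` at input-space coordinates
    ``x``.

    For ``scale < 1`` the kernel is stretched by ``1/scale`` so it acts as
    an anti-aliasing low-pass filter, and the weights are renormalized.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    out_len = x.size
    # kernel stretch: identity when enlarging, low-pass when shrinking
    kscale = min(scale, 1.0)
    support = 2.0 / kscale
    left = np.ceil(x - support).astype(int)
    width = int(np.ceil(2 * support)) + 1
    idx = left[:, None] + np.arange(width)[None, :]      # (out_len, width)
    dist = x[:, None] - idx
    w = _keys_kernel(dist * kscale, kernel_a) * kscale
    wsum = w.sum(axis=1, keepdims=True)
    w = np.divide(w, wsum, out=w, where=wsum != 0)
    idx = np.clip(idx, 0, n - 1)            # replicate boundary samples
    return (values[idx] * w).sum(axis=1)


def resize_cubic(values: np.ndarray, factor: float,
                 kernel_a: float = -0.5) -> np.ndarray:
    """Resample a sequence to ``round(len * factor)`` samples.

    Enlarging interpolates with the 4-tap Keys kernel; shrinking first
    low-passes by stretching the kernel.  ``factor=1`` is the identity to
    floating precision.
    """
    values = np.asarray(values, dtype=float)
    if factor <= 0:
        raise ValidationError("interpolation factor must be positive")
    if values.size < 2:
        raise ValidationError("resize_cubic needs at least 2 samples")
    out_len = int(round(values.size * factor))
    if out_len < 1:
        raise ValidationError(f"factor {factor} collapses the sequence to nothing")
    # start-pinned grid: output j sits at input coordinate j/factor, so
    # integer-aligned positions reproduce input samples exactly
    x = np.arange(out_len) / factor
    return _resize_grid(values, x, factor, kernel_a)


def resize_to_length(values: np.ndarray, target_length: int,
                     kernel_a: float = -0.5) -> np.ndarray:
    """Resample a sequence to an exact target length (cubic convolution)."""
    values = np.asarray(values, dtype=float)
    if target_length < 2:
        raise ValidationError("target_length must be at least 2")
    if values.size < 2:
        raise ValidationError("resize needs at least 2 samples")
    if target_length == values.size:
        return values.copy()
    # endpoint-aligned grid: both sequences are assumed to span the same
    # duration, so the first and last samples map onto each other
    n = values.size
    scale = (target_length - 1) / (n - 1)
    x = np.arange(target_length) / scale
    return _resize_grid(values, x, scale, kernel_a)


def pad_to(values: np.ndarray, target_length: int,
           pad_value: float = 0.0) -> np.ndarray:
    """Right-pad a sequence with ``pad_value`` to exactly ``target_length``."""
    values = np.asarray(values, dtype=float)
    if values.size > target_length:
        raise ValidationError(
            f"sequence length {values.size} exceeds target {target_length}; "
            "increase max_dim"
        )
    if values.size == target_length:
        return values.copy()
    return np.concatenate(
        [values, np.full(target_length - values.size, float(pad_value))])


def preprocess_dataset(dataset: LabeledDataset,
                       config: PreprocessConfig = PreprocessConfig(),
                       ) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Turn a labeled dataset into model-ready arrays.

    Per event: 0-1 normalization, then cubic resize by
    ``interpolation_factor``, then right-padding to the model input width.
    Returns ``(X, y, class_names)`` where ``X`` is ``(n_events, width)``,
    ``y`` holds integer class indices in the fixed order
    (barking, growling, howling, whining).
    """
    if len(dataset) == 0:
        raise ValidationError("cannot preprocess an empty dataset")
    width = config.model_input_length
    class_names = tuple(dataset.class_names)
    class_index = {c: i for i, c in enumerate(class_names)}
    X = np.empty((len(dataset), width))
    y = np.empty(len(dataset), dtype=np.int64)
    for row, seq in enumerate(dataset):
        v = normalize01(seq.values)
        if config.interpolation_factor != 1.0:
            v = resize_cubic(v, config.interpolation_factor, config.kernel_a)
        X[row] = pad_to(v, width, config.pad_value)
        y[row] = class_index[seq.label]
    return X, y, class_names
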