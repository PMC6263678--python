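"""barkline: resource-efficient dog-vocalization classification from
noise-sensor intensity data.

The package simulates a wearable noise sensor (10-bit peak-to-peak ADC at
138 frames/s) on audio, preprocesses the resulting intensity sequences
(0-1 normalization, cubic-convolution length augmentation), classifies the
four vocalization classes (barking, growling, howling, whining) with an
LSTM-FCN, and budgets the sensing/transmission energy that motivates the
cheap sensor.
"""

from importlib import resources

from .datamodel import (
    CLASS_NAMES,
    SENSOR_RATE_HZ,
    BarklineError,
    FormatError,
    IntensitySequence,
    LabeledDataset,
    LengthStats,
    LengthSummary,
    ValidationError,
    Waveform,
)
from .io import (
    read_intensity_csv,
    read_wav,
    split_dataset,
    summarize_lengths,
    write_intensity_csv,
    write_wav,
)
from .preprocess import (
    PreprocessConfig,
    normalize01,
    pad_to,
    preprocess_dataset,
    resize_cubic,
    resize_to_length,
)
from .sensor import (
    ADCSpec,
    RmseMatrix,
    align_lengths,
    frame_waveform,
    peak_to_peak_level,
    rmse,
    rmse_matrix,
    to_db,
    waveform_to_intensity,
)
from .synth import (
    ClassTemplate,
    SynthConfig,
    default_templates,
    generate_dataset,
    generate_event,
    generate_event_waveform,
    generate_paired_dataset,
    generate_paired_event,
)
from .classifier import (
    EvalReport,
    LSTMFCNConfig,
    TrainedClassifier,
    build_model,
    evaluate,
    sweep_interpolation_factor,
    train,
    train_evaluate_split,
)
from . import energy

__version__ = "0.1.0"


def example_dataset() -> LabeledDataset:
    """The packaged 4-event example dataset (one 64-sample event per class)."""
    path = resources.files("barkline").joinpath("data/example_intensity.csv")
    with resources.as_file(path) as p:
        return read_intensity_csv(p)
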