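import numpy as np
import pytest

from barkline import example_dataset
from barkline.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def example_ds():
    """The packaged 4-event example dataset (64 samples per event)."""
    return example_dataset()


@pytest.fixture(scope="session")
def small_synth_ds():
    """A small balanced synthetic dataset shared across tests."""
    return generate_dataset(SynthConfig(events_per_class=20, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
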