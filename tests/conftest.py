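import numpy as np
import pytest

from bbbdce.phantom import (
    AcquisitionSchedule,
    default_phantom_spec,
    generate_phantom_dataset,
)


@pytest.fixture(scope="session")
def schedule():
    """The dual-time-resolution schedule: 29 x 3.2 s fast, 30 x 30.5 s slow."""
    return AcquisitionSchedule()


@pytest.fixture(scope="session")
def small_grid():
    return (12, 10, 6)


@pytest.fixture(scope="session")
def noiseless_dataset(schedule, small_grid):
    spec = default_phantom_spec(small_grid, noise_sd=0.0, seed=11)
    return generate_phantom_dataset(spec, schedule)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
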