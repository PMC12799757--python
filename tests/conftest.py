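import numpy as np
import pytest

from hemaspec import GeneratorConfig, WavelengthGrid, generate_dataset

SMALL_CONFIG = GeneratorConfig(
    n_subjects=5,
    n_male=3,
    schedule=(0, 1, 3, 5, 7, 10, 14, 21),
    seed=7,
)


@pytest.fixture(scope="session")
def grid() -> WavelengthGrid:
    return WavelengthGrid()


@pytest.fixture(scope="session")
def small_recordings():
    """A 5-subject cohort over a thinned schedule; both age strata populated."""
    return generate_dataset(SMALL_CONFIG)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
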