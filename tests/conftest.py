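import numpy as np
import pytest

from mwfocus import Medium, load_material
from mwfocus.tissue_properties import FREE_SPACE


@pytest.fixture(scope="session")
def brain_1ghz():
    return load_material("Brain", 1e9)


@pytest.fixture(scope="session")
def brain_medium(brain_1ghz):
    return Medium(brain_1ghz, 1e9)


@pytest.fixture(scope="session")
def air_medium():
    return Medium(FREE_SPACE, 1e9)


@pytest.fixture
def rng():
    return np.random.default_rng(20230209)
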