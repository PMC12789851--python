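import numpy as np
import pytest

from chromalight.spectra import WavelengthGrid, default_pigment_types


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid.default()


@pytest.fixture(scope="session")
def pigment_types():
    return default_pigment_types()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
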