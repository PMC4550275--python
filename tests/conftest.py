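import numpy as np
import pytest

from lcpufa.screen import ScreenConfig
from lcpufa.synth import default_references


@pytest.fixture(scope="session")
def refs():
    return default_references()


@pytest.fixture(scope="session")
def cfg():
    return ScreenConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1)
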