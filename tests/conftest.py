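import numpy as np
import pytest

from surfhop import models


@pytest.fixture(scope="session")
def thymine_model():
    return models.build_thymine_model()


@pytest.fixture(scope="session")
def single_crossing_model():
    return models.build_single_crossing()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
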