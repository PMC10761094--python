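import numpy as np
import pytest

from adagcn import synthetic_data


@pytest.fixture
def toy():
    """The fixed 3-drug x 2-disease oracle fixture."""
    return synthetic_data.toy_fixture()


@pytest.fixture
def toy_data():
    return synthetic_data.toy_dataset()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
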