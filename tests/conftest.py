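import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ridge_profile():
    """0,1,0 intensity profile along x, replicated in y and z."""
    vol = np.zeros((3, 4, 4))
    vol[1] = 1.0
    return vol
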