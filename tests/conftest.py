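import numpy as np
import pytest

from fmcadti import autograd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(autouse=True)
def _float64_default():
    """Keep the engine in float64 between tests (some switch to float32)."""
    autograd.set_default_dtype(np.float64)
    yield
    autograd.set_default_dtype(np.float64)
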