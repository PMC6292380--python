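import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def uniform_pvalues(rng):
    """2,000 p-values from the global null with an uninformative covariate."""
    m = 2000
    return rng.uniform(size=m), rng.uniform(size=m)
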