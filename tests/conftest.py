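import numpy as np
import pytest

from mammosim import params as P


@pytest.fixture(scope="session")
def registry():
    return P.default_registry()


@pytest.fixture(scope="session")
def base_params(registry):
    return P.sample_parameter_set(registry, np.random.default_rng(0), psa=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
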