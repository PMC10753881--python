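import numpy as np
import pytest

from azeopatch.interactions import build_n2c8s2


@pytest.fixture(scope="session")
def n2c8s2():
    return build_n2c8s2()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
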