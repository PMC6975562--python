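import numpy as np
import pytest

import transparentgames as tg


@pytest.fixture(scope="session")
def ipd():
    return tg.get_preset("ipd")


@pytest.fixture(scope="session")
def iacg():
    return tg.get_preset("iacg")


@pytest.fixture(scope="session")
def wsls():
    """Win-stay lose-shift with the standard error-floor substitution."""
    return tg.MemoryOneStrategy.from_pure([1, 0, 0, 1, 1, 0, 0, 1, 0, 0, 0, 0])


@pytest.fixture(scope="session")
def alld():
    return tg.MemoryOneStrategy.from_pure([0] * 12)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
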