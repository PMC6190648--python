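import numpy as np
import pytest

from hhfx.gating import BASE_STEPS, DOUBLE_STEPS, HALF_STEPS, build_tables


@pytest.fixture(scope="session")
def base_tables():
    return build_tables(BASE_STEPS)


@pytest.fixture(scope="session")
def double_tables():
    return build_tables(DOUBLE_STEPS)


@pytest.fixture(scope="session")
def half_tables():
    return build_tables(HALF_STEPS)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
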