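import numpy as np
import pytest

from arclass import SyntheticConfig, generate, make_table1_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """Default study conditions: 205 binders / 1480 non-binders, n = 1685."""
    return make_table1_fixture(seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """A fast, fully informative dataset for procedure-level unit tests."""
    return generate(
        SyntheticConfig(
            n_active=40,
            n_inactive=160,
            fp_length=128,
            seed=7,
        )
    )
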