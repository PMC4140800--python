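import numpy as np
import pytest

import soilecol as se


@pytest.fixture(scope="session")
def design():
    return se.simulate_design(5, seed=0)


@pytest.fixture(scope="session")
def effects():
    return se.default_group_effects(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
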