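import numpy as np
import pytest

from lunarbase import make_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_config():
    """Baseline scenario shortened to 5 days for fast integration tests."""
    return make_scenario("initial", {"duration_hours": 120})


@pytest.fixture
def world(short_config):
    from lunarbase import initialize_world

    return initialize_world(short_config, seed=1)
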