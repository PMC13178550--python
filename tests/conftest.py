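import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from thermosweat.synthetic import TruthParams, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """Shared tiny simulated study: 4 participants per child group,
    both conditions, fixed seed."""
    return simulate_study(4, TruthParams(seed=42))


@pytest.fixture(scope="session")
def warm_env():
    from thermosweat.heat_balance import Environment

    return Environment(Ta=30.0, RH=0.40, v=1.389)


@pytest.fixture(scope="session")
def hot_env():
    from thermosweat.heat_balance import Environment

    return Environment(Ta=40.0, RH=0.30, v=1.389)
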