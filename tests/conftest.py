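import numpy as np
import pytest

from candycodes import SimConfig, simulate_candycode


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def sim_code():
    """One seeded 94-particle simulated code (default alphabet A)."""
    return simulate_candycode(SimConfig(seed=42))


@pytest.fixture(scope="session")
def sim_codes():
    """Ten seeded simulated codes for property checks."""
    return [
        simulate_candycode(SimConfig(seed=1000 + i), code_id=f"code_{i}")
        for i in range(10)
    ]
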