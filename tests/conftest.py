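import numpy as np
import pytest

from fireocc import studies, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small three-species simulated survey reused across tests."""
    return synthetic.simulate_community(
        seed=42, species=("SPA", "SPB", "SPC"), n_sites=30, n_years=2,
    )


@pytest.fixture(scope="session")
def small_design_matrices():
    """Random standardized designs: 60 periods of 4 nights, 20 sites."""
    rng = np.random.default_rng(99)
    return studies.simple_design_matrices(
        rng, n_periods=60, nights_per_period=4, n_sites=20, n_years=3,
    )
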