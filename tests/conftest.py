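import pytest

from lncreg.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One synthetic study shared by read-only tests (seed fixed)."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(seed=1)
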