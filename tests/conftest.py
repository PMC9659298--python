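import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from dualsafe import (
    Policy,
    SafetyBehaviorModel,
    SimulationConfig,
    load_builtin_fixture,
)


@pytest.fixture(scope="session")
def coeffs():
    """Packaged normalized coefficient table."""
    return load_builtin_fixture("table2_coefficients")


@pytest.fixture(scope="session")
def effect_records():
    """Packaged coded effect-size table."""
    return load_builtin_fixture("table1_effects")


@pytest.fixture(scope="session")
def active_results():
    """One active-policy run at the published defaults (seed 1)."""
    return SafetyBehaviorModel(SimulationConfig(seed=1)).simulate()


@pytest.fixture(scope="session")
def passive_results():
    """One passive-policy run at the published defaults (seed 1)."""
    cfg = SimulationConfig(seed=1, policy=Policy(kind="passive"))
    return SafetyBehaviorModel(cfg).simulate()
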