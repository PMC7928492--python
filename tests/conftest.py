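import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from redcell.reference_state import build_reference_state
from redcell.transit_experiments import run_reference_transit


@pytest.fixture(scope="session")
def ref():
    """Reference steady state and back-computed parameters, built once."""
    return build_reference_state()


@pytest.fixture(scope="session")
def ref_run_5min(ref):
    system, params = ref
    return run_reference_transit(5.0, system, params)


@pytest.fixture(scope="session")
def ref_run_60min(ref):
    system, params = ref
    return run_reference_transit(60.0, system, params)


@pytest.fixture(scope="session")
def ref_run_long(ref):
    """Ref transit followed for 25 days of model time (recovery horizon)."""
    system, params = ref
    return run_reference_transit(25.0 * 24.0 * 60.0, system, params,
                                 follow_epochs=3000)
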