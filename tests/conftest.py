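import pytest

from coxflux import (
    SimulationSettings,
    build_mini_cox_model,
    generate_expression_profiles,
    initialize,
    recommended_settings,
    run_to_steady_state,
)


@pytest.fixture(scope="session")
def mini_cox():
    return build_mini_cox_model()


@pytest.fixture(scope="session")
def low_ep_profile(mini_cox):
    """One low-EP-receptor expression profile (fixed seed)."""
    return generate_expression_profiles(mini_cox, 1, seed=1, low_ep=True)[0]


@pytest.fixture(scope="session")
def fixture_settings():
    return recommended_settings()


@pytest.fixture(scope="session")
def quick_settings():
    """Coarser tolerance for tests that only need directional answers."""
    return recommended_settings(convergence_tol=1e-7, max_steps=40000)


@pytest.fixture(scope="session")
def mini_cox_control(mini_cox, low_ep_profile, fixture_settings):
    """Steady control state of the fixture under the low-EP profile."""
    s0 = initialize(mini_cox, low_ep_profile)
    res = run_to_steady_state(mini_cox, s0, fixture_settings)
    assert res.converged
    return res
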