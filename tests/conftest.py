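import pytest
from hypothesis import HealthCheck, settings

from settlegame import IntegrationSettings, PopulationState, baseline_parameters

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def baseline():
    return baseline_parameters()


@pytest.fixture
def fast_settings():
    """Short-horizon integration settings for sweep-heavy tests."""
    return IntegrationSettings(t_max=200.0)


@pytest.fixture
def coarse_grid():
    """3x3 interior grid of initial conditions for sweep-heavy tests."""
    return tuple(
        PopulationState(x, y)
        for x in (0.25, 0.5, 0.75)
        for y in (0.25, 0.5, 0.75)
    )
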