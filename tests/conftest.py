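import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from endovesiq import (SecondaryMarker, SimulationParams, simulate_field)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_params():
    """A compact two-secondary field used by several suites."""
    return SimulationParams(
        field_shape=(128, 128),
        vesicle_density=1.5,
        seed=42,
        secondaries=(
            SecondaryMarker("endoglin", true_positive_fraction=0.6),
            SecondaryMarker("smad1", true_positive_fraction=0.4),
        ),
    )


@pytest.fixture(scope="session")
def small_field(small_params):
    """(FieldOfView, GroundTruth) for the compact field."""
    return simulate_field(small_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
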