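import numpy as np
import pytest

from stepdown.cohort import CohortParameters, Participant, generate_cohort


@pytest.fixture(scope="session")
def default_params() -> CohortParameters:
    return CohortParameters(seed=123)


@pytest.fixture(scope="session")
def cohort(default_params):
    return generate_cohort(default_params)


def make_participant(
    h_low: float = 0.075,
    h_high: float = 0.065,
    slope: float = 150.0,
    speed: float = 1.1,
    **kwargs,
) -> Participant:
    """Hand-built participant with fully specified latent truth."""
    defaults = dict(
        id="pX",
        condition_order=("low", "high"),
        true_hcrit_low=h_low,
        true_hcrit_high=h_high,
        true_slope=slope,
        fear_responder=False,
        eda_tonic_uS=16.8,
        speed_low=speed,
        speed_high=speed,
        fear_first_low=1.0,
        fear_first_high=1.0,
        metadata={},
    )
    defaults.update(kwargs)
    return Participant(**defaults)


@pytest.fixture
def participant():
    return make_participant()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
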