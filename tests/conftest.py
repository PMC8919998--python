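import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from lcda_backpack import generate_study


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (30 participants, 4 loads x 5 conditions)."""
    participants, trials, truth = generate_study(seed=11)
    m_rest = {p.id: p.resting_rate for p in participants}
    return participants, trials, truth, m_rest


@pytest.fixture(scope="session")
def noise_free_study():
    from lcda_backpack.synthetic_data import NoiseModel

    participants, trials, truth = generate_study(
        seed=11, noise=NoiseModel(residual_sd=0.0, participant_intercept_sd=0.0)
    )
    m_rest = {p.id: p.resting_rate for p in participants}
    return participants, trials, truth, m_rest
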