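import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from triage_sim import (
    BASELINE,
    ScenarioConfig,
    TriangularParams,
    load_profiles,
)

HYPERTENSION = TriangularParams(0.19, 0.63, 0.23)


@pytest.fixture(scope="session")
def baseline():
    return BASELINE


@pytest.fixture(scope="session")
def hypertension():
    return HYPERTENSION


@pytest.fixture(scope="session")
def packaged_profiles():
    return load_profiles()[1]


@pytest.fixture(scope="session")
def realworld():
    return ScenarioConfig.realworld()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
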