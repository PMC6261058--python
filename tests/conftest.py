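import pytest
from hypothesis import HealthCheck, settings

from interlogit.data import example_observations, reconstruct_example_cells
from interlogit.glm import LogitGlm, ModelFormula

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def example_obs():
    return example_observations()


@pytest.fixture(scope="session")
def example_cells():
    return reconstruct_example_cells()


@pytest.fixture(scope="session")
def full_fit(example_obs):
    return LogitGlm.from_observations(example_obs, ModelFormula.full()).fit()


@pytest.fixture(scope="session")
def main_effects_fit(example_obs):
    return LogitGlm.from_observations(example_obs, ModelFormula.main_effects()).fit()


@pytest.fixture(scope="session")
def single_factor_fit(example_obs):
    return LogitGlm.from_observations(
        example_obs, ModelFormula.single_factor_mode()
    ).fit()
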