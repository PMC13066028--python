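import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nutrimap import simulate as sim

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def survey_default_config():
    return sim.default_survey_config()


@pytest.fixture(scope="session")
def plain_config(survey_default_config):
    """Default marginal distribution, no covariate effects: the configured
    base_sigma is then the marginal covariance of the responses."""
    return sim.SyntheticConfig(
        n_clusters=250,
        children_per_cluster=(20, 20),
        base_mu=survey_default_config.base_mu,
        base_sigma=survey_default_config.base_sigma,
        effects=[],
    )


@pytest.fixture(scope="session")
def plain_survey(plain_config):
    """~5,000 children with no covariate effects (shared, read-only)."""
    return sim.simulate_survey(plain_config, seed=101)


@pytest.fixture(scope="session")
def default_survey(survey_default_config):
    """~9,000 children under the full default generator (shared, read-only)."""
    return sim.simulate_survey(survey_default_config, seed=7)


def random_spd(rng: np.random.Generator, m: int = 4) -> np.ndarray:
    a = rng.normal(size=(m, m))
    return a @ a.T + 0.05 * np.eye(m)
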