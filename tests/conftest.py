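import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_trial():
    """A small synthetic trial with a planted diabetes interaction."""
    from bartcate import default_marginals, generate_trial, scenario

    return generate_trial(200, default_marginals(), scenario("diabetes-interaction"), seed=7)


@pytest.fixture(scope="session")
def std_small_trial(small_trial):
    from bartcate import standardize_covariates

    return standardize_covariates(small_trial)


@pytest.fixture(scope="session")
def tiny_cfg():
    """A very short MCMC schedule for smoke-level fits."""
    from bartcate import BartConfig

    return BartConfig(m=20, n_chains=1, n_total=120, n_burn=40)


@pytest.fixture()
def rng():
    # fresh, identically-seeded generator per test: results do not depend on
    # which other tests ran first
    return np.random.default_rng(2024)
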