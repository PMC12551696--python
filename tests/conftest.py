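import numpy as np
import pytest
from hypothesis import settings

import chronomr as cm
from chronomr.presets import validation_config

settings.register_profile("reproducible", deadline=None, derandomize=True)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def validation_cohort():
    """One calibrated-scenario cohort (n=100k, fixed seed), shared across tests."""
    return cm.simulate_cohort(validation_config(100_000, seed=42))


@pytest.fixture(scope="session")
def validation_beta(validation_cohort):
    return cm.fit_beta_quartic(validation_cohort, covariates=["covar"])


@pytest.fixture(scope="session")
def validation_increments(validation_cohort):
    fit = cm.fit_aalen(
        validation_cohort, ["instrument", "covar"], max_follow_age=80, seed=7
    )
    return cm.yearly_increments(fit, "instrument")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
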