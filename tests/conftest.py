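import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neutrosim import io as nio
from neutrosim.lifecycle import PatientTraits

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# fast-but-accurate solver settings for cohort-level tests (max relative
# deviation ~3e-4 from the reference tolerances)
SCREEN = dict(rtol=1e-6, atol=1e3)


@pytest.fixture(scope="session")
def gbm_traits() -> PatientTraits:
    return nio.load_disease_set("GBM").traits


@pytest.fixture(scope="session")
def dlbcl():
    return nio.load_disease_set("DLBCL")


@pytest.fixture(scope="session")
def dlbcl_traits(dlbcl) -> PatientTraits:
    return dlbcl.traits


@pytest.fixture(scope="session")
def pk_default():
    return nio.default_pk()


@pytest.fixture(scope="session")
def pk_exposure():
    return nio.exposure_calibrated_pk()


@pytest.fixture(scope="session")
def pd_default(dlbcl):
    return dlbcl.pd_params


@pytest.fixture(scope="session")
def small_cohort():
    """20 DLBCL-like virtual patients with spread baselines and traits."""
    from neutrosim.synthetic import default_trait_distributions, sample_traits

    rng = np.random.default_rng(7)
    return sample_traits(default_trait_distributions(), 20, rng)
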