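import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cardiomet as cm

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_specs():
    return cm.paper_default_specs(seed=7)


@pytest.fixture(scope="session")
def pws_cohort(default_specs):
    return cm.generate_cohort(default_specs[0])


@pytest.fixture(scope="session")
def eob_cohort(default_specs):
    return cm.generate_cohort(default_specs[1])


@pytest.fixture(scope="session")
def panels(pws_cohort, eob_cohort):
    return cm.derive_panels([eob_cohort, pws_cohort])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
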