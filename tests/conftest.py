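import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160223)


@pytest.fixture(scope="session")
def score1_fixture():
    """Small deterministic cohort + true 3-SNP model (effect preset)."""
    from snpscore import make_fixture

    return make_fixture("score1", n_case=80, n_control=240, seed=7)


@pytest.fixture(scope="session")
def null_fixture():
    """Cohort simulated with all ORs = 1: status independent of genotype."""
    from snpscore import make_fixture

    return make_fixture("null", n_case=80, n_control=240, seed=11)
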