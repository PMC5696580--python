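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
def female_cohort_frame():
    """Reference female cohort with craniofacial features, n=4000."""
    from osakit import cohort

    spec = cohort.build_reference_spec("female", features="craniofacial",
                                       n=4000, seed=11)
    return cohort.cohort_to_frame(cohort.generate_cohort(spec))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
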