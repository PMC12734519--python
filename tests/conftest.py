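import pytest
from hypothesis import settings

import pdrscreen

settings.register_profile("det", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def study_cohort():
    """The deterministic 58-patient cohort with the published factor counts."""
    return pdrscreen.fixture_cohort()


@pytest.fixture(scope="session")
def large_cohort():
    """Synthetic cohort at ~1e5 records per group for parameter recovery."""
    spec = pdrscreen.CohortSpec.default(scale=100_000 / 27)
    return spec, pdrscreen.generate_cohort(spec, seed=20240)
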