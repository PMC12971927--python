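import numpy as np
import pytest
from hypothesis import settings

from couinaudps import CohortConfig, default_template, generate_cohort

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def small_cohort():
    """30 subjects, single template, modest variability; shared read-only."""
    config = CohortConfig(
        n_subjects=30,
        templates=[default_template()],
        subtype_weights=(1.0,),
        jitter_sd=5.0,
        global_scale_sd=0.0,
        rotation_sd_deg=0.0,
        translation_sd_mm=20.0,
        missing_prob=0.0,
        seed=11,
    )
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
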