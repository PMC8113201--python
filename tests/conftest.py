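import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from petmr_lesionrisk.pipeline import extract_cohort_features
from petmr_lesionrisk.synthetic import CohortConfig, generate_cohort

warnings.filterwarnings("ignore", message="dropping .* zero-variance")
warnings.filterwarnings("ignore", message="non-finite features")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten synthetic patients with default study conditions."""
    return generate_cohort(CohortConfig(n_patients=10, seed=42))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Feature table of the ten-patient cohort (trilinear resampling for
    speed; kriging is exercised by the preprocessing tests)."""
    return extract_cohort_features(small_cohort, interp="trilinear")
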