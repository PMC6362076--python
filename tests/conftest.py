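import numpy as np
import pytest

from lofscreen import (
    DEFAULT_LOF_FEATURES,
    CohortSpec,
    flag_at_percentile,
    generate_cohort,
    score_features,
)

#: the reference evaluation cohort: n and contamination of the motivating
#: community sample, 3-SD effect, k=20, 95th-percentile threshold
REFERENCE_SPEC = CohortSpec(n_subjects=1570, seed=42)
REFERENCE_K = 20
REFERENCE_PERCENTILE = 95.0


@pytest.fixture(scope="session")
def reference_cohort():
    return generate_cohort(REFERENCE_SPEC)


@pytest.fixture(scope="session")
def reference_features(reference_cohort):
    return reference_cohort.features[list(DEFAULT_LOF_FEATURES)]


@pytest.fixture(scope="session")
def reference_scores(reference_features):
    return score_features(reference_features, REFERENCE_K).as_series()


@pytest.fixture(scope="session")
def reference_decision(reference_scores):
    return flag_at_percentile(reference_scores, REFERENCE_PERCENTILE)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
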