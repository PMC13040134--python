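import warnings

import numpy as np
import pytest

from adnexrad.synthetic import (CohortSpec, cohort_clinical_frame,
                                generate_cohort)
from adnexrad.features import extract_cohort_features


@pytest.fixture(scope="session")
def small_cohort():
    """60-case synthetic cohort shared across tests (deterministic)."""
    return generate_cohort(CohortSpec(n_cases=60, seed=5))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return extract_cohort_features(small_cohort)


@pytest.fixture(scope="session")
def small_clinical(small_cohort):
    return cohort_clinical_frame(small_cohort)


@pytest.fixture(scope="session")
def medium_cohort():
    """300-case cohort for selection/modeling tests."""
    return generate_cohort(CohortSpec(n_cases=300, seed=11))


@pytest.fixture(scope="session")
def medium_data(medium_cohort):
    X = extract_cohort_features(medium_cohort)
    cl = cohort_clinical_frame(medium_cohort)
    return medium_cohort, X, cl


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _quiet_selector_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="no feature significant")
        yield
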