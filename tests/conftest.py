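import numpy as np
import pytest

from frfx.classifier import ClassifierConfig, train_functional_classifier
from frfx.phantom import CaseParams, CohortParams, generate_case, generate_cohort


@pytest.fixture(scope="session")
def train_cohort():
    """Small default-contrast training cohort with truth masks."""
    return generate_cohort(CohortParams(n=8, n_alpps=4), seed=7001)


@pytest.fixture(scope="session")
def trained(train_cohort):
    return train_functional_classifier(train_cohort, ClassifierConfig())


@pytest.fixture(scope="session")
def selection_report(trained):
    return trained[0]


@pytest.fixture(scope="session")
def default_model(trained):
    return trained[1]


@pytest.fixture(scope="session")
def sample_case():
    """One default-contrast phantom with a moderate oedema rim."""
    return generate_case(CaseParams(theta=0.4), seed=303, case_id="sample")
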