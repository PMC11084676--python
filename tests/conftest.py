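import numpy as np
import pytest
from hypothesis import settings

from raman_pcad import (
    CVConfig,
    average_per_patient,
    generate_study,
    preprocess_dataset,
)
from raman_pcad.synthgen import small_study_config

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale study: 38 patients over two cohorts, ~200
    wavenumbers, default peak/noise structure."""
    return small_study_config(seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def patient_table(small_dataset):
    """Preprocessed, patient-averaged table from the reduced study."""
    return average_per_patient(preprocess_dataset(small_dataset))


@pytest.fixture()
def cv15():
    return CVConfig(n_subsets=15, n_iterations=5, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
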