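import numpy as np
import pytest

from siteshift.experiments import default_profiles
from siteshift.synthetic import GeneratorConfig, generate_study_set


@pytest.fixture(scope="session")
def small_study_set():
    """A small rendered two-site study set shared across tests."""
    config = GeneratorConfig(patients_per_site=40, seed=123)
    profiles = default_profiles()[:2]
    return generate_study_set(config, profiles)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
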