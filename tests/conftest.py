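import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dtgam.data_model import expand_person_period
from dtgam.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """80-subject synthetic cohort with the default study conditions."""
    cfg = SimulationConfig(n_subjects=80)
    subjects, truth = simulate_cohort(cfg, seed=20260927)
    return subjects, truth


@pytest.fixture(scope="session")
def small_table(small_cohort):
    subjects, _ = small_cohort
    return expand_person_period(subjects)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
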