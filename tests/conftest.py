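import numpy as np
import pytest

from agestage import make_cohort, toy_cohort
from agestage.simulate import preset_scenarios, simulate_cohort


@pytest.fixture
def hand_cohort():
    """3-individual cohort small enough to enumerate by hand (R0 = 2)."""
    return make_cohort("toy", toy_cohort())


@pytest.fixture(scope="session")
def presets():
    return preset_scenarios()


@pytest.fixture(scope="session")
def cohort_25c(presets):
    """One simulated 25°C-like cohort at the study sample size."""
    return simulate_cohort(presets["25C"], seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
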