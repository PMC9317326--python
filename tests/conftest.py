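import numpy as np
import pytest

from stepsense.cohort import CohortDesign, make_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced but structurally complete crossover cohort (fast to fit)."""
    design = CohortDesign(n_per_group=4, n_blocks=2, trials_per_block=50, seed=42)
    return make_cohort(design)
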