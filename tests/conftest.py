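import numpy as np
import pytest

from mrdjoint import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-condition cohort with ground truth (n=150)."""
    return generate_cohort(SimConfig(n_patients=150, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
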