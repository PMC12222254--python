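import numpy as np
import pytest

from plantarzone import phantom


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-subject phantom cohort shared by read-only tests."""
    return phantom.generate_cohort(10, seed=42)


@pytest.fixture(scope="session")
def one_sample(small_cohort):
    return small_cohort[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
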