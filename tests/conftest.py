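import numpy as np
import pytest

import twopartcac as tp


@pytest.fixture(scope="session")
def config():
    return tp.default_mesa_config()


@pytest.fixture(scope="session")
def cohort_i1():
    """Mid-sized cohort from the proportional linear-effects truth."""
    return tp.generate_cohort(tp.example_truth("i.1"), 2000, 101)


@pytest.fixture(scope="session")
def cohort_ii1():
    """Mid-sized cohort from the nonproportional linear-effects truth."""
    return tp.generate_cohort(tp.example_truth("ii.1"), 2000, 102)


@pytest.fixture(scope="session")
def fitted_i1(cohort_i1):
    return tp.fit("i.1", cohort_i1)


@pytest.fixture(scope="session")
def fitted_ii1(cohort_ii1):
    return tp.fit("ii.1", cohort_ii1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
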