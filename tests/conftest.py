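import numpy as np
import pytest

from uromet.simulate import (CohortConfig, default_axis, default_library,
                             generate_cohort)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def axis():
    return default_axis()


@pytest.fixture(scope="session")
def cohort(library):
    """One default six-subject paired cohort (seed-fixed)."""
    return generate_cohort(CohortConfig(seed=11), library)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
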