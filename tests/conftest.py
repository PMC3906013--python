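import numpy as np
import pytest

from thyrocal import CohortConfig, calibrate_cohort, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded cohort at the default study conditions (n=13,127)."""
    return generate_cohort(CohortConfig(), seed=1)


@pytest.fixture(scope="session")
def default_calibration(default_cohort):
    return calibrate_cohort(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
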