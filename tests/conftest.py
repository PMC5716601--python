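import logging

import numpy as np
import pytest

from valuetasks.cohort import CohortConfig, simulate_cohort

logging.getLogger("valuetasks").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def grid():
    """The 11x11 euro offer grid as (gains, donations) arrays."""
    amounts = np.arange(0.0, 101.0, 10.0)
    g, d = np.meshgrid(amounts, amounts, indexing="ij")
    return g.ravel(), d.ravel()


@pytest.fixture(scope="session")
def small_cohort():
    """Three synthetic subjects at default study conditions."""
    datasets, table = simulate_cohort(CohortConfig(n_subjects=3, seed=42))
    return datasets, table


@pytest.fixture(scope="session")
def one_subject(small_cohort):
    return small_cohort[0][0]
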