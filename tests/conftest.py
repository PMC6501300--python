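import numpy as np
import pandas as pd
import pytest

from ihcsig import CohortConfig, generate_cohort
from ihcsig.scoring import add_measure_labels


@pytest.fixture(scope="session")
def cohort_163():
    """A seeded study-sized cohort with score/label columns."""
    return add_measure_labels(generate_cohort(CohortConfig(n_patients=163, seed=11)))


@pytest.fixture(scope="session")
def cohort_100():
    return add_measure_labels(generate_cohort(CohortConfig(n_patients=100, seed=23)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def exponential_surv(rng, n, hazard, censor_rate):
    """Exponential event times with independent exponential censoring."""
    t = rng.exponential(1.0 / hazard, n)
    c = rng.exponential(1.0 / censor_rate, n)
    times = np.minimum(t, c)
    events = (t <= c).astype(int)
    return times, events
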