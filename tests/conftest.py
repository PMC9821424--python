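import numpy as np
import pytest

from gadopk.data import TimeSeries
from gadopk.synthetic import (
    HumanProtocolSpec,
    RatCohortSpec,
    generate_human_subject,
    generate_rat_cohort,
)


@pytest.fixture(scope="session")
def rat_times():
    return np.arange(0.0, 3601.0, 60.0)


@pytest.fixture(scope="session")
def bolus_input(rat_times):
    """Smooth gamma-variate-like bolus starting at zero, typical rat shape."""
    vals = 0.8 * (rat_times / 120.0) * np.exp(1 - rat_times / 120.0)
    return TimeSeries(times=rat_times, values=vals, tissue="spleen")


@pytest.fixture(scope="session")
def constant_input():
    return TimeSeries(times=[0.0, 10000.0], values=[0.5, 0.5], tissue="spleen")


@pytest.fixture(scope="session")
def noiseless_rat():
    """Single rat with zero noise and zero between-rat variability."""
    spec = RatCohortSpec(doses=(0.0, 50.0), n_per_dose=1, noise_cv=0.0,
                         omega_frac=0.0, seed=5)
    cohort, truth = generate_rat_cohort(spec)
    return cohort[0], truth["subjects"][cohort[0].subject_id]


@pytest.fixture(scope="session")
def default_cohort():
    """The default 30-rat cohort at study conditions (5% noise, 10% omega)."""
    spec = RatCohortSpec(seed=42)
    return generate_rat_cohort(spec)


@pytest.fixture(scope="session")
def human_subject():
    return generate_human_subject(HumanProtocolSpec(seed=3), subject_id="h1")
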