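import numpy as np
import pytest

from bicarbkin.data_io import RunConfig
from bicarbkin.synth import CohortParams, sample_cohort, sample_gi_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """12-subject, 2-visit synthetic cohort at study-default settings."""
    return sample_cohort(CohortParams(rng_seed=42))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Cohort with no measurement noise and no visit-to-visit variation."""
    params = CohortParams(
        measurement_noise_sd=0.0,
        baseline_sd_within=0.0,
        delta_peak_sd_within=0.0,
        ttp_sd_within=0.0,
        rng_seed=7,
    )
    return sample_cohort(params)


@pytest.fixture(scope="session")
def gi_cohort():
    return sample_gi_cohort(n_subjects=12, rng_seed=3)


@pytest.fixture()
def config():
    return RunConfig(rng_seed=11)


def random_knot_sets(n_sets, rng_seed=0, monotone=False):
    """Random strictly-increasing time knots with plausible concentrations."""
    rng = np.random.default_rng(rng_seed)
    for _ in range(n_sets):
        n = int(rng.integers(3, 12))
        x = np.sort(rng.choice(np.arange(0, 241), size=n, replace=False)).astype(float)
        x[0] = 0.0
        if monotone:
            y = 24.0 + np.cumsum(rng.uniform(0.0, 2.0, size=n))
        else:
            y = rng.normal(28.0, 3.0, size=n)
        yield x, np.clip(y, 1.0, None)
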