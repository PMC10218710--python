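import numpy as np
import pytest

from sternmag import scheduler, synthetic_rt
from sternmag.synthetic_rt import GeneratorParams


@pytest.fixture(scope="session")
def pools():
    return scheduler.make_symbol_pools(0)


@pytest.fixture(scope="session")
def study_params():
    """Generator truth at the study's fitted coefficients, 80 ms trial noise."""
    return GeneratorParams()


@pytest.fixture(scope="session")
def noiseless_params():
    return GeneratorParams(resid_sd=0.0, subject_sd=0.0, p_error=0.0)


@pytest.fixture(scope="session")
def cohort_plan():
    """The study cohort: 65 subjects, 34 exposed / 31 sham."""
    return scheduler.default_cohort_plan(seed=11)


@pytest.fixture(scope="session")
def noiseless_records(cohort_plan, noiseless_params):
    return synthetic_rt.simulate_cohort(cohort_plan, noiseless_params, seed=5)


@pytest.fixture(scope="session")
def noisy_records(cohort_plan, study_params):
    return synthetic_rt.simulate_cohort(cohort_plan, study_params, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
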