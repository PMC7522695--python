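import warnings

import pytest

from gistcea import default_parameters, generate_fixture_trials
from gistcea.markov import cohorts


@pytest.fixture(scope="session")
def params():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # known CI-inconsistency flags on AE costs
        return default_parameters()


@pytest.fixture(scope="session")
def curves():
    """Noiseless synthetic trial curves (the packaged study conditions)."""
    return generate_fixture_trials(seed=17)


@pytest.fixture(scope="session")
def cohort_map(params, curves):
    """All six strategy × genotype cohort runs on the default fixtures."""
    return cohorts(params, curves)
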