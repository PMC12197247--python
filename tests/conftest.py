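import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cavsat.cohort import covariate_matrix, treatment_indicator
from cavsat.outcomes import attach_outcomes
from cavsat.simulate import CohortParams, generate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """Simulated cohort (n=300) with outcome metric columns attached."""
    df, _ = attach_outcomes(generate_cohort(CohortParams(n_total=300, seed=42)))
    return df.reset_index(drop=True)


@pytest.fixture(scope="session")
def cohort_design(small_cohort):
    """(X, t) design for the small cohort."""
    return covariate_matrix(small_cohort), treatment_indicator(small_cohort)


@pytest.fixture(scope="session")
def unconfounded_cohort():
    """Cohort with no propensity slopes and no treatment effects."""
    from cavsat.simulate import null_outcome_model

    params = CohortParams(
        n_total=400,
        treated_fraction=0.3,
        propensity_slopes={},
        outcome_model=null_outcome_model(),
        seed=7,
    )
    df, _ = attach_outcomes(generate_cohort(params))
    return df.reset_index(drop=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
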