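import numpy as np
import pytest

from idex.preprocessing import encode, impute
from idex.synthetic import CohortConfig, default_paper_schema, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """486-patient default-schema cohort with flips and missingness."""
    cohort, truth = generate_cohort(
        CohortConfig(
            n_patients=486,
            target_prevalence=0.29,
            confounder_fraction=0.12,
            seed=11,
        )
    )
    return cohort, truth


@pytest.fixture(scope="session")
def tiny_cohort():
    """60-patient cohort, no flips, no missingness — fast paths."""
    cohort, _ = generate_cohort(
        CohortConfig(
            n_patients=60,
            target_prevalence=0.4,
            schema=default_paper_schema(missing_rate=0.0),
            seed=5,
        )
    )
    return cohort


@pytest.fixture(scope="session")
def encoded_small(small_cohort):
    cohort, _ = small_cohort
    return impute(encode(cohort), cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
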