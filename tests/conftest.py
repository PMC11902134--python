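import numpy as np
import pytest

from bmirecal import AdiposityModel, GeneratorConfig, generate_cohort
from bmirecal.synthetic_cohort import DEFAULT_LN_COEFFS, DEFAULT_RESID_SD

N_BANK = 100


@pytest.fixture(scope="session")
def cohort_bank():
    """100 default cohorts (n=622, seeds 1..100), shared across the suite."""
    return [generate_cohort(GeneratorConfig(seed=s)) for s in range(1, N_BANK + 1)]


@pytest.fixture(scope="session")
def default_cohort(cohort_bank):
    return cohort_bank[0]


@pytest.fixture
def calibrated_model():
    """The generating log-quadratic wrapped as a fitted model object."""
    return AdiposityModel(
        coeffs=DEFAULT_LN_COEFFS,
        degree=2,
        r_squared=0.4447,
        resid_sd=DEFAULT_RESID_SD,
        n_fit=622,
        bf_range_fit=(5.0, 35.0),
    )


@pytest.fixture
def hand_model():
    """Small hand-evaluable quadratic used in worked examples."""
    return AdiposityModel(
        coeffs=(3.2, -0.02, 0.001),
        degree=2,
        r_squared=0.9,
        resid_sd=0.01,
        n_fit=100,
        bf_range_fit=(5.0, 35.0),
    )


def table_to_labels(table, row_labels, col_labels):
    """Expand a contingency table into paired label sequences (test oracle)."""
    a, b = [], []
    t = np.asarray(table, dtype=int)
    for i, ra in enumerate(row_labels):
        for j, cb in enumerate(col_labels):
            a.extend([ra] * t[i, j])
            b.extend([cb] * t[i, j])
    return a, b
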