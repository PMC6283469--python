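import warnings

import pytest

from vlab import (CohortSpec, generate_cohort, inject_selection_bias,
                  interpolate_series)


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate-size cohort with the default phenotype profiles and OS bias."""
    spec = CohortSpec(n_os=240, n_rct=120, seed=5)
    patients, series = generate_cohort(spec)
    patients = inject_selection_bias(patients, 0.5, seed=6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        series = interpolate_series(series)
    return patients, series


@pytest.fixture(scope="session")
def separated_cohort():
    """Well-separated 6-cluster cohort (separation = 3 within-cluster SDs)."""
    spec = CohortSpec.separated(n_os=300, n_rct=150, seed=3)
    patients, series = generate_cohort(spec)
    series = interpolate_series(series)
    return patients, series
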