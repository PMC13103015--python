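import numpy as np
import pandas as pd
import pytest

from trajscreen import (
    apply_design_filters,
    generate_cohort,
    log_transform_proteins,
    make_cohort,
    pair_config,
)


@pytest.fixture
def toy_tables():
    """Two patients, one protein and one echo variable, 6 rows."""
    meas = pd.DataFrame(
        {
            "patient_id": ["P1", "P1", "P1", "P2", "P2", "P2"],
            "time_months": [1.0, 3.0, 12.0, 0.0, 3.0, 12.0],
            "variable_id": ["prot_a", "prot_a", "prot_a", "av", "av", "av"],
            "variable_type": ["protein"] * 3 + ["echo"] * 3,
            "value": [2.0, 2.5, 3.0, 20.0, 24.0, 25.0],
        }
    )
    cov = pd.DataFrame(
        {
            "patient_id": ["P1", "P2"],
            "age_years": [55.0, 68.0],
            "sex": ["male", "female"],
        }
    )
    return meas, cov


@pytest.fixture
def toy_cohort(toy_tables):
    return make_cohort(*toy_tables)


def prepared_cohort(cfg, seed):
    """Generate, log-transform and design-filter a synthetic cohort."""
    ds, truth = generate_cohort(cfg, seed=seed)
    return apply_design_filters(log_transform_proteins(ds)), truth


@pytest.fixture(scope="session")
def ri_pair_cohort():
    """Mid-sized cohort with a rho=0.6 random-intercept coupling."""
    cfg = pair_config(n_patients=150, rho=0.6, missingness=0.0, seed=42)
    return prepared_cohort(cfg, 42)
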