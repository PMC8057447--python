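import numpy as np
import pandas as pd
import pytest

from cogjoint import default_config
from cogjoint.cohort import assemble_cohort
from cogjoint.survival import define_dropout


@pytest.fixture(scope="session")
def small_mnar_cohort():
    """A 200-subject MNAR cohort shared across read-only tests."""
    cfg = default_config(seed=314, n_subjects=200)
    return assemble_cohort(cfg)


@pytest.fixture(scope="session")
def small_mar_cohort():
    cfg = default_config(seed=159, n_subjects=200, regime="MAR")
    return assemble_cohort(cfg)


@pytest.fixture(scope="session")
def small_mnar_outcomes(small_mnar_cohort):
    return define_dropout(
        small_mnar_cohort.events,
        admin_end=small_mnar_cohort.config.admin_censor_time,
    )


@pytest.fixture()
def toy_baselines():
    """Three hand-built subjects covering both sexes and MCI statuses."""
    return pd.DataFrame(
        {
            "subject_id": [1, 2, 3],
            "age_at_enrollment": [75.0, 80.0, 90.0],
            "sex": ["F", "M", "F"],
            "education_level": ["ge16", "hs12", "lt12"],
            "apoe4": [0, 1, 0],
            "mci_at_enrollment": [0, 0, 1],
            "midlife_diabetes": [0, 0, 0],
            "midlife_hypertension": [0, 1, 0],
            "midlife_dyslipidemia": [0, 0, 1],
            "atrial_fibrillation": [0, 0, 0],
            "chf": [0, 0, 0],
            "stroke": [0, 0, 0],
            "cad": [0, 1, 0],
            "charlson_index": [1, 2, 3],
            "marital_status": ["married", "single", "widowed_divorced"],
            "smoking_status": ["never", "former", "current"],
            "alcohol_problem": [0, 0, 0],
            "prior_20yr_exposure": [1, 0, 0],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
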