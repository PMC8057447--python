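"""Covariate coding: the data dictionary mapping baseline tables to design columns.

Raw baseline tables carry one row per subject with the columns in
:data:`BASELINE_COLUMNS`.  Model code never touches raw columns directly;
it works with encoded design columns with fixed reference levels:

====================  =========================================================
encoded column        definition
====================  =========================================================
``age_c``             (age_at_enrollment - 80) / 10, i.e. decades over 80
``female``            1 if sex == 'F'
``educ_*``            education dummies, reference level '<12 years' (``lt12``)
``apoe4``             APOE e4 carrier
``mci``               mild cognitive impairment at enrollment
``diabetes`` ...      midlife/cardiovascular comorbidity indicators, as-is
``charlson``          Charlson comorbidity index (integer, linear)
``marital_*``         marital dummies, reference level ``married``
``smoking_*``         smoking dummies, reference level ``never``
``alcohol``           diagnosed alcohol problem
``prior_exposure``    surgery with general anesthesia in 20 years pre-enrollment
====================  =========================================================

Age is modelled linearly and education as a 4-level ordinal factor; both are
modelling choices, not facts about the data.
"""

from __future__ import annotations

import pandas as pd

EDUCATION_LEVELS = ("lt12", "hs12", "coll13_15", "ge16")
MARITAL_LEVELS = ("married", "single", "widowed_divorced")
SMOKING_LEVELS = ("never", "former", "current")

BASELINE_COLUMNS = (
    "subject_id",
    "age_at_enrollment",
    "sex",
    "education_level",
    "apoe4",
    "mci_at_enrollment",
    "midlife_diabetes",
    "midlife_hypertension",
    "midlife_dyslipidemia",
    "atrial_fibrillation",
    "chf",
    "stroke",
    "cad",
    "charlson_index",
    "marital_status",
    "smoking_status",
    "alcohol_problem",
    "prior_20yr_exposure",
)

_SIMPLE_BINARY = {
    "apoe4": "apoe4",
    "mci": "mci_at_enrollment",
    "diabetes": "midlife_diabetes",
    "hypertension": "midlife_hypertension",
    "dyslipidemia": "midlife_dyslipidemia",
    "afib": "atrial_fibrillation",
    "chf": "chf",
    "stroke": "stroke",
    "cad": "cad",
    "alcohol": "alcohol_problem",
    "prior_exposure": "prior_20yr_exposure",
}

#: covariate set used by the default experiment configurations
DEFAULT_MODEL_COVARIATES = ("age_c", "female", "apoe4", "mci")

#: the full adjustment set
FULL_MODEL_COVARIATES = (
    "age_c",
    "female",
    "educ_hs12",
    "educ_coll13_15",
    "educ_ge16",
    "apoe4",
    "mci",
    "diabetes",
    "hypertension",
    "dyslipidemia",
    "afib",
    "chf",
    "stroke",
    "cad",
    "charlson",
    "marital_single",
    "marital_widowed_divorced",
    "smoking_former",
    "smoking_current",
    "alcohol",
    "prior_exposure",
)


def encode_baselines(baselines: pd.DataFrame, covariates) -> pd.DataFrame:
    """Encode a raw baseline table into numeric design columns.

    Returns a DataFrame indexed like ``baselines`` with one float column per
    requested encoded covariate, in the requested order.
    """
    def _dummy(column, level, levels, kind):
        if level not in levels:
            raise KeyError(f"unknown {kind} level {level!r}")
        values = baselines[column]
        seen = set(values.dropna().unique())
        if not seen <= set(levels):
            raise ValueError(f"unknown {kind} level(s) in data: {sorted(seen - set(levels))}")
        return (values.to_numpy() == level).astype(float)

    out = {}
    for name in covariates:
        if name == "age_c":
            out[name] = (baselines["age_at_enrollment"].to_numpy(float) - 80.0) / 10.0
        elif name == "female":
            sex = baselines["sex"]
            if not set(sex.dropna().unique()) <= {"F", "M"}:
                raise ValueError("sex must be coded F/M")
            out[name] = (sex.to_numpy() == "F").astype(float)
        elif name.startswith("educ_"):
            out[name] = _dummy("education_level", name[5:], EDUCATION_LEVELS, "education")
        elif name.startswith("marital_"):
            out[name] = _dummy("marital_status", name[8:], MARITAL_LEVELS, "marital")
        elif name.startswith("smoking_"):
            out[name] = _dummy("smoking_status", name[8:], SMOKING_LEVELS, "smoking")
        elif name == "charlson":
            out[name] = baselines["charlson_index"].to_numpy(float)
        elif name in _SIMPLE_BINARY:
            out[name] = baselines[_SIMPLE_BINARY[name]].to_numpy(float)
        else:
            raise KeyError(f"unknown encoded covariate {name!r}")
    return pd.DataFrame(out, index=baselines.index)
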