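"""Outcome kinds and their modelling transforms.

Prevalences are modelled on the logit scale; mean BMI and mean systolic
blood pressure are modelled on the natural (identity) scale.
"""

from __future__ import annotations

import numpy as np

MEAN_BMI = "mean_bmi"
MEAN_SBP = "mean_sbp"
PREV_OBESITY = "prev_obesity"
PREV_RAISED_BP = "prev_raised_bp"
PREV_DIABETES = "prev_diabetes"

OUTCOME_KINDS = (MEAN_BMI, MEAN_SBP, PREV_OBESITY, PREV_RAISED_BP, PREV_DIABETES)

#: residual person-level SD used for the sampling variance of a mean outcome
MEAN_OUTCOME_SD = {MEAN_BMI: 4.5, MEAN_SBP: 18.0}

#: minimum adult age modelled per outcome (BMI outcomes are reported for 20+)
MIN_AGE = {MEAN_BMI: 20, PREV_OBESITY: 20,
           MEAN_SBP: 18, PREV_RAISED_BP: 18, PREV_DIABETES: 18}


def validate_outcome(outcome_kind: str) -> str:
    if outcome_kind not in OUTCOME_KINDS:
        raise ValueError(f"unknown outcome kind {outcome_kind!r}; "
                         f"expected one of {OUTCOME_KINDS}")
    return outcome_kind


def is_prevalence(outcome_kind: str) -> bool:
    validate_outcome(outcome_kind)
    return outcome_kind.startswith("prev_")


def logit(p):
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log(p) - np.log1p(-p)  # +-inf outside (0, 1); callers validate


def expit(x):
    x = np.asarray(x, dtype=float)
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def to_transformed(value, outcome_kind: str):
    """Natural scale -> modelling scale (logit for prevalences)."""
    return logit(value) if is_prevalence(outcome_kind) else np.asarray(value, float)


def from_transformed(value, outcome_kind: str):
    """Modelling scale -> natural scale."""
    return expit(value) if is_prevalence(outcome_kind) else np.asarray(value, float)
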