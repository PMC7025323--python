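import numpy as np
import pytest

import cmtrends as ct
from cmtrends.model import ModelConfig, ParameterLayout, ParameterState, \
    build_model_data


@pytest.fixture(scope="session")
def small_hierarchy():
    """2 regions x 2 countries, 11 years — enough structure, fast."""
    return ct.make_hierarchy(2, [2, 2], years=(1995, 2005), seed=7)


@pytest.fixture(scope="session")
def small_covariates(small_hierarchy):
    return ct.generate_covariates(small_hierarchy, ("urbanisation",), seed=7)


@pytest.fixture(scope="session")
def small_truth(small_hierarchy, small_covariates):
    return ct.generate_truth(small_hierarchy, ct.GenerativeSettings(),
                             "prev_diabetes", seed=7,
                             covariates=small_covariates)


@pytest.fixture(scope="session")
def small_layout(small_hierarchy):
    cfg = ModelConfig(outcome_kind="prev_diabetes", covariates=(),
                      year_center=2000.0)
    return ParameterLayout(small_hierarchy, cfg)


@pytest.fixture(scope="session")
def small_model_data(small_hierarchy, small_covariates, small_truth):
    surveys = ct.sample_surveys(small_truth,
                                ct.SurveyDesign(studies_per_country=4), seed=3)
    cfg = ModelConfig(outcome_kind="prev_diabetes",
                      covariates=("urbanisation",), year_center=2000.0)
    return build_model_data(surveys[surveys["sex"] == "men"], small_hierarchy,
                            small_covariates, cfg)


def random_state(layout, rng, sd_floor=0.05):
    """A random valid ParameterState for density oracles."""
    coef = rng.normal(0, 0.3, layout.n_coef)
    sds = sd_floor + rng.random(layout.n_sd)
    return ParameterState(layout, coef, sds)


@pytest.fixture(scope="session")
def recovery_experiment():
    """The default parameter-recovery + shrinkage experiment (both sexes).

    This is the expensive session fixture backing the recovery, shrinkage
    and acceptance-rate checks; it runs the full default synthetic
    scenario at the 4 x 4000 test schedule.
    """
    from cmtrends.recovery import run_default_recovery
    return run_default_recovery(seed=1)
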