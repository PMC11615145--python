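import numpy as np
import pandas as pd
import pytest

import empdecomp as e
from empdecomp import synthetic as S
from empdecomp.config import MissingnessRule, SimulationConfig, coef_frame


@pytest.fixture(scope="session")
def default_cfg():
    return e.default_config(2000, seed=42)


@pytest.fixture(scope="session")
def full_cohort(default_cfg):
    """A complete (pre-missingness) default cohort with both profiles drawn."""
    co = S.generate_cohort(default_cfg)
    co = S.assign_employment(co)
    co = S.assign_mental_health(co)
    return co


@pytest.fixture(scope="session")
def fitted_models(default_cfg, full_cohort):
    df = full_cohort.truth
    med = e.fit_explanatory_model(df, default_cfg.confounder_names,
                                  default_cfg.employment_categories)
    out = e.fit_outcome_model(df, default_cfg.confounder_names,
                              default_cfg.employment_categories,
                              default_cfg.outcome_categories)
    return med, out


def binary_scenario_config() -> SimulationConfig:
    """No confounders; binary mediator and outcome with known conditionals.

    P(M=m2|woman)=0.5, P(M=m2|man)=0.1; P(Y=y1|W,m1)=0.8, P(Y=y1|W,m2)=0.4,
    P(Y=y1|man,m1)=0.7, P(Y=y1|man,m2)=0.3. By hand: natural prevalence of y1
    is 0.60 (women) vs 0.66 (men); counterfactual women 0.76.
    """
    ln = np.log
    med = coef_frame(("m1", "m2"), ["Intercept", "woman"],
                     {"m2": {"Intercept": ln(1 / 9), "woman": -ln(1 / 9)}})
    out = coef_frame(
        ("y0", "y1"),
        ["Intercept", "woman", "employment_profile[m2]",
         "woman:employment_profile[m2]"],
        {"y1": {
            "Intercept": ln(0.7 / 0.3),
            "woman": ln(0.8 / 0.2) - ln(0.7 / 0.3),
            "employment_profile[m2]": ln(0.3 / 0.7) - ln(0.7 / 0.3),
            "woman:employment_profile[m2]":
                (ln(0.4 / 0.6) - ln(0.8 / 0.2)) - (ln(0.3 / 0.7) - ln(0.7 / 0.3)),
        }})
    return SimulationConfig(
        n_respondents=4000, gender_prob=0.5, confounders=[],
        mediator_coefs=med, outcome_coefs=out,
        employment_categories=("m1", "m2"), outcome_categories=("y0", "y1"),
        profile_templates=None, quartile_score_ranges=None, seed=5)


@pytest.fixture()
def binary_cfg():
    return binary_scenario_config()


def analysis_frame(cfg, with_missing=True):
    """Latent analysis dataset (gender, confounders, profiles), optionally with
    missingness injected directly on the analysis variables."""
    co = S.assign_mental_health(S.assign_employment(S.generate_cohort(cfg)))
    if with_missing:
        co = S.inject_missingness(co, [
            MissingnessRule(("mh_profile",), 0.068),
            MissingnessRule(("education",), 0.046),
            MissingnessRule(("employment_profile",), 0.035),
        ])
    keep = ["gender"] + cfg.confounder_names + ["employment_profile", "mh_profile"]
    return co.frame[keep]
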