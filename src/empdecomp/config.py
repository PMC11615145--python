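"""Simulation configuration for synthetic survey cohorts.

The generator emulates a cross-sectional working-age household survey: a binary
gender variable, a set of categorical confounders, a 7-level employment profile
(four job-control quartiles among the employed plus three unemployment subtypes),
and a 4-level mental-health profile, with item-level nonresponse injected on top.
All model structure is multinomial-logistic with explicit, named design terms so
that the same coefficient matrices drive both the generator and the enumeration
oracle for the true decomposition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

GENDERS = ("man", "woman")

#: Canonical 7-level employment profile; first entry is the model reference.
EMPLOYMENT_CATEGORIES = (
    "Q1_highest_control",
    "Q2",
    "Q3",
    "Q4_lowest_control",
    "Unemployed_looking",
    "Unemployed_unable",
    "Unemployed_not_looking",
)

#: Canonical 4-level mental-health profile; first entry is the model reference.
OUTCOME_CATEGORIES = (
    "flourishing_no_stress",
    "flourishing_some_stress",
    "moderate_mh_stress",
    "clinical_mood_disorder",
)

JOB_CONTROL_ITEMS = (
    "learn_new_things",
    "high_skill",
    "freedom_how",
    "repetitive_tasks",
    "input_own_job",
)

WORK_STATUS_ITEMS = (
    "worked_past_2wk",
    "absent_sick_or_leave",
    "looking_for_work",
    "unable_to_work",
)

MH_BINARY_ITEMS = (
    "mood_disorder",
    "anxiety_disorder",
    "substance_use_disorder",
    "schizophrenia_psychosis",
    "eating_disorder",
    "suicidal_thoughts_attempts",
)

MH_ORDINAL_ITEMS = ("self_rated_mental_health", "life_stress", "positive_mental_health")

MH_ITEMS = MH_BINARY_ITEMS + MH_ORDINAL_ITEMS

POSITIVE_MH_LEVELS = ("languishing", "moderate", "flourishing")


class ConfigurationError(ValueError):
    """Raised when a simulation config is internally inconsistent."""


@dataclass(frozen=True)
class ConfounderSpec:
    """A categorical confounder with per-gender (or shared) marginals."""

    name: str
    labels: tuple[str, ...]
    probs: Mapping[str, tuple[float, ...]]  # keys: gender labels or "all"

    def probs_for(self, gender: str) -> np.ndarray:
        p = self.probs.get(gender, self.probs.get("all"))
        if p is None:
            raise ConfigurationError(f"no marginals for gender {gender!r} in {self.name}")
        return np.asarray(p, dtype=float)

    def validate(self) -> None:
        if len(self.labels) < 2:
            raise ConfigurationError(f"confounder {self.name} needs >= 2 labels")
        for key, p in self.probs.items():
            if key not in GENDERS and key != "all":
                raise ConfigurationError(f"unknown gender key {key!r} in {self.name}")
            arr = np.asarray(p, dtype=float)
            if len(arr) != len(self.labels):
                raise ConfigurationError(f"marginals/labels length mismatch in {self.name}")
            if (arr < 0).any() or (arr > 1).any():
                raise ConfigurationError(f"probabilities outside [0,1] in {self.name}")
            if abs(arr.sum() - 1.0) > 1e-8:
                raise ConfigurationError(f"marginals for {self.name} do not sum to 1")


@dataclass(frozen=True)
class MissingnessRule:
    """One nonresponse rule: set ``columns`` missing jointly for sampled rows.

    If ``logit_terms`` is given the per-row missingness probability is
    expit(sum of term values times coefficients), evaluated on the complete
    (latent) data — a missing-at-random mechanism. Otherwise ``rate`` applies
    uniformly (MCAR). ``where`` restricts the rule to rows matching the given
    column==value conditions (e.g. job-control items only for the employed).
    """

    columns: tuple[str, ...]
    rate: float = 0.0
    logit_terms: Mapping[str, float] | None = None
    where: Mapping[str, str] | None = None

    def validate(self) -> None:
        if not self.columns:
            raise ConfigurationError("missingness rule with no columns")
        if self.logit_terms is None and not 0.0 <= self.rate <= 1.0:
            raise ConfigurationError(f"missingness rate {self.rate} outside [0,1]")


@dataclass
class SimulationConfig:
    """Full description of the synthetic cohort generator.

    Coefficient matrices are DataFrames indexed by the non-reference categories
    with columns named after design terms ("Intercept", "woman",
    "age_group[35-44]", "employment_profile[Q4_lowest_control]",
    "woman:employment_profile[...]" ...). The reference category's linear
    predictor is fixed at zero.
    """

    n_respondents: int
    gender_prob: float  # P(gender == "woman")
    confounders: list[ConfounderSpec]
    mediator_coefs: pd.DataFrame
    outcome_coefs: pd.DataFrame
    employment_categories: tuple[str, ...] = EMPLOYMENT_CATEGORIES
    outcome_categories: tuple[str, ...] = OUTCOME_CATEGORIES
    missingness: list[MissingnessRule] = field(default_factory=list)
    profile_templates: dict | None = None
    quartile_score_ranges: dict[str, tuple[int, int]] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_respondents < 0:
            raise ConfigurationError("n_respondents must be >= 0")
        if not 0.0 <= self.gender_prob <= 1.0:
            raise ConfigurationError("gender_prob outside [0,1]")
        for c in self.confounders:
            c.validate()
        for rule in self.missingness:
            rule.validate()
        for cats, coefs, label in (
            (self.employment_categories, self.mediator_coefs, "mediator"),
            (self.outcome_categories, self.outcome_coefs, "outcome"),
        ):
            if len(cats) < 2:
                raise ConfigurationError(f"{label}: need >= 2 categories")
            expected = list(cats[1:])
            if list(coefs.index) != expected:
                raise ConfigurationError(
                    f"{label} coefficient rows {list(coefs.index)} != non-reference "
                    f"categories {expected}"
                )
            if not np.isfinite(coefs.to_numpy(dtype=float)).all():
                raise ConfigurationError(f"{label} coefficients must be finite")

    @property
    def confounder_names(self) -> list[str]:
        return [c.name for c in self.confounders]


def coef_frame(categories: Sequence[str], terms: Sequence[str],
               values: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Build a dense coefficient frame from a sparse {category: {term: value}} map."""
    out = pd.DataFrame(0.0, index=list(categories)[1:], columns=list(terms))
    for cat, row in values.items():
        for term, val in row.items():
            if cat not in out.index:
                raise ConfigurationError(f"unknown category {cat!r} in coefficient map")
            if term not in out.columns:
                raise ConfigurationError(f"unknown term {term!r} in coefficient map")
            out.loc[cat, term] = float(val)
    return out


# ---------------------------------------------------------------------------
# Default configuration
# ---------------------------------------------------------------------------

def _default_confounders() -> list[ConfounderSpec]:
    # Marginals approximate a 2012 Ontario working-age household survey sample;
    # education marginals are renormalized over observed categories.
    return [
        ConfounderSpec(
            "age_group",
            ("25-34", "35-44", "45-54", "55-64"),
            {
                "woman": (0.236, 0.219, 0.254, 0.291),
                "man": (0.196, 0.273, 0.240, 0.291),
            },
        ),
        ConfounderSpec(
            "region",
            ("urban", "rural"),
            {"woman": (0.841, 0.159), "man": (0.822, 0.178)},
        ),
        ConfounderSpec(
            "ethnicity",
            ("white", "racialized"),
            {"all": (0.780, 0.220)},
        ),
        ConfounderSpec(
            "education",
            ("less_than_secondary", "secondary", "some_postsecondary", "postsecondary"),
            {
                "woman": (0.0587, 0.1017, 0.0355, 0.8041),
                "man": (0.0624, 0.1273, 0.0354, 0.7749),
            },
        ),
        ConfounderSpec(
            "recent_immigrant",
            ("no", "yes"),
            {"woman": (0.929, 0.071), "man": (0.943, 0.057)},
        ),
        ConfounderSpec(
            "chronic_condition",
            ("no", "yes"),
            {"woman": (0.435, 0.565), "man": (0.490, 0.510)},
        ),
    ]


def _mediator_terms(confounders: list[ConfounderSpec]) -> list[str]:
    terms = ["Intercept", "woman"]
    for c in confounders:
        terms += [f"{c.name}[{lab}]" for lab in c.labels[1:]]
    return terms


def _outcome_terms(confounders: list[ConfounderSpec],
                   employment_categories: Sequence[str]) -> list[str]:
    terms = _mediator_terms(confounders)
    emp = [f"employment_profile[{c}]" for c in employment_categories[1:]]
    inter = [f"woman:employment_profile[{c}]" for c in employment_categories[1:]]
    return terms + emp + inter


def _default_mediator_coefs(confounders: list[ConfounderSpec]) -> pd.DataFrame:
    terms = _mediator_terms(confounders)
    # Intercepts/gender contrasts back-calculated from observed per-gender
    # employment-profile proportions; confounder effects are modest and the
    # intercepts are shifted to keep marginals near the observed table.
    values = {
        "Q2": {"Intercept": -0.15, "woman": 0.34},
        "Q3": {"Intercept": -0.10, "woman": 0.18},
        "Q4_lowest_control": {
            "Intercept": -0.14, "woman": 0.53,
            "education[postsecondary]": -0.30,
            "chronic_condition[yes]": 0.10, "region[rural]": 0.10,
        },
        "Unemployed_looking": {
            "Intercept": -1.56, "woman": 0.38,
            "recent_immigrant[yes]": 0.40,
        },
        "Unemployed_unable": {
            "Intercept": -2.10, "woman": 0.40,
            "chronic_condition[yes]": 0.90, "age_group[55-64]": 0.40,
        },
        "Unemployed_not_looking": {
            "Intercept": -0.87, "woman": 1.02,
            "age_group[55-64]": 0.70, "chronic_condition[yes]": 0.20,
            "education[postsecondary]": -0.30,
        },
    }
    return coef_frame(EMPLOYMENT_CATEGORIES, terms, values)


def _default_outcome_coefs(confounders: list[ConfounderSpec]) -> pd.DataFrame:
    terms = _outcome_terms(confounders, EMPLOYMENT_CATEGORIES)
    e = "employment_profile"
    values = {
        "flourishing_some_stress": {
            "Intercept": 0.16, "woman": 0.16,
            "chronic_condition[yes]": 0.15,
            f"{e}[Q2]": 0.05, f"{e}[Q3]": 0.10, f"{e}[Q4_lowest_control]": 0.20,
            f"{e}[Unemployed_looking]": 0.25, f"{e}[Unemployed_unable]": 0.30,
            f"{e}[Unemployed_not_looking]": 0.15,
            f"woman:{e}[Q4_lowest_control]": 0.15,
            f"woman:{e}[Unemployed_not_looking]": 0.30,
        },
        "moderate_mh_stress": {
            "Intercept": -0.62, "woman": -0.38,
            "chronic_condition[yes]": 0.35, "education[postsecondary]": -0.20,
            f"{e}[Q2]": 0.15, f"{e}[Q3]": 0.30, f"{e}[Q4_lowest_control]": 0.55,
            f"{e}[Unemployed_looking]": 0.70, f"{e}[Unemployed_unable]": 0.90,
            f"{e}[Unemployed_not_looking]": 0.35,
            f"woman:{e}[Unemployed_not_looking]": -0.20,
        },
        "clinical_mood_disorder": {
            "Intercept": -2.25, "woman": 0.47,
            "chronic_condition[yes]": 0.50, "education[postsecondary]": -0.30,
            "age_group[55-64]": -0.20,
            f"{e}[Q2]": 0.10, f"{e}[Q3]": 0.25, f"{e}[Q4_lowest_control]": 0.60,
            f"{e}[Unemployed_looking]": 0.90, f"{e}[Unemployed_unable]": 1.60,
            f"{e}[Unemployed_not_looking]": 0.60,
            f"woman:{e}[Q4_lowest_control]": 0.30,
            f"woman:{e}[Unemployed_unable]": 0.30,
        },
    }
    return coef_frame(OUTCOME_CATEGORIES, terms, values)


#: Per-profile conditional distributions of the nine raw indicators. Binary
#: indicators map to a Bernoulli probability; ordinal indicators map to a
#: {level: probability} dict. The blocks are well separated so that clustering
#: on the raw indicators can recover the generating profile.
DEFAULT_PROFILE_TEMPLATES: dict[str, dict] = {
    "flourishing_no_stress": {
        "mood_disorder": 0.01, "anxiety_disorder": 0.01,
        "substance_use_disorder": 0.01, "schizophrenia_psychosis": 0.002,
        "eating_disorder": 0.002, "suicidal_thoughts_attempts": 0.005,
        "self_rated_mental_health": {4: 0.20, 5: 0.80},
        "life_stress": {1: 0.90, 2: 0.10},
        "positive_mental_health": {"moderate": 0.03, "flourishing": 0.97},
    },
    "flourishing_some_stress": {
        "mood_disorder": 0.02, "anxiety_disorder": 0.04,
        "substance_use_disorder": 0.02, "schizophrenia_psychosis": 0.002,
        "eating_disorder": 0.005, "suicidal_thoughts_attempts": 0.01,
        "self_rated_mental_health": {3: 0.10, 4: 0.65, 5: 0.25},
        "life_stress": {3: 0.70, 4: 0.30},
        "positive_mental_health": {"moderate": 0.07, "flourishing": 0.93},
    },
    "moderate_mh_stress": {
        "mood_disorder": 0.07, "anxiety_disorder": 0.10,
        "substance_use_disorder": 0.07, "schizophrenia_psychosis": 0.01,
        "eating_disorder": 0.01, "suicidal_thoughts_attempts": 0.06,
        "self_rated_mental_health": {1: 0.05, 2: 0.55, 3: 0.40},
        "life_stress": {2: 0.10, 3: 0.40, 4: 0.40, 5: 0.10},
        "positive_mental_health": {"languishing": 0.35, "moderate": 0.63,
                                   "flourishing": 0.02},
    },
    "clinical_mood_disorder": {
        "mood_disorder": 0.95, "anxiety_disorder": 0.45,
        "substance_use_disorder": 0.12, "schizophrenia_psychosis": 0.03,
        "eating_disorder": 0.05, "suicidal_thoughts_attempts": 0.35,
        "self_rated_mental_health": {1: 0.35, 2: 0.45, 3: 0.20},
        "life_stress": {3: 0.20, 4: 0.45, 5: 0.35},
        "positive_mental_health": {"languishing": 0.50, "moderate": 0.48,
                                   "flourishing": 0.02},
    },
}

#: Latent job-control sum ranges per quartile used when back-filling Likert
#: items (score 5 = highest control ... 25 = lowest).
DEFAULT_QUARTILE_SCORE_RANGES = {
    "Q1_highest_control": (5, 9),
    "Q2": (10, 12),
    "Q3": (13, 15),
    "Q4_lowest_control": (16, 25),
}


def _default_missingness() -> list[MissingnessRule]:
    # Overall ~13% of rows end up with at least one missing analysis measure:
    # the mental-health block (6.8%), education (4.6%), and the job-control
    # items among the employed (3.5%).
    return [
        MissingnessRule(columns=MH_ITEMS, rate=0.068),
        MissingnessRule(columns=("education",), rate=0.046),
        MissingnessRule(columns=JOB_CONTROL_ITEMS, rate=0.035,
                        where={"worked_past_2wk": "yes"}),
    ]


def default_config(n_respondents: int = 2458, seed: int = 0) -> SimulationConfig:
    """The stock synthetic-survey configuration.

    Marginals emulate the descriptive tables of a working-age (25-64) Ontario
    household survey: 51.4% women, roughly a quarter of respondents presumed
    unemployed, and mental-health profile marginals near 26/44/17/6 percent.
    """
    confounders = _default_confounders()
    cfg = SimulationConfig(
        n_respondents=n_respondents,
        gender_prob=1263 / 2458,
        confounders=confounders,
        mediator_coefs=_default_mediator_coefs(confounders),
        outcome_coefs=_default_outcome_coefs(confounders),
        missingness=_default_missingness(),
        profile_templates=DEFAULT_PROFILE_TEMPLATES,
        quartile_score_ranges=DEFAULT_QUARTILE_SCORE_RANGES,
        seed=seed,
    )
    cfg.validate()
    return cfg


def null_gender_mediator_config(n_respondents: int = 2458, seed: int = 0) -> SimulationConfig:
    """Default config with the gender->employment pathway switched off.

    Used for null calibration: with no gender difference in the mediator model
    the counterfactual shift does nothing and the true percent change is zero.
    """
    cfg = default_config(n_respondents, seed)
    med = cfg.mediator_coefs.copy()
    med["woman"] = 0.0
    cfg.mediator_coefs = med
    return cfg


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def config_to_dict(cfg: SimulationConfig) -> dict:
    return {
        "n_respondents": cfg.n_respondents,
        "gender_prob": cfg.gender_prob,
        "seed": cfg.seed,
        "employment_categories": list(cfg.employment_categories),
        "outcome_categories": list(cfg.outcome_categories),
        "confounders": [
            {"name": c.name, "labels": list(c.labels),
             "probs": {k: list(map(float, v)) for k, v in c.probs.items()}}
            for c in cfg.confounders
        ],
        "mediator_coefs": {cat: {t: float(v) for t, v in row.items() if v != 0.0}
                           for cat, row in cfg.mediator_coefs.iterrows()},
        "mediator_terms": list(cfg.mediator_coefs.columns),
        "outcome_coefs": {cat: {t: float(v) for t, v in row.items() if v != 0.0}
                          for cat, row in cfg.outcome_coefs.iterrows()},
        "outcome_terms": list(cfg.outcome_coefs.columns),
        "missingness": [
            {"columns": list(r.columns), "rate": r.rate,
             "logit_terms": dict(r.logit_terms) if r.logit_terms else None,
             "where": dict(r.where) if r.where else None}
            for r in cfg.missingness
        ],
        "profile_templates": cfg.profile_templates,
        "quartile_score_ranges": (
            {k: list(v) for k, v in cfg.quartile_score_ranges.items()}
            if cfg.quartile_score_ranges else None
        ),
    }


def config_from_dict(d: dict) -> SimulationConfig:
    confounders = [
        ConfounderSpec(c["name"], tuple(c["labels"]),
                       {k: tuple(v) for k, v in c["probs"].items()})
        for c in d["confounders"]
    ]
    emp_cats = tuple(d.get("employment_categories", EMPLOYMENT_CATEGORIES))
    out_cats = tuple(d.get("outcome_categories", OUTCOME_CATEGORIES))
    med = coef_frame(emp_cats, d["mediator_terms"], d["mediator_coefs"])
    out = coef_frame(out_cats, d["outcome_terms"], d["outcome_coefs"])
    missingness = [
        MissingnessRule(tuple(r["columns"]), r.get("rate", 0.0),
                        r.get("logit_terms"), r.get("where"))
        for r in d.get("missingness", [])
    ]
    qsr = d.get("quartile_score_ranges")
    templates = d.get("profile_templates")
    if templates is not None:
        templates = {
            prof: {k: ({int(l) if isinstance(l, str) and l.isdigit() else l: p
                        for l, p in v.items()} if isinstance(v, dict) else v)
                   for k, v in spec.items()}
            for prof, spec in templates.items()
        }
    cfg = SimulationConfig(
        n_respondents=int(d["n_respondents"]),
        gender_prob=float(d["gender_prob"]),
        confounders=confounders,
        mediator_coefs=med,
        outcome_coefs=out,
        employment_categories=emp_cats,
        outcome_categories=out_cats,
        missingness=missingness,
        profile_templates=templates,
        quartile_score_ranges={k: (int(v[0]), int(v[1])) for k, v in qsr.items()} if qsr else None,
        seed=int(d.get("seed", 0)),
    )
    cfg.validate()
    return cfg


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))
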