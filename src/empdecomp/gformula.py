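"""Monte Carlo g-formula: natural-course and counterfactual simulation.

The decomposition asks how the women-minus-men gap in each mental-health
profile would change if women drew their employment profile from the men's
(confounder-specific) distribution. Both scenarios are simulated: per Monte
Carlo repetition each respondent draws an employment profile from the fitted
explanatory model and then a mental-health profile from the fitted outcome
model given the drawn employment. In the counterfactual scenario women's
employment draw uses the explanatory model with gender set to man; the outcome
draw always uses actual gender (so gender x employment interactions are
evaluated at gender = woman for women).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import CategoricalModel, SchemaError, build_design, softmax_probs


@dataclass
class ScenarioPrevalences:
    """Per-gender outcome prevalences under one simulated scenario."""

    scenario: str
    table: pd.DataFrame  # index: gender, columns: outcome categories
    reps: int
    seed: int | None

    def __post_init__(self):
        sums = self.table.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-10):
            raise ValueError(f"{self.scenario}: prevalences do not sum to 1 per gender")


def _draw(rng: np.random.Generator, probs: np.ndarray, u: np.ndarray | None = None) -> np.ndarray:
    if u is None:
        u = rng.random(len(probs))
    idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return np.minimum(idx, probs.shape[1] - 1)


def _check_schema(models, cohort: pd.DataFrame) -> None:
    med_model, out_model = models
    for term in med_model.terms + out_model.terms:
        for part in term.split(":"):
            if part in ("Intercept", "woman"):
                continue
            name = part.split("[")[0]
            if name != med_model.outcome and name not in cohort.columns:
                raise SchemaError(name)


def _simulate(models: tuple[CategoricalModel, CategoricalModel],
              cohort: pd.DataFrame, reps: int, seed: int | None,
              counterfactual: bool, common_random_numbers: bool = False,
              scenario_name: str = "") -> ScenarioPrevalences:
    med_model, out_model = models
    _check_schema(models, cohort)
    rng = np.random.default_rng(seed)
    n = len(cohort)
    med_cats = np.asarray(med_model.categories, dtype=object)
    out_cats = list(out_model.categories)

    if counterfactual:
        flipped = cohort.copy()
        flipped.loc[flipped["gender"] == "woman", "gender"] = "man"
        med_probs = med_model.predict_proba(flipped)
        woman = (cohort["gender"] == "woman").to_numpy()
        med_probs = np.where(woman[:, None], med_probs,
                             med_model.predict_proba(cohort))
    else:
        med_probs = med_model.predict_proba(cohort)

    genders = ("man", "woman")
    counts = {g: np.zeros(len(out_cats)) for g in genders}
    gmask = {g: (cohort["gender"] == g).to_numpy() for g in genders}

    # Precompute the static outcome-design columns; only the mediator dummies
    # (and their gender interactions) change between Monte Carlo draws.
    med_col = med_model.outcome
    dummy_re = re.compile(rf"^(woman:)?{re.escape(med_col)}\[(.+)\]$")
    work = cohort.copy()
    work[med_col] = med_model.categories[0]
    X = build_design(work, out_model.terms)
    dynamic: list[tuple[int, int, bool]] = []  # (column, mediator index, interacts)
    cat_pos = {c: i for i, c in enumerate(med_model.categories)}
    for j, term in enumerate(out_model.terms):
        m = dummy_re.match(term)
        if m:
            dynamic.append((j, cat_pos[m.group(2)], m.group(1) is not None))
        elif med_col in term:
            raise ValueError(f"unsupported mediator term {term!r} in outcome model")
    woman_vec = (cohort["gender"].to_numpy() == "woman").astype(float)
    B = out_model.coef.to_numpy(dtype=float).T

    for _ in range(reps):
        u_med = rng.random(n) if common_random_numbers else None
        m_idx = _draw(rng, med_probs, u_med)
        for j, mi, interacts in dynamic:
            col = (m_idx == mi).astype(float)
            X[:, j] = col * woman_vec if interacts else col
        out_probs = softmax_probs(X @ B)
        u_out = rng.random(n) if common_random_numbers else None
        k_idx = _draw(rng, out_probs, u_out)
        for g in genders:
            counts[g] += np.bincount(k_idx[gmask[g]], minlength=len(out_cats))
    table = pd.DataFrame.from_dict(
        {g: counts[g] / (gmask[g].sum() * reps) for g in genders},
        orient="index", columns=out_cats)
    return ScenarioPrevalences(scenario=scenario_name or
                               ("counterfactual" if counterfactual else "natural"),
                               table=table, reps=reps, seed=seed)


def simulate_natural_course(models: tuple[CategoricalModel, CategoricalModel],
                            cohort: pd.DataFrame, reps: int = 20,
                            seed: int | None = None,
                            common_random_numbers: bool = False) -> ScenarioPrevalences:
    """Simulate mediator and outcome at every respondent's actual gender."""
    return _simulate(models, cohort, reps, seed, counterfactual=False,
                     common_random_numbers=common_random_numbers, scenario_name="natural")


def simulate_counterfactual(models: tuple[CategoricalModel, CategoricalModel],
                            cohort: pd.DataFrame, reps: int = 20,
                            seed: int | None = None,
                            common_random_numbers: bool = False) -> ScenarioPrevalences:
    """Women draw employment from the men's model; outcomes at actual gender."""
    return _simulate(models, cohort, reps, seed, counterfactual=True,
                     common_random_numbers=common_random_numbers,
                     scenario_name="counterfactual")


def mc_prevalence_se(models: tuple[CategoricalModel, CategoricalModel],
                     cohort: pd.DataFrame, reps: int,
                     counterfactual: bool = False) -> pd.DataFrame:
    """Exact Monte Carlo standard error of each simulated prevalence.

    Given the models and cohort, each respondent-repetition outcome draw is an
    independent categorical variable with marginal probability
    q_i(k) = sum_m P(m|i) P(k|i,m), so the prevalence estimator's variance is
    sum_i q_i(1-q_i) / (n_g * reps)^2 within gender g.
    """
    med_model, out_model = models
    # per-row marginal outcome probabilities under the requested scenario
    if counterfactual:
        flipped = cohort.copy()
        flipped.loc[flipped["gender"] == "woman", "gender"] = "man"
        woman = (cohort["gender"] == "woman").to_numpy()
        med_probs = np.where(woman[:, None], med_model.predict_proba(flipped),
                             med_model.predict_proba(cohort))
    else:
        med_probs = med_model.predict_proba(cohort)
    q = np.zeros((len(cohort), len(out_model.categories)))
    work = cohort.copy()
    for mi, mcat in enumerate(med_model.categories):
        work[med_model.outcome] = mcat
        q += med_probs[:, mi][:, None] * out_model.predict_proba(work)
    rows = {}
    for g in ("man", "woman"):
        mask = (cohort["gender"] == g).to_numpy()
        var = (q[mask] * (1 - q[mask])).sum(axis=0) / (mask.sum() ** 2 * reps)
        rows[g] = np.sqrt(var)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(out_model.categories))


def percent_change(rd_natural: float, rd_counterfactual: float) -> float:
    """Relative reduction (+) or widening (-) of the gap, in percent.

    (|RD_nat| - |RD_cf|) / |RD_nat| * 100. Undefined (NaN) when RD_nat is 0.
    """
    if rd_natural == 0:
        return float("nan")
    return (abs(rd_natural) - abs(rd_counterfactual)) / abs(rd_natural) * 100.0


def risk_differences(natural: pd.DataFrame | ScenarioPrevalences,
                     counterfactual: pd.DataFrame | ScenarioPrevalences) -> pd.DataFrame:
    """Women-minus-men risk differences per 1000 and the percent change.

    Input frames are gender x outcome prevalence tables (or
    :class:`ScenarioPrevalences`); both must share the outcome categories.
    """
    nat = natural.table if isinstance(natural, ScenarioPrevalences) else natural
    cf = (counterfactual.table if isinstance(counterfactual, ScenarioPrevalences)
          else counterfactual)
    if list(nat.columns) != list(cf.columns):
        raise ValueError("scenario outcome categories differ")
    rd_nat = (nat.loc["woman"] - nat.loc["man"]) * 1000.0
    rd_cf = (cf.loc["woman"] - cf.loc["man"]) * 1000.0
    pct = [percent_change(a, b) for a, b in zip(rd_nat, rd_cf)]
    return pd.DataFrame({
        "rd_natural": rd_nat,
        "rd_counterfactual": rd_cf,
        "pct_change": pct,
    })
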