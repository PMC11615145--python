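"""Synthetic survey-cohort generator with a known true decomposition.

The generator draws gender, categorical confounders, a 7-level employment
profile (multinomial logistic in gender + confounders), and a 4-level
mental-health profile (multinomial logistic in gender, confounders, employment
and gender x employment), then back-fills raw survey items consistent with the
drawn categories and finally injects item-level nonresponse. Because every
variable is categorical, the implied natural-course and counterfactual
prevalences — and hence the true risk differences the pipeline estimates — can
be computed exactly by enumeration (:func:`oracle_decomposition`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    GENDERS,
    JOB_CONTROL_ITEMS,
    MH_BINARY_ITEMS,
    ConfigurationError,
    MissingnessRule,
    SimulationConfig,
)
from .models import CategoricalModel, build_design, softmax_probs

# fixed per-purpose RNG streams, so toggling one stage leaves the others alone
_STREAMS = {"cohort": 0, "mediator": 1, "outcome": 2, "missingness": 3}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(config.seed), spawn_key=(_STREAMS[stream],)))


@dataclass
class SyntheticCohort:
    """Generated microdata: observed frame, latent truth, and provenance."""

    frame: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.frame)


def _draw_categorical(rng: np.random.Generator, probs: np.ndarray,
                      labels: tuple[str, ...]) -> np.ndarray:
    """Vectorized draw of one label per row from an n x K probability matrix."""
    u = rng.random(len(probs))
    idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    idx = np.minimum(idx, len(labels) - 1)  # guard against cumsum rounding
    return np.asarray(labels, dtype=object)[idx]


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw gender and confounders for ``n_respondents`` rows."""
    config.validate()
    rng = _rng(config, "cohort")
    n = config.n_respondents
    gender = np.where(rng.random(n) < config.gender_prob, "woman", "man").astype(object)
    data = {"respondent_id": np.arange(n), "gender": gender}
    for spec in config.confounders:
        col = np.empty(n, dtype=object)
        for g in GENDERS:
            mask = gender == g
            p = spec.probs_for(g)
            if mask.any():
                cum = p.cumsum()
                u = rng.random(int(mask.sum()))
                idx = np.minimum((cum < u[:, None]).sum(axis=1), len(spec.labels) - 1)
                col[mask] = np.asarray(spec.labels, dtype=object)[idx]
            else:
                rng.random(0)
        data[spec.name] = col
    truth = pd.DataFrame(data)
    return SyntheticCohort(frame=truth.copy(), truth=truth, config=config)


def mediator_model(config: SimulationConfig) -> CategoricalModel:
    """The generator's true explanatory model as a :class:`CategoricalModel`."""
    return CategoricalModel(
        outcome="employment_profile",
        categories=tuple(config.employment_categories),
        terms=list(config.mediator_coefs.columns),
        coef=config.mediator_coefs.copy(),
    )


def outcome_model(config: SimulationConfig) -> CategoricalModel:
    """The generator's true outcome model."""
    return CategoricalModel(
        outcome="mh_profile",
        categories=tuple(config.outcome_categories),
        terms=list(config.outcome_coefs.columns),
        coef=config.outcome_coefs.copy(),
    )


def category_probabilities(df: pd.DataFrame, coefs: pd.DataFrame,
                           categories: tuple[str, ...]) -> np.ndarray:
    """Softmax probabilities for arbitrary coefficient matrices (ref lp = 0)."""
    X = build_design(df, list(coefs.columns))
    eta = X @ coefs.to_numpy(dtype=float).T
    if not np.isfinite(eta).all():
        raise FloatingPointError("non-finite linear predictor")
    return softmax_probs(eta)


def _likert_with_sum(rng: np.random.Generator, totals: np.ndarray) -> np.ndarray:
    """Random 5-vectors of values in 1..5 with given row sums (uniform-ish)."""
    n = len(totals)
    out = np.empty((n, 5), dtype=int)
    rem = totals.astype(int).copy()
    for i in range(5):
        left = 4 - i
        lo = np.maximum(1, rem - 5 * left)
        hi = np.minimum(5, rem - left)
        draw = lo + (rng.random(n) * (hi - lo + 1)).astype(int)
        draw = np.minimum(draw, hi)
        out[:, i] = draw
        rem -= draw
    return out


def assign_employment(cohort: SyntheticCohort,
                      coefs: pd.DataFrame | None = None) -> SyntheticCohort:
    """Draw the employment profile and back-fill consistent raw items."""
    config = cohort.config
    if coefs is None:
        coefs = config.mediator_coefs
    rng = _rng(config, "mediator")
    truth = cohort.truth.copy()
    cats = tuple(config.employment_categories)
    probs = category_probabilities(truth, coefs, cats)
    truth["employment_profile"] = _draw_categorical(rng, probs, cats)

    if config.quartile_score_ranges is not None:
        _backfill_employment_items(truth, config, rng)
    frame = truth.copy()
    return SyntheticCohort(frame=frame, truth=truth, config=config)


def _backfill_employment_items(truth: pd.DataFrame, config: SimulationConfig,
                               rng: np.random.Generator) -> None:
    n = len(truth)
    emp = truth["employment_profile"].to_numpy()
    quartiles = set(config.quartile_score_ranges)
    employed = np.isin(emp, list(quartiles))

    worked = np.full(n, "no", dtype=object)
    absent = np.full(n, "no", dtype=object)
    looking = np.full(n, "no", dtype=object)
    unable = np.full(n, "no", dtype=object)
    # a small share of the employed were absent on sick leave rather than at work
    on_leave = employed & (rng.random(n) < 0.05)
    worked[employed & ~on_leave] = "yes"
    absent[on_leave] = "yes"
    looking[emp == "Unemployed_looking"] = "yes"
    unable[emp == "Unemployed_unable"] = "yes"
    truth["worked_past_2wk"] = worked
    truth["absent_sick_or_leave"] = absent
    truth["looking_for_work"] = looking
    truth["unable_to_work"] = unable

    # Likert back-fill: draw a latent job-control sum within the category's
    # range, then a random item composition with that sum. 'repetitive_tasks'
    # is stored reverse-coded relative to its control contribution.
    for col in JOB_CONTROL_ITEMS:
        truth[col] = np.nan
    totals = np.zeros(n, dtype=int)
    for q, (lo, hi) in config.quartile_score_ranges.items():
        mask = emp == q
        totals[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    comp = _likert_with_sum(rng, np.where(employed, totals, 5))
    items = comp.astype(float)
    items[:, 3] = 6 - items[:, 3]  # store the raw (non-reversed) answer
    for j, col in enumerate(JOB_CONTROL_ITEMS):
        vals = np.where(employed, items[:, j], np.nan)
        truth[col] = vals


def assign_mental_health(cohort: SyntheticCohort,
                         coefs: pd.DataFrame | None = None) -> SyntheticCohort:
    """Draw the mental-health profile and back-fill the nine raw indicators."""
    config = cohort.config
    if "employment_profile" not in cohort.truth.columns:
        raise ValueError("assign_employment must run before assign_mental_health")
    if coefs is None:
        coefs = config.outcome_coefs
    rng = _rng(config, "outcome")
    truth = cohort.truth.copy()
    cats = tuple(config.outcome_categories)
    probs = category_probabilities(truth, coefs, cats)
    truth["mh_profile"] = _draw_categorical(rng, probs, cats)

    if config.profile_templates is not None:
        _backfill_mh_items(truth, config, rng)
    return SyntheticCohort(frame=truth.copy(), truth=truth, config=config)


def _backfill_mh_items(truth: pd.DataFrame, config: SimulationConfig,
                       rng: np.random.Generator) -> None:
    n = len(truth)
    prof = truth["mh_profile"].to_numpy()
    templates = config.profile_templates
    missing = [p for p in np.unique(prof) if p not in templates]
    if missing:
        raise ConfigurationError(f"no indicator template for profiles {missing}")
    items: dict[str, np.ndarray] = {}
    for col in MH_BINARY_ITEMS:
        p = np.array([templates[pr][col] for pr in prof], dtype=float)
        items[col] = (rng.random(n) < p).astype(int)
    for col in ("self_rated_mental_health", "life_stress", "positive_mental_health"):
        out = np.empty(n, dtype=object)
        for pr in templates:
            mask = prof == pr
            dist = templates[pr][col]
            levels = list(dist.keys())
            pvec = np.asarray(list(dist.values()), dtype=float)
            pvec = pvec / pvec.sum()
            if mask.any():
                u = rng.random(int(mask.sum()))
                idx = np.minimum((pvec.cumsum() < u[:, None]).sum(axis=1), len(levels) - 1)
                out[mask] = np.asarray(levels, dtype=object)[idx]
            else:
                rng.random(0)
        items[col] = out
    for col, vals in items.items():
        truth[col] = vals


def inject_missingness(cohort: SyntheticCohort,
                       rules: list[MissingnessRule] | None = None) -> SyntheticCohort:
    """Blank out cells per the missingness spec; truth is retained."""
    config = cohort.config
    if rules is None:
        rules = config.missingness
    rng = _rng(config, "missingness")
    frame = cohort.truth.copy()
    from scipy.special import expit

    for rule in rules:
        rule.validate()
        for col in rule.columns:
            if col not in frame.columns:
                raise ConfigurationError(f"missingness rule targets unknown column {col!r}")
        eligible = np.ones(len(frame), dtype=bool)
        if rule.where:
            for col, val in rule.where.items():
                eligible &= cohort.truth[col].astype(object).to_numpy() == val
        if rule.logit_terms is not None:
            lp = np.zeros(len(frame))
            for term, beta in rule.logit_terms.items():
                lp += beta * _term_value(cohort.truth, term)
            p = expit(lp)
        else:
            p = np.full(len(frame), rule.rate)
        hit = eligible & (rng.random(len(frame)) < p)
        frame.loc[hit, list(rule.columns)] = np.nan
    return SyntheticCohort(frame=frame, truth=cohort.truth, config=config)


def _term_value(df: pd.DataFrame, term: str) -> np.ndarray:
    return build_design(df, [term])[:, 0]


# ---------------------------------------------------------------------------
# Enumeration oracle
# ---------------------------------------------------------------------------

def confounder_cells(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Per gender: all confounder combinations with their exact probabilities."""
    out = {}
    for g in GENDERS:
        frames = [pd.DataFrame({"gender": [g], "_w": [1.0]})]
        cells = frames[0]
        for spec in config.confounders:
            p = spec.probs_for(g)
            add = pd.DataFrame({spec.name: list(spec.labels), "_p": p})
            cells = cells.merge(add, how="cross")
            cells["_w"] = cells["_w"] * cells.pop("_p")
        out[g] = cells.reset_index(drop=True)
    return out


def exact_prevalences(med_model: CategoricalModel, out_model: CategoricalModel,
                      df: pd.DataFrame, weights: np.ndarray | None = None,
                      mediator_col: str = "employment_profile") -> dict[str, pd.DataFrame]:
    """Closed-form natural-course and counterfactual prevalences.

    For each row the mediator distribution is taken from ``med_model`` and the
    outcome distribution from ``out_model`` marginalized over the mediator:
    P(k | row) = sum_m P(m | row) P(k | row, m). Rows are weighted within
    gender (uniform when ``weights`` is None). In the counterfactual scenario
    women take their mediator distribution from the men's model (gender
    flipped in the mediator model only); the outcome model keeps actual gender.

    Returns {"natural": ..., "counterfactual": ...} frames indexed by gender
    with one column per outcome category.
    """
    genders = ("man", "woman")
    if weights is None:
        weights = np.ones(len(df))
    weights = np.asarray(weights, dtype=float)

    med_nat = med_model.predict_proba(df)
    flipped = df.copy()
    flipped.loc[flipped["gender"] == "woman", "gender"] = "man"
    med_cf_all = med_model.predict_proba(flipped)
    is_woman = (df["gender"] == "woman").to_numpy()
    med_cf = np.where(is_woman[:, None], med_cf_all, med_nat)

    def marginal_outcome(med_probs: np.ndarray) -> np.ndarray:
        acc = np.zeros((len(df), len(out_model.categories)))
        work = df.copy()
        for mi, mcat in enumerate(med_model.categories):
            work[mediator_col] = mcat
            acc += med_probs[:, mi][:, None] * out_model.predict_proba(work)
        return acc

    out_nat = marginal_outcome(med_nat)
    out_cf = marginal_outcome(med_cf)

    result = {}
    for name, mat in (("natural", out_nat), ("counterfactual", out_cf)):
        rows = {}
        for g in genders:
            mask = (df["gender"] == g).to_numpy()
            w = weights[mask]
            rows[g] = (w[:, None] * mat[mask]).sum(axis=0) / w.sum()
        result[name] = pd.DataFrame.from_dict(rows, orient="index",
                                              columns=list(out_model.categories))
    return result


@dataclass
class OracleDecomposition:
    """Exact decomposition implied by a simulation config."""

    prevalences: dict[str, pd.DataFrame]   # scenario -> gender x outcome
    table: pd.DataFrame                    # per outcome: rd_natural, rd_counterfactual, pct_change


def oracle_decomposition(config: SimulationConfig) -> OracleDecomposition:
    """Enumerate the exact natural-course and counterfactual decomposition.

    prev(g, k) = sum_c P(c|g) sum_m P(m|g,c) P(k|g,c,m); the counterfactual
    replaces P(m|woman,c) with P(m|man,c). Requires a finite (all-categorical)
    confounder space.
    """
    from .gformula import risk_differences  # local import avoids a cycle

    cells = confounder_cells(config)
    df = pd.concat([cells["man"], cells["woman"]], ignore_index=True)
    weights = df.pop("_w").to_numpy()
    prev = exact_prevalences(mediator_model(config), outcome_model(config),
                             df, weights)
    table = risk_differences(prev["natural"], prev["counterfactual"])
    return OracleDecomposition(prevalences=prev, table=table)
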