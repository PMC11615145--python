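"""Multinomial-logistic models with named design terms.

Both stages of the decomposition use the same model family: a multinomial
logistic regression with the first category as reference. The explanatory
(mediator) model regresses the 7-level employment profile on gender and the
confounders; the outcome model regresses the 4-level mental-health profile on
gender, confounders, employment-profile dummies and gender x employment
interactions. Terms are identified by name so fitted models, generator
coefficient matrices and the enumeration oracle all share one design builder.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
import warnings

_DUMMY_RE = re.compile(r"^([A-Za-z_]\w*)\[(.+)\]$")


class PositivityError(ValueError):
    """A category required by the model has no observations."""


class SchemaError(KeyError):
    """Data frame does not carry the columns a model expects."""


def _atom(df: pd.DataFrame, term: str) -> np.ndarray:
    if term == "Intercept":
        return np.ones(len(df))
    if term == "woman":
        if "gender" not in df.columns:
            raise SchemaError("gender")
        return (df["gender"].to_numpy() == "woman").astype(float)
    m = _DUMMY_RE.match(term)
    if m:
        name, label = m.groups()
        if name not in df.columns:
            raise SchemaError(name)
        return (df[name].astype(object).to_numpy() == label).astype(float)
    if term in df.columns:
        return df[term].to_numpy(dtype=float)
    raise SchemaError(term)


def build_design(df: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Evaluate named terms into an n x p design matrix.

    A ``:`` in a term denotes a product of atomic terms (interaction).
    """
    X = np.empty((len(df), len(terms)))
    for j, term in enumerate(terms):
        col = np.ones(len(df))
        for part in term.split(":"):
            col = col * _atom(df, part)
        X[:, j] = col
    return X


def softmax_probs(eta_nonref: np.ndarray) -> np.ndarray:
    """Category probabilities with the reference linear predictor fixed at 0.

    ``eta_nonref`` is n x (K-1); returns n x K with the reference first.
    """
    eta = np.column_stack([np.zeros(len(eta_nonref)), eta_nonref])
    eta -= eta.max(axis=1, keepdims=True)
    ex = np.exp(eta)
    return ex / ex.sum(axis=1, keepdims=True)


@dataclass
class CategoricalModel:
    """A fitted (or constructed) reference-coded multinomial logistic model."""

    outcome: str
    categories: tuple[str, ...]          # first = reference
    terms: list[str]
    coef: pd.DataFrame                   # (K-1) x terms, indexed by category
    converged: bool = True
    ridge_used: bool = False
    loglik: float = float("nan")
    _design_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if list(self.coef.index) != list(self.categories[1:]):
            raise ValueError("coefficient rows must match non-reference categories")
        if list(self.coef.columns) != list(self.terms):
            raise ValueError("coefficient columns must match terms")
        if not np.isfinite(self.coef.to_numpy(dtype=float)).all():
            raise ValueError("non-finite coefficients")

    def linear_predictors(self, df: pd.DataFrame) -> np.ndarray:
        X = build_design(df, self.terms)
        return X @ self.coef.to_numpy(dtype=float).T

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        """n x K matrix of category probabilities (columns follow ``categories``)."""
        return softmax_probs(self.linear_predictors(df))


def fit_categorical(df: pd.DataFrame, outcome: str, terms: list[str],
                    categories: tuple[str, ...],
                    ridge_fallback_C: float = 100.0,
                    tol: float = 1e-7) -> CategoricalModel:
    """Maximum-likelihood multinomial fit with a ridge fallback.

    Raises :class:`PositivityError` naming any declared category absent from
    the data. If the unpenalized fit fails to converge or shows signs of
    separation (runaway coefficients), the model is refit with a small L2
    penalty and flagged via ``ridge_used``.
    """
    if outcome not in df.columns:
        raise SchemaError(outcome)
    y = df[outcome].astype(object).to_numpy()
    present = pd.unique(y[pd.notna(y)])
    missing_cats = [c for c in categories if c not in present]
    if missing_cats:
        raise PositivityError(
            f"{outcome}: no observations in categories {missing_cats}")
    unknown = [c for c in present if c not in categories]
    if unknown:
        raise PositivityError(f"{outcome}: unknown categories {unknown}")

    X = build_design(df, terms)
    code = {c: i for i, c in enumerate(categories)}
    yi = np.array([code[v] for v in y])

    def _fit(C):
        # C = inf gives the unpenalized maximum-likelihood fit
        clf = LogisticRegression(C=C, solver="newton-cg",
                                 fit_intercept=False, max_iter=2000, tol=tol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X, yi)
        return clf

    clf = _fit(np.inf)
    coef = _reference_coded(clf, categories)
    converged = int(np.max(clf.n_iter_)) < 2000
    ridge_used = False
    if not converged or np.abs(coef).max() > 15.0:
        clf = _fit(ridge_fallback_C)
        coef = _reference_coded(clf, categories)
        converged = int(np.max(clf.n_iter_)) < 2000
        ridge_used = True

    model = CategoricalModel(
        outcome=outcome, categories=tuple(categories), terms=list(terms),
        coef=pd.DataFrame(coef, index=list(categories[1:]), columns=list(terms)),
        converged=converged, ridge_used=ridge_used,
    )
    probs = model.predict_proba(df)
    model.loglik = float(np.log(probs[np.arange(len(yi)), yi] + 1e-300).sum())
    return model


def _reference_coded(clf: LogisticRegression, categories: tuple[str, ...]) -> np.ndarray:
    """Convert scikit-learn's symmetric multinomial coding to reference coding."""
    if len(clf.classes_) == 2:
        # binary special case: one coefficient row, for classes_[1] vs classes_[0]
        full = np.zeros((len(categories), clf.coef_.shape[1]))
        full[int(clf.classes_[1])] = clf.coef_[0]
        return full[1:] - full[0]
    full = np.zeros((len(categories), clf.coef_.shape[1]))
    for row, cls in zip(clf.coef_, clf.classes_):
        full[int(cls)] = row
    return full[1:] - full[0]


def coef_standard_errors(model: CategoricalModel, df: pd.DataFrame) -> pd.DataFrame:
    """Asymptotic SEs from the observed information of the reference-coded fit."""
    X = build_design(df, model.terms)
    P = model.predict_proba(df)[:, 1:]  # n x (K-1)
    n, p = X.shape
    k1 = P.shape[1]
    info = np.zeros((k1 * p, k1 * p))
    for a in range(k1):
        for b in range(a, k1):
            w = P[:, a] * ((a == b) - P[:, b])
            block = (X * w[:, None]).T @ X
            info[a * p:(a + 1) * p, b * p:(b + 1) * p] = block
            if b != a:
                info[b * p:(b + 1) * p, a * p:(a + 1) * p] = block
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.diag(cov)).reshape(k1, p)
    return pd.DataFrame(se, index=model.coef.index, columns=model.coef.columns)


# ---------------------------------------------------------------------------
# The two analysis models
# ---------------------------------------------------------------------------

def mediator_term_list(confounder_names_labels: list[tuple[str, list[str]]]) -> list[str]:
    terms = ["Intercept", "woman"]
    for name, labels in confounder_names_labels:
        terms += [f"{name}[{lab}]" for lab in labels[1:]]
    return terms


def _confounder_levels(df: pd.DataFrame, confounders: list[str]) -> list[tuple[str, list[str]]]:
    out = []
    for name in confounders:
        if name not in df.columns:
            raise SchemaError(name)
        levels = sorted(df[name].dropna().astype(str).unique())
        out.append((name, levels))
    return out


def fit_explanatory_model(df: pd.DataFrame, confounders: list[str],
                          employment_categories: tuple[str, ...],
                          mediator_col: str = "employment_profile") -> CategoricalModel:
    """Employment profile ~ gender + confounders."""
    terms = mediator_term_list(_confounder_levels(df, confounders))
    return fit_categorical(df, mediator_col, terms, employment_categories)


def fit_outcome_model(df: pd.DataFrame, confounders: list[str],
                      employment_categories: tuple[str, ...],
                      outcome_categories: tuple[str, ...],
                      outcome_col: str = "mh_profile",
                      mediator_col: str = "employment_profile") -> CategoricalModel:
    """Mental-health profile ~ gender + confounders + employment + gender x employment."""
    terms = mediator_term_list(_confounder_levels(df, confounders))
    terms += [f"{mediator_col}[{c}]" for c in employment_categories[1:]]
    terms += [f"woman:{mediator_col}[{c}]" for c in employment_categories[1:]]
    # positivity on the mediator too: every employment level must be observed
    obs = set(df[mediator_col].dropna().astype(str))
    empty = [c for c in employment_categories if c not in obs]
    if empty:
        raise PositivityError(f"{mediator_col}: no observations in categories {empty}")
    return fit_categorical(df, outcome_col, terms, outcome_categories)
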