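"""Multiple imputation of categorical item nonresponse by chained equations.

Each incomplete variable is modelled by a multinomial logistic regression on
all other analysis variables; missing cells are initialized by draws from the
observed marginals and then updated for a fixed number of cycles by drawing
from each fitted conditional's predictive distribution. The m imputations use
independent RNG streams, so the procedure is reproducible given the seed.
Drawing from the predictive distribution without a posterior draw of the
coefficients understates between-imputation variance slightly; the pipeline
pools final estimates by averaging, not coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression


@dataclass
class ImputationSpec:
    """Knobs of the chained-equation imputer."""

    m: int = 20
    n_cycles: int = 10
    variables: list[str] | None = None   # default: every column with a missing cell
    predictors: list[str] | None = None  # default: all other spec/analysis columns
    seed: int = 0

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


def _onehot(df: pd.DataFrame, columns: list[str]) -> np.ndarray:
    X = pd.get_dummies(df[columns].astype(object), columns=columns, dtype=float)
    return np.column_stack([np.ones(len(df)), X.to_numpy()])


def _fit_draw(rng: np.random.Generator, X_obs, y_obs, X_mis) -> np.ndarray:
    """Fit a (lightly ridged) multinomial conditional and draw for missing rows."""
    classes, y_codes = np.unique(y_obs, return_inverse=True)
    if len(classes) == 1:
        return np.full(len(X_mis), classes[0], dtype=object)
    # a loose tolerance is plenty for predictive draws
    clf = LogisticRegression(solver="newton-cg", max_iter=100, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X_obs, y_codes)
    probs = clf.predict_proba(X_mis)
    u = rng.random(len(X_mis))
    idx = np.minimum((probs.cumsum(axis=1) < u[:, None]).sum(axis=1), len(classes) - 1)
    return classes[clf.classes_[idx].astype(int)]


def impute(data: pd.DataFrame, spec: ImputationSpec) -> list[pd.DataFrame]:
    """Return ``spec.m`` completed copies of ``data``.

    Observed cells are bit-identical across all outputs; only cells missing in
    the input are filled. Raises if a target variable has no observed value.
    """
    spec.validate()
    variables = spec.variables
    if variables is None:
        variables = [c for c in data.columns if data[c].isna().any()]
    for v in variables:
        if v not in data.columns:
            raise KeyError(f"unknown imputation variable {v!r}")
        if data[v].isna().all():
            raise ValueError(f"variable {v!r} is 100% missing; no model can be fit")
    if not variables or not any(data[v].isna().any() for v in variables):
        return [data.copy() for _ in range(spec.m)]

    predictors = spec.predictors
    if predictors is None:
        predictors = [c for c in data.columns if c != "respondent_id"]

    masks = {v: data[v].isna().to_numpy() for v in variables}
    marginals = {v: data[v].dropna() for v in variables}

    out = []
    for i in range(spec.m):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=int(spec.seed), spawn_key=(i,)))
        work = data.copy()
        # initialize by marginal draws (keeping each column's dtype intact)
        for v in variables:
            miss = masks[v]
            if miss.any():
                pool = marginals[v].to_numpy()
                _fill(work, v, miss, rng.choice(pool, size=int(miss.sum()),
                                                replace=True))
        for _ in range(spec.n_cycles):
            for v in variables:
                miss = masks[v]
                if not miss.any():
                    continue
                others = [c for c in predictors if c != v]
                X = _onehot(work, others)
                y = data[v].to_numpy(dtype=object)
                drawn = _fit_draw(rng, X[~miss], y[~miss], X[miss])
                _fill(work, v, miss, drawn)
        out.append(work)
    return out


def _fill(work: pd.DataFrame, v: str, miss: np.ndarray, values) -> None:
    col = work[v].to_numpy(copy=True)
    col[miss] = values
    work[v] = pd.Series(col, index=work.index).astype(work[v].dtype)
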