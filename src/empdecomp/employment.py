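"""Derivation of the 7-level employment profile from raw survey items.

Respondents reporting paid work in the prior two weeks (or absence from a job
due to sickness or leave) are employed and classified into quartiles of a
summed 5-item job-control score; the remainder are split into three
unemployment subtypes. The job-control items are Likert 1-5 (strongly agree to
strongly disagree) and the repetitive-tasks item is reverse coded, so a lower
sum means higher control and quartile 1 is the highest-control group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import JOB_CONTROL_ITEMS

QUARTILE_LABELS = ("Q1_highest_control", "Q2", "Q3", "Q4_lowest_control")
UNEMPLOYED_LABELS = ("Unemployed_looking", "Unemployed_unable", "Unemployed_not_looking")

_LIKERT = {1.0, 2.0, 3.0, 4.0, 5.0}


def reverse_code(x):
    """Map agreement x in 1..5 to 6-x (an involution on the Likert scale)."""
    return 6 - x


def job_control_score(items: pd.DataFrame) -> pd.Series:
    """Summed job-control score in [5, 25]; lower = higher control.

    ``items`` must carry the five Likert columns. The repetitive-tasks item is
    reverse coded before summing. Any missing item yields a missing score.
    """
    vals = {}
    for col in JOB_CONTROL_ITEMS:
        if col not in items.columns:
            raise KeyError(f"missing job-control item column {col!r}")
        v = pd.to_numeric(items[col], errors="coerce")
        ok = v.dropna()
        if not set(ok.unique()).issubset(_LIKERT):
            bad = sorted(set(ok.unique()) - _LIKERT)
            raise ValueError(f"{col}: values outside the 1-5 Likert scale: {bad}")
        vals[col] = v
    score = (vals["learn_new_things"] + vals["high_skill"] + vals["freedom_how"]
             + reverse_code(vals["repetitive_tasks"]) + vals["input_own_job"])
    score.name = "job_control_score"
    return score


def quartile_cutpoints(scores) -> np.ndarray:
    """Empirical 25th/50th/75th percentiles (linear interpolation)."""
    arr = np.asarray(pd.Series(scores).dropna(), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute quartile cutpoints from an empty collection")
    return np.percentile(arr, [25, 50, 75])


def assign_quartiles(scores, cutpoints: np.ndarray | None = None) -> pd.Series:
    """Map job-control scores to quartile labels using <=-cutpoint rules.

    Cutpoints default to the empirical quartiles of the supplied scores.
    Scores tied with a cutpoint go to the lower-numbered quartile, so constant
    input maps everything to Q1. Missing scores yield missing labels.
    """
    s = pd.Series(scores, dtype=float)
    if cutpoints is None:
        cutpoints = quartile_cutpoints(s)
    p25, p50, p75 = (float(c) for c in cutpoints)
    out = pd.Series(pd.NA, index=s.index, dtype=object)
    notna = s.notna()
    v = s[notna]
    lab = np.select(
        [v <= p25, v <= p50, v <= p75],
        QUARTILE_LABELS[:3],
        default=QUARTILE_LABELS[3],
    )
    out[notna] = lab
    out.name = "job_control_quartile"
    return out


def _yes(col: pd.Series) -> np.ndarray:
    return col.astype(object).to_numpy() == "yes"


def _no(col: pd.Series) -> np.ndarray:
    return col.astype(object).to_numpy() == "no"


def derive_employment_profile(frame: pd.DataFrame,
                              population_scores=None) -> pd.Series:
    """Classify every row into one of the 7 employment-profile categories.

    Employment branch: worked in the past two weeks, or absent on
    sickness/leave, then quartile of the job-control score (cutpoints from
    ``population_scores`` when given, otherwise from the employed rows of
    ``frame`` itself). Unemployment branch with precedence unable > looking >
    not-looking ('unable to work' makes job-search answers uninterpretable).
    Rows whose work status cannot be resolved get a missing profile.
    """
    n = len(frame)
    worked = frame["worked_past_2wk"]
    absent = frame["absent_sick_or_leave"]
    employed = _yes(worked) | _yes(absent)
    unemployed = _no(worked) & _no(absent)
    # neither branch resolvable (a needed item missing) -> missing profile

    out = pd.Series(pd.NA, index=frame.index, dtype=object)

    scores = job_control_score(frame)
    scores[~employed] = np.nan
    if population_scores is not None:
        cuts = quartile_cutpoints(population_scores)
    else:
        if scores.notna().any():
            cuts = quartile_cutpoints(scores)
        else:
            cuts = None
    if cuts is not None:
        quart = assign_quartiles(scores, cuts)
        out[employed] = quart[employed]
    # employed rows with a missing score stay missing (imputation handles them)

    unable = _yes(frame["unable_to_work"])
    looking = _yes(frame["looking_for_work"])
    neither = _no(frame["unable_to_work"]) & _no(frame["looking_for_work"])
    out[unemployed & unable] = "Unemployed_unable"
    out[unemployed & ~unable & looking] = "Unemployed_looking"
    out[unemployed & neither & ~looking] = "Unemployed_not_looking"
    # unemployed rows with unresolvable search/ability answers stay missing
    unresolved = unemployed & ~unable & ~looking & ~neither
    out[unresolved] = pd.NA

    out.name = "employment_profile"
    assert len(out) == n
    return out


def add_employment_profile(frame: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``frame`` with the derived employment_profile column."""
    out = frame.copy()
    out["employment_profile"] = derive_employment_profile(frame)
    return out
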