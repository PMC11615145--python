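"""Descriptive tables, standardized differences, and the pipeline driver.

Renders Table-1/2-style gender crosstabs ("97 (7.7%)" cells, one-decimal
half-up rounding), computes multi-category standardized differences, and wires
the whole pipeline together: generate -> derive employment -> cluster
mental-health indicators -> (impute inside) Boot-MI decomposition -> report
bundle as delimited text plus a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, employment, synthetic
from .bootmi import UncertaintySpec, boot_mi_decomposition
from .config import SimulationConfig, default_config
from .models import SchemaError

log = logging.getLogger(__name__)

ANALYSIS_VARIABLES = ("employment_profile", "mh_profile", "education")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (matches how survey tables print percents)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(count: int, denom: int, decimals: int = 1) -> str:
    """Render a table cell like ``97 (7.7%)``."""
    if denom == 0:
        return f"{count} (-)"
    pct = round_half_up(100.0 * count / denom, decimals)
    return f"{count} ({pct:.{decimals}f}%)"


def filter_working_age(df: pd.DataFrame, age_column: str = "age",
                       low: int = 25, high: int = 64) -> pd.DataFrame:
    """Eligibility filter: keep respondents aged ``low``..``high`` inclusive."""
    age = pd.to_numeric(df[age_column], errors="coerce")
    return df.loc[(age >= low) & (age <= high)].copy()


def fraction_rows_missing(df: pd.DataFrame, columns) -> float:
    """Share of rows missing at least one of the given measures."""
    cols = [c for c in columns if c in df.columns]
    if not cols:
        return 0.0
    return float(df[cols].isna().any(axis=1).mean())


def crosstab_by_gender(data: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Counts and percents of ``variable`` by gender, missing reported apart.

    Denominators are the per-gender counts of non-missing values, matching how
    descriptive survey tables are printed.
    """
    if variable not in data.columns:
        raise SchemaError(variable)
    rows = []
    groups = {"woman": data[data["gender"] == "woman"],
              "man": data[data["gender"] == "man"],
              "overall": data}
    observed = data[variable].dropna()
    cats = sorted(observed.astype(str).unique())
    denoms = {g: int(sub[variable].notna().sum()) for g, sub in groups.items()}
    for cat in cats:
        row = {"variable": variable, "category": cat}
        for g, sub in groups.items():
            cnt = int((sub[variable].astype(object) == cat).sum())
            row[f"{g}_n"] = cnt
            row[f"{g}_pct"] = round_half_up(100.0 * cnt / denoms[g], 1) if denoms[g] else 0.0
            row[f"{g}_cell"] = format_percent(cnt, denoms[g])
        rows.append(row)
    miss = {"variable": variable, "category": "(missing)"}
    for g, sub in groups.items():
        cnt = int(sub[variable].isna().sum())
        miss[f"{g}_n"] = cnt
        miss[f"{g}_pct"] = round_half_up(100.0 * cnt / len(sub), 1) if len(sub) else 0.0
        miss[f"{g}_cell"] = format_percent(cnt, len(sub))
    rows.append(miss)
    return pd.DataFrame(rows)


def standardized_difference(data: pd.DataFrame, variable: str,
                            group: str = "gender",
                            groups: tuple[str, str] = ("woman", "man")) -> float:
    """Standardized difference between two groups for a categorical variable.

    For two categories: d = (p1 - p2) / sqrt((p1(1-p1) + p2(1-p2)) / 2).
    For K > 2: the Mahalanobis generalization d = sqrt(T' S^-1 T) with T the
    K-1 prevalence differences and S the average of the two multinomial
    covariance matrices. Invariant to which category is omitted.
    """
    sub = data[[group, variable]].dropna()
    cats = sorted(sub[variable].astype(str).unique())
    if len(cats) < 2:
        raise ValueError(f"{variable}: need >= 2 observed categories")
    p = {}
    for g in groups:
        vals = sub.loc[sub[group] == g, variable].astype(str)
        if len(vals) == 0:
            raise ValueError(f"no observations for group {g!r}")
        p[g] = np.array([float((vals == c).mean()) for c in cats])
    p1, p2 = p[groups[0]], p[groups[1]]
    if len(cats) == 2:
        a, b = p1[1], p2[1]
        denom = np.sqrt((a * (1 - a) + b * (1 - b)) / 2.0)
        if denom == 0:
            return 0.0 if a == b else float("inf")
        return float(abs(a - b) / denom)
    t = (p1 - p2)[:-1]
    s = (_multinomial_cov(p1) + _multinomial_cov(p2)) / 2.0
    try:
        sol = np.linalg.solve(s, t)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            f"{variable}: singular covariance; consider collapsing sparse categories"
        ) from err
    return float(np.sqrt(max(t @ sol, 0.0)))


def _multinomial_cov(p: np.ndarray) -> np.ndarray:
    q = p[:-1]
    return np.diag(q) - np.outer(q, q)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(config: SimulationConfig | None = None, mode: str = "full",
                 out_dir: str | Path = "results",
                 uspec: UncertaintySpec | None = None,
                 derive_from_items: bool = True) -> dict:
    """Execute the requested pipeline stages and write the report bundle.

    Modes: ``simulate`` (cohort files only), ``describe`` (adds the derived
    profiles and descriptive tables), ``decompose``/``full`` (adds the Boot-MI
    decomposition, Table-3-style). Numeric outputs are deterministic given the
    config seed and the uncertainty spec.
    """
    t0 = time.time()
    if mode not in {"simulate", "describe", "decompose", "full"}:
        raise ValueError(f"unknown mode {mode!r}")
    config = config or default_config()
    uspec = uspec or UncertaintySpec(seed=config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"mode": mode, "seed": config.seed,
                      "n_respondents": config.n_respondents}

    cohort = synthetic.generate_cohort(config)
    cohort = synthetic.assign_employment(cohort)
    cohort = synthetic.assign_mental_health(cohort)
    cohort = synthetic.inject_missingness(cohort)
    log.info("stage=simulate rows=%d seed=%d", len(cohort), config.seed)
    cohort.frame.to_csv(out / "cohort.csv", index=False)
    cohort.truth.to_csv(out / "cohort_truth.csv", index=False)
    manifest["rows"] = int(len(cohort))
    if mode == "simulate":
        return _finish(out, manifest, t0)

    frame = cohort.frame
    analysis = frame.copy()
    if derive_from_items and config.quartile_score_ranges is not None:
        analysis["employment_profile"] = employment.derive_employment_profile(frame)
    if derive_from_items and config.profile_templates is not None:
        mh, composition = clustering.derive_mh_profiles(frame)
        analysis["mh_profile"] = mh
        composition.to_csv(out / "profile_composition.csv")
    log.info("stage=derive rows=%d", len(analysis))

    confounders = config.confounder_names
    keep = ["respondent_id", "gender"] + confounders + ["employment_profile", "mh_profile"]
    analysis = analysis[keep]
    analysis.to_csv(out / "analysis.csv", index=False)

    table1 = pd.concat([crosstab_by_gender(analysis, v) for v in confounders],
                       ignore_index=True)
    table2_parts = []
    for v in ("employment_profile", "mh_profile"):
        tab = crosstab_by_gender(analysis, v)
        tab["standardized_difference"] = round_half_up(
            standardized_difference(analysis, v), 2)
        table2_parts.append(tab)
    table2 = pd.concat(table2_parts, ignore_index=True)
    table1.to_csv(out / "table1.csv", index=False)
    table2.to_csv(out / "table2.csv", index=False)
    manifest["missing_any_pct"] = round_half_up(
        100 * fraction_rows_missing(analysis, confounders + list(ANALYSIS_VARIABLES)), 1)
    if mode == "describe":
        return _finish(out, manifest, t0)

    result = boot_mi_decomposition(
        analysis.drop(columns=["respondent_id"]), confounders,
        config.employment_categories, config.outcome_categories, uspec)
    table3 = result.table.round(6)
    table3.index.name = "outcome"
    table3.to_csv(out / "table3.csv")
    manifest.update(result.manifest)
    log.info("stage=decompose dropped=%d", result.n_dropped)
    return _finish(out, manifest, t0, result=result)


def _finish(out: Path, manifest: dict, t0: float, result=None) -> dict:
    manifest["wall_clock_s"] = round(time.time() - t0, 3)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle = {"manifest": manifest, "out_dir": str(out)}
    if result is not None:
        bundle["decomposition"] = result
    return bundle
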