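"""Boot-MI uncertainty: bootstrap first, impute within each resample.

The nesting mirrors the estimation procedure itself: for each bootstrap
resample of respondents, m imputed datasets are created; within each imputed
dataset the explanatory and outcome models are refit and the Monte Carlo
g-formula is run, averaging risk differences over the Monte Carlo repetitions;
the per-resample estimate averages over the imputations, and the 2.5th/97.5th
percentiles of the per-resample estimates are the confidence limits. Point
estimates come from the same nested procedure applied to the original
(non-resampled) data. Resamples that lose an entire mediator or outcome
category are dropped with a warning and the drop count is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .gformula import risk_differences, simulate_counterfactual, simulate_natural_course
from .impute import ImputationSpec, impute
from .models import PositivityError, fit_explanatory_model, fit_outcome_model

log = logging.getLogger(__name__)


@dataclass
class UncertaintySpec:
    """Counts of the three nested repetition layers plus seeding/parallelism."""

    n_bootstrap: int = 100
    m_imputations: int = 20
    mc_reps: int = 20
    impute_cycles: int = 10
    seed: int = 0
    n_jobs: int = 1

    def validate(self) -> None:
        for name in ("n_bootstrap", "m_imputations", "mc_reps", "impute_cycles"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class DecompositionResult:
    """Point estimates with bootstrap percentile intervals, per outcome."""

    table: pd.DataFrame          # point rd_natural/rd_counterfactual/pct_change + CI bounds
    replicates: pd.DataFrame     # per kept bootstrap replicate, long format
    n_dropped: int
    spec: UncertaintySpec
    manifest: dict = field(default_factory=dict)


def _estimate_once(df: pd.DataFrame, confounders: list[str],
                   employment_categories, outcome_categories,
                   uspec: UncertaintySpec, seed_seq: np.random.SeedSequence) -> pd.DataFrame:
    """One full MI x MC estimate on one dataset: per-outcome RDs and % change."""
    imp_seed, mc_seed = (int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(2))
    if df.isna().any().any():
        datasets = impute(df, ImputationSpec(m=uspec.m_imputations,
                                             n_cycles=uspec.impute_cycles,
                                             seed=imp_seed))
    else:
        datasets = [df]
    rng = np.random.default_rng(mc_seed)
    rd_nat = []
    rd_cf = []
    for completed in datasets:
        med = fit_explanatory_model(completed, confounders, employment_categories)
        out = fit_outcome_model(completed, confounders, employment_categories,
                                outcome_categories)
        s_nat = int(rng.integers(2**31))
        s_cf = int(rng.integers(2**31))
        nat = simulate_natural_course((med, out), completed, uspec.mc_reps, s_nat)
        cf = simulate_counterfactual((med, out), completed, uspec.mc_reps, s_cf)
        rd = risk_differences(nat, cf)
        rd_nat.append(rd["rd_natural"])
        rd_cf.append(rd["rd_counterfactual"])
    rd_nat = pd.concat(rd_nat, axis=1).mean(axis=1)
    rd_cf = pd.concat(rd_cf, axis=1).mean(axis=1)
    from .gformula import percent_change

    pct = pd.Series([percent_change(a, b) for a, b in zip(rd_nat, rd_cf)],
                    index=rd_nat.index)
    return pd.DataFrame({"rd_natural": rd_nat, "rd_counterfactual": rd_cf,
                         "pct_change": pct})


def _replicate(b: int, df: pd.DataFrame, confounders, employment_categories,
               outcome_categories, uspec: UncertaintySpec) -> pd.DataFrame | None:
    # per-replicate seeds keyed by replicate index, not scheduling order
    ss = np.random.SeedSequence(entropy=int(uspec.seed), spawn_key=(1, b))
    rng = np.random.default_rng(ss.generate_state(1)[0] % (2**31))
    idx = rng.integers(0, len(df), size=len(df))
    resample = df.iloc[idx].reset_index(drop=True)
    try:
        est = _estimate_once(resample, confounders, employment_categories,
                             outcome_categories, uspec, ss.spawn(1)[0])
    except PositivityError as err:
        log.warning("bootstrap replicate %d dropped: %s", b, err)
        return None
    est = est.copy()
    est["replicate"] = b
    return est


def boot_mi_decomposition(data: pd.DataFrame, confounders: list[str],
                          employment_categories, outcome_categories,
                          uspec: UncertaintySpec) -> DecompositionResult:
    """Full Boot-MI x Monte-Carlo decomposition with percentile intervals.

    ``data`` is the analysis dataset (gender, confounders, employment_profile,
    mh_profile) with its missingness intact; imputation runs inside every
    bootstrap resample.
    """
    uspec.validate()
    point = _estimate_once(data, confounders, employment_categories,
                           outcome_categories, uspec,
                           np.random.SeedSequence(entropy=int(uspec.seed), spawn_key=(0,)))

    run = delayed(_replicate)
    jobs = (run(b, data, confounders, employment_categories, outcome_categories, uspec)
            for b in range(uspec.n_bootstrap))
    if uspec.n_jobs != 1:
        results = Parallel(n_jobs=uspec.n_jobs)(jobs)
    else:
        results = [_replicate(b, data, confounders, employment_categories,
                              outcome_categories, uspec)
                   for b in range(uspec.n_bootstrap)]
    kept = [r for r in results if r is not None]
    n_dropped = uspec.n_bootstrap - len(kept)
    if not kept:
        raise RuntimeError("every bootstrap replicate failed the positivity check")
    reps = pd.concat([r.rename_axis("outcome").reset_index() for r in kept],
                     ignore_index=True)

    table = point.copy()
    for col in ("rd_natural", "rd_counterfactual", "pct_change"):
        stats = reps.pivot(index="replicate", columns="outcome", values=col)
        lo = stats.quantile(0.025, interpolation="linear")
        hi = stats.quantile(0.975, interpolation="linear")
        table[f"{col}_lo"] = lo.reindex(table.index)
        table[f"{col}_hi"] = hi.reindex(table.index)
    return DecompositionResult(
        table=table, replicates=reps, n_dropped=n_dropped, spec=uspec,
        manifest={"seed": uspec.seed, "n_bootstrap": uspec.n_bootstrap,
                  "m_imputations": uspec.m_imputations, "mc_reps": uspec.mc_reps,
                  "impute_cycles": uspec.impute_cycles, "n_dropped": n_dropped,
                  "n_rows": int(len(data))},
    )


def percentile_interval(values, lo: float = 2.5, hi: float = 97.5) -> tuple[float, float]:
    """Linear-interpolation percentile bounds of a collection of statistics."""
    arr = np.asarray(list(values), dtype=float)
    return (float(np.percentile(arr, lo)), float(np.percentile(arr, hi)))
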