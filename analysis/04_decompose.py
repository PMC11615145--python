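"""Run the Boot-MI Monte Carlo g-formula decomposition.

Fits the explanatory model (employment ~ gender + confounders) and the outcome
model (profile ~ gender + confounders + employment + gender x employment) and
simulates the natural-course and counterfactual scenarios, with multiple
imputation of item nonresponse inside each bootstrap resample. Compares the
point estimates with the generator's exact enumeration oracle and writes the
Table-3-style report.
"""

import sys
from pathlib import Path

import pandas as pd

import empdecomp as e

OUT = Path("results")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    analysis = pd.read_csv(OUT / "analysis.csv")
    cfg = e.default_config(seed=SEED)
    # a moderate spec keeps this driver interactive; the full published-style
    # nesting is (100 bootstraps, 20 imputations, 20 MC repetitions)
    uspec = e.UncertaintySpec(n_bootstrap=40, m_imputations=2, mc_reps=10,
                              impute_cycles=2, seed=SEED)
    res = e.boot_mi_decomposition(
        analysis.drop(columns=["respondent_id"]), cfg.confounder_names,
        cfg.employment_categories, cfg.outcome_categories, uspec)
    oracle = e.oracle_decomposition(cfg).table

    table = res.table.copy()
    table["oracle_rd_natural"] = oracle["rd_natural"]
    table.index.name = "outcome"
    table.round(4).to_csv(OUT / "table3.csv")

    print(f"Boot-MI: {uspec.n_bootstrap} bootstraps x {uspec.m_imputations} "
          f"imputations x {uspec.mc_reps} MC reps; {res.n_dropped} replicates dropped")
    cols = ["rd_natural", "rd_natural_lo", "rd_natural_hi",
            "rd_counterfactual", "pct_change", "oracle_rd_natural"]
    print(table[cols].round(1).to_string())
    covered = ((table["rd_natural_lo"] <= table["oracle_rd_natural"])
               & (table["oracle_rd_natural"] <= table["rd_natural_hi"]))
    print(f"oracle natural-course RD inside the 95% interval: "
          f"{int(covered.sum())}/4 profiles")
    print("wrote results/table3.csv")


if __name__ == "__main__":
    main()
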