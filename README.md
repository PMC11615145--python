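# empdecomp

Causal decomposition of gender differences in multidimensional mental-health
profiles attributable to employment profile, for epidemiologists and social
scientists studying work as a determinant of mental health.

## The question and the method

Working-age women and men differ in how mental health presents: women are more
often in a *clinical mood disorder* profile, men more often *flourishing
without life stress* or showing *moderate mental health and stress*. They also
differ in employment — women are more often out of the labour force and, when
employed, hold jobs with lower job control. How much of the mental-health gap
would change **if women had men's distribution of employment profiles**, given
their own confounder values?

The package answers this with a Monte Carlo implementation of the parametric
g-formula:

1. **Explanatory model** — multinomial logistic regression of the 7-level
   employment profile *M* (4 job-control quartiles among the employed + 3
   unemployment subtypes) on gender *G* and confounders *C*:
   P(M = m | G, C).
2. **Outcome model** — multinomial logistic regression of the 4-level
   mental-health profile *Y* on gender, confounders, employment, and a
   gender × employment interaction: P(Y = k | G, C, M).
3. **Natural course** — for every respondent, draw M then Y from the fitted
   models at their actual gender; the risk difference per outcome k is
   RD_k = (prev_women,k − prev_men,k) × 1000.
4. **Counterfactual** — women draw M from the explanatory model with gender
   set to *man* (their own confounders), then draw Y at their actual gender
   with the counterfactual M. Percent change
   = (|RD_nat| − |RD_cf|)/|RD_nat| × 100: positive means employment explains
   part of the gap, negative means it suppresses it.
5. **Uncertainty (Boot MI)** — bootstrap respondents; *inside* each resample,
   multiply impute item nonresponse (chained multinomial conditionals), run
   the Monte Carlo loop per imputed dataset, and average; the 2.5th/97.5th
   percentiles of the replicate estimates are the confidence limits.

The survey data the design mirrors are confidential, so the package ships a
**synthetic-data generator** with the same schema (raw employment items,
nine mental-health indicators, categorical confounders, ~13% item-level
nonresponse) and — because every variable is categorical — an **exact
enumeration oracle** for the true decomposition, against which the whole
pipeline is validated.

Derivation of the analysis variables from raw items is part of the package:
summed job-control scores (reverse-coded repetitive-tasks item) quartiled
among the employed, and mental-health profiles from Gower dissimilarity + PAM
(k = 4) clustering of the nine indicators with composition-based labelling.

## Worked example

```python
import empdecomp as e

cfg = e.default_config(n_respondents=2458, seed=1)
oracle = e.oracle_decomposition(cfg)          # exact truth by enumeration
print(oracle.table.round(1))
```

```
                         rd_natural  rd_counterfactual  pct_change
flourishing_no_stress         -28.5              -19.8        30.4
flourishing_some_stress        79.2               71.2        10.0
moderate_mh_stress            -85.0              -83.1         2.2
clinical_mood_disorder         34.3               31.7         7.6
```

Under the default generator, 34.3 per 1000 more women than men fall in the
clinical mood disorder profile; if women drew their employment profile from
the men's distribution the gap would shrink to 31.7 per 1000, i.e. employment
explains 7.6% of it. The estimation pipeline recovers these numbers from
simulated microdata:

```bash
python analysis/01_simulate_cohort.py 1   # cohort with raw items + nonresponse
python analysis/02_derive_profiles.py     # job-control quartiles, Gower+PAM profiles
python analysis/03_describe.py            # Table-1/2 style crosstabs
python analysis/04_decompose.py 1         # Boot-MI decomposition (Table-3 style)
python analysis/05_oracle_checks.py       # Monte Carlo vs enumeration calibration
```

`04_decompose.py` prints, for example (seed 1):

```
                         rd_natural  rd_natural_lo  rd_natural_hi  rd_counterfactual  pct_change  oracle_rd_natural
flourishing_no_stress         -13.0          -49.0           18.9               -9.2        29.0              -28.5
flourishing_some_stress        76.1           48.8          126.8               77.7        -2.1               79.2
moderate_mh_stress            -90.6         -117.6          -62.6              -87.7         3.3              -85.0
clinical_mood_disorder         27.5            5.4           38.4               19.2        30.2               34.3
oracle natural-course RD inside the 95% interval: 4/4 profiles
```

A `empdecomp` console script runs the same pipeline end to end
(`empdecomp --mode full --seed 1 --out-dir results`).

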