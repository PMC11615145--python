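# Methods

## Estimand and identification

The target is a counterfactual disparity reduction: for each of four
mental-health profiles, the change in the women-minus-men prevalence gap
(risk difference per 1000) if women kept their own confounder values but drew
their employment profile from the men's confounder-specific distribution.
Identification rests on conditional exchangeability given the measured
confounders (age band, geographic region, ethnicity, education,
recent-immigrant status, any physical chronic condition), positivity in every
confounder × gender cell used by the models, and consistency. Because the
mediator distribution is *shifted* rather than decomposed into natural
direct/indirect paths, exposure-induced mediator–outcome confounders do not
invalidate the estimand; they are simply part of the outcome model's
conditioning set.

Both models are multinomial logistic regressions with reference coding
(reference mediator: highest-control quartile; reference outcome: flourishing
with no life stress; gender indicator 1 = woman). The outcome model includes
six employment dummies and six gender × employment products. Results are
invariant to the reference choices. Age enters as a categorical band; this
keeps the confounder space finite so the generator's implied decomposition can
be enumerated exactly.

## Monte Carlo g-formula

Per Monte Carlo repetition, each respondent draws an employment profile from
the fitted explanatory model and then an outcome from the fitted outcome model
at the drawn employment; prevalences average over respondents × repetitions
within gender. In the counterfactual scenario women's mediator draw sets the
gender term of the explanatory model to *man*; the outcome draw keeps gender
*woman* (so the interaction terms are evaluated at woman). Draws in the two
scenarios are independent, matching the procedure the estimator emulates; a
common-random-numbers mode (shared uniforms) exists for variance-reduction
experiments and is off by default.

The default repetition counts mirror the published procedure: 20 Monte Carlo
repetitions × 20 imputations × 100 bootstraps, all configurable. Risk
differences are averaged over repetitions, then over imputations; percent
change is computed from the averaged RDs per bootstrap replicate.

Percent change uses (|RD_nat| − |RD_cf|)/|RD_nat| × 100 (positive = gap
explained/reduced; negative = gap suppressed/widened). The published verbal
definition is sign-ambiguous; this convention reproduces the published table's
printed values from its printed RDs for the first two profiles exactly and for
the remaining two up to last-digit rounding of already-rounded inputs. When
RD_nat = 0 the percent change is reported as NaN, never fabricated.

## Uncertainty: Boot MI

Bootstrap first, impute within each resample: each of B resamples (with
replacement, individual respondents, unstratified) is imputed m times; models
are refit per imputed dataset; the replicate estimate averages RDs over Monte
Carlo repetitions and imputations. Confidence limits are the 2.5th/97.5th
percentiles (linear interpolation between order statistics) of the replicate
estimates; the point estimate applies the identical nested procedure to the
original sample, so percentile intervals need not bracket it. Replicates in
which a resample loses an entire mediator or outcome category fail the
positivity check and are dropped with a logged warning and a reported count;
re-drawing would bias toward common configurations. Replicate seeds derive
from the master seed by replicate index, so results are bit-reproducible
including under parallel execution.

Small bootstrap counts make percentile endpoints noisy and systematically
short; B = 100 (the procedure's default) or more is recommended, and the
calibration tests use B = 100.

## Multiple imputation

Chained equations over the categorical analysis variables: each incomplete
variable gets a multinomial-logistic conditional on all other analysis
variables, missing cells are initialized from observed marginals and updated
for a fixed number of cycles (default 10) by draws from the fitted predictive
distribution. The conditionals carry scikit-learn's default L2 penalty, which
stabilizes sparse cells; coefficients are not redrawn from their posterior, so
between-imputation variance is somewhat understated — acceptable here because
the pipeline pools final estimates by averaging and takes uncertainty from the
bootstrap, not from Rubin's rules. In the pipeline the derived categorical
analysis variables (employment profile, mental-health profile, education) are
imputed directly; re-deriving profiles from imputed raw items inside every
bootstrap × imputation cell would require re-clustering per cell at
prohibitive cost and with unstable labels.

## Derived variables

**Job control**: five Likert items (1 = strongly agree … 5 = strongly
disagree; repetitive-tasks reverse-coded as 6 − x) summed to 5–25, lower =
more control. Quartile cutpoints are the empirical 25th/50th/75th percentiles
(linear interpolation) of the employed respondents' scores in the dataset at
hand; scores tied with a cutpoint go to the lower quartile, making the map
deterministic. Respondents with no paid work and no sickness/leave absence are
unemployed, split with precedence unable > looking > not-looking — "unable to
work" makes job-search answers uninterpretable, and the precedence is a
declared decision rather than survey intent.

**Mental-health profiles**: Gower dissimilarity over nine indicators — six
binary flags matched symmetrically (a shared absence counts as a match; the
asymmetric-binary variant is a documented alternative, not used), two 5-point
ordinals and one 3-level ordinal normalized by range, variables missing in
either row dropped pairwise with renormalization. PAM with classic BUILD +
SWAP, deterministic via lowest-index tie-breaking; k is fixed at 4, with a
mean-silhouette diagnostic available. Clusters are named by composition:
highest mood-disorder prevalence → clinical mood disorder; lowest flourishing
prevalence among the rest → moderate mental health and stress; remaining two
split by mean life stress. Ties raise an error naming the tied statistic.

## Synthetic data generator

The generator emulates the survey the design targets: 2458 respondents aged
25–64, 51.4% women, categorical confounder marginals per gender matching the
published descriptive table, employment-profile intercepts and gender
contrasts back-calculated from the published per-gender proportions (women
more often unemployed-not-looking and in the lowest-control quartile), and
outcome-model coefficients calibrated so profile marginals land near
26/44/17/6 percent with the published directions of gender difference.
Nonresponse defaults emulate the published pattern: the nine mental-health
indicators missing as a block (6.8%), education (4.6%), and job-control items
among the employed (3.5%), giving ~13% of rows with at least one missing
measure. The mechanism is missing-at-random given observed covariates (the
source analysis does not state its assumption; MAR is declared here), with an
optional logit-linear dependence on observed variables.

Raw items are back-filled per category: work-status answers encode the
employment category (5% of the employed are absent on sick leave), job-control
items are a random composition of a latent sum drawn within per-quartile
ranges (5–9 / 10–12 / 13–15 / 16–25), and the nine indicators are drawn from
per-profile conditional distributions chosen to be well separated so the
clustering stage has recoverable structure (≥95% label agreement at
n = 1000). Four independent RNG streams (cohort, mediator, outcome,
missingness) derive from the master seed by fixed offsets, so toggling one
stage does not perturb the others.

What the generator does **not** emulate: survey sampling design and weights,
continuous age, item-level correlation beyond the profile templates,
missingness that depends on unobserved values (MNAR), and the full instrument
codings behind each indicator. Passing tests therefore demonstrate internal
validity of the estimation machinery under a correctly specified categorical
world, not robustness to the measurement issues of real survey data.

## The enumeration oracle and calibration

With categorical-only variables, prev(g, k) = Σ_c P(c|g) Σ_m P(m|g,c)
P(k|g,c,m) is computed exactly over all confounder cells; the counterfactual
replaces P(m|woman,c) by P(m|man,c). The same marginalization applied to a
given cohort and fitted models yields the exact conditional expectation of the
Monte Carlo procedure, together with an exact Monte Carlo standard error
(independent categorical draws per respondent × repetition). Simulation
correctness is asserted at 3 such SEs against this cohort-conditional
enumeration; comparing against the population oracle at fixed models would
confound Monte Carlo error with O(n^-1/2) sampling error.

Pipeline calibration is checked by replication: on freshly generated cohorts
the Boot-MI 95% interval for each natural-course RD should contain the
population-oracle value in ≥90% of 20 independent runs, and with the
gender→employment coefficients zeroed the percent-change intervals should
cover 0 likewise. These suites run at reduced nesting — n = 1000–1200
respondents, B = 100 bootstraps (natural-RD coverage) or B = 40 (null
calibration, whose intervals are far from the boundary), m = 2 imputations,
10 Monte Carlo repetitions, 1 imputation cycle, with nonresponse placed
directly on the analysis variables — sizes chosen once as the package's test
conditions. Smaller samples widen the intervals but also increase the relative
plug-in bias of the g-formula, so the check is informative, not trivially
conservative.

## Numerical choices and degenerate inputs

Model fits use unpenalized maximum likelihood (newton-cg); non-convergence or
runaway coefficients (|β| > 15, a separation symptom) trigger one refit with a
small L2 penalty, flagged on the model object. A declared category absent from
the data raises a positivity error naming the empty cell rather than fitting a
degenerate model. Predicted probabilities per row sum to 1 within 1e-10; RDs
across the four profiles sum to 0 within 1e-6 per scenario by construction.
Percentile and quartile computations use linear interpolation throughout.
Empty cohorts, all-identical job-control scores (everything Q1), 100%-missing
variables (error), and rows with no shared observed indicator in a Gower pair
(error) are all handled explicitly.

## Known limitations

- Single-timepoint world: the generator has no reverse causation from mental
  health to employment, which the real design cannot rule out either.
- Predictive-draw imputation understates between-imputation variance; Boot MI
  absorbs this, but the imputations alone are not proper in Rubin's sense.
- The multi-category standardized difference uses the Mahalanobis-type
  generalization; published balance statistics may use a different formula, so
  they are not treated as exact targets.
- Percentile intervals at small B are short; use B ≥ 100 for inference.
- The published headline risk differences derive from confidential microdata
  and are structurally, not numerically, reproduced here.
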