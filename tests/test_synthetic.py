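"""Generator contracts and the enumeration oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import empdecomp as e
from empdecomp import synthetic as S
from empdecomp.config import (
    MH_ITEMS,
    ConfigurationError,
    MissingnessRule,
    coef_frame,
    default_config,
)
from empdecomp.models import softmax_probs

from conftest import binary_scenario_config


class TestGenerateCohort:
    def test_empty_cohort(self):
        co = S.generate_cohort(default_config(0))
        assert len(co) == 0

    def test_same_seed_same_cohort(self):
        cfg = default_config(500, seed=11)
        a = S.generate_cohort(cfg)
        b = S.generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_women_fraction_matches_marginal(self):
        # 1263/2458 women; 3 binomial SEs at n=2458
        p = 1263 / 2458
        cfg = default_config(2458, seed=1)
        co = S.generate_cohort(cfg)
        frac = (co.truth["gender"] == "woman").mean()
        se = np.sqrt(p * (1 - p) / 2458)
        assert abs(frac - p) < 3 * se

    def test_confounder_labels_in_declared_sets(self, full_cohort):
        for spec in full_cohort.config.confounders:
            assert set(full_cohort.truth[spec.name]) <= set(spec.labels)

    def test_invalid_probability_rejected(self):
        cfg = default_config(10)
        cfg.gender_prob = 1.5
        with pytest.raises(ConfigurationError):
            S.generate_cohort(cfg)


class TestSoftmaxAssignment:
    def test_zero_coefficients_uniform_over_categories(self):
        cfg = default_config(7000, seed=2)
        zero = cfg.mediator_coefs * 0.0
        co = S.generate_cohort(cfg)
        probs = S.category_probabilities(co.truth, zero, cfg.employment_categories)
        assert np.allclose(probs, 1 / 7)

    def test_saturating_intercept_forces_category(self):
        cfg = default_config(300, seed=3)
        coefs = cfg.mediator_coefs * 0.0
        coefs.loc["Unemployed_unable", "Intercept"] = 20.0
        co = S.assign_employment(S.generate_cohort(cfg), coefs)
        probs = S.category_probabilities(co.truth, coefs, cfg.employment_categories)
        j = cfg.employment_categories.index("Unemployed_unable")
        assert probs[:, j].min() >= 1 - 1e-6
        assert (co.truth["employment_profile"] == "Unemployed_unable").all()

    def test_softmax_hand_example(self):
        # linear predictors (0, 1, 2) -> (0.0900, 0.2447, 0.6652)
        p = softmax_probs(np.array([[1.0, 2.0]]))
        assert np.allclose(np.round(p[0], 4), [0.0900, 0.2447, 0.6652])

    def test_nonfinite_linear_predictor_raises(self):
        cfg = default_config(5, seed=0)
        co = S.generate_cohort(cfg)
        bad = cfg.mediator_coefs.copy()
        bad.loc["Q2", "Intercept"] = np.inf
        with pytest.raises(Exception):
            S.category_probabilities(co.truth, bad, cfg.employment_categories)

    def test_zero_interactions_make_genders_exchangeable(self):
        cfg = default_config(4, seed=0)
        coefs = cfg.outcome_coefs.copy()
        inter = [c for c in coefs.columns if c.startswith("woman:")]
        coefs[inter] = 0.0
        coefs["woman"] = 0.0
        row = {c.name: c.labels[0] for c in cfg.confounders}
        df = pd.DataFrame([{**row, "gender": g, "employment_profile": "Q3"}
                           for g in ("man", "woman")])
        probs = S.category_probabilities(df, coefs, cfg.outcome_categories)
        assert np.allclose(probs[0], probs[1])

    def test_degenerate_templates_give_deterministic_indicators(self):
        cfg = default_config(400, seed=4)
        binaries = ("mood_disorder", "anxiety_disorder", "substance_use_disorder",
                    "schizophrenia_psychosis", "eating_disorder",
                    "suicidal_thoughts_attempts")
        cfg.profile_templates = {
            prof: {**{b: 0.0 for b in binaries},
                   "self_rated_mental_health": {i + 1: 1.0},
                   "life_stress": {i + 1: 1.0},
                   "positive_mental_health": {"moderate": 1.0}}
            for i, prof in enumerate(cfg.outcome_categories)
        }
        co = S.assign_mental_health(S.assign_employment(S.generate_cohort(cfg)))
        for i, prof in enumerate(cfg.outcome_categories):
            sub = co.truth[co.truth["mh_profile"] == prof]
            assert (sub["self_rated_mental_health"] == i + 1).all()
            assert (sub["life_stress"] == i + 1).all()


class TestMissingness:
    def test_zero_rates_leave_cohort_unchanged(self, full_cohort):
        out = S.inject_missingness(full_cohort, [MissingnessRule(("education",), 0.0)])
        pd.testing.assert_frame_equal(out.frame, full_cohort.truth)

    def test_rate_one_blanks_variable_everywhere(self, full_cohort):
        out = S.inject_missingness(full_cohort, [MissingnessRule(("education",), 1.0)])
        assert out.frame["education"].isna().all()

    def test_untargeted_cells_bit_identical(self, full_cohort):
        out = S.inject_missingness(full_cohort)
        targeted = set(MH_ITEMS) | {"education"} | {
            c for r in full_cohort.config.missingness for c in r.columns}
        untouched = [c for c in out.frame.columns if c not in targeted]
        pd.testing.assert_frame_equal(out.frame[untouched],
                                      full_cohort.truth[untouched])

    def test_mar_rates_follow_logit(self):
        cfg = default_config(20000, seed=6)
        co = S.assign_mental_health(S.assign_employment(S.generate_cohort(cfg)))
        rule = MissingnessRule(("mh_profile",),
                               logit_terms={"Intercept": -2.0, "woman": 1.0})
        out = S.inject_missingness(co, [rule])
        for g, lp in (("man", -2.0), ("woman", -1.0)):
            sub = out.frame[out.frame["gender"] == g]
            p = expit(lp)
            se = np.sqrt(p * (1 - p) / len(sub))
            assert abs(sub["mh_profile"].isna().mean() - p) < 3 * se

    def test_bad_rate_rejected(self, full_cohort):
        with pytest.raises(ConfigurationError):
            S.inject_missingness(full_cohort, [MissingnessRule(("education",), 1.2)])


class TestOracle:
    def test_prevalences_sum_to_one_and_rds_to_zero(self):
        for seed in (0, 1, 2):
            cfg = default_config(10, seed=seed)
            orc = S.oracle_decomposition(cfg)
            for scen in ("natural", "counterfactual"):
                sums = orc.prevalences[scen].sum(axis=1).to_numpy()
                assert np.allclose(sums, 1.0, atol=1e-12)
            assert abs(orc.table["rd_natural"].sum()) < 1e-9
            assert abs(orc.table["rd_counterfactual"].sum()) < 1e-9

    def test_mediator_irrelevance_equalizes_scenarios(self):
        cfg = default_config(10)
        coefs = cfg.outcome_coefs.copy()
        emp_terms = [c for c in coefs.columns if "employment_profile[" in c]
        coefs[emp_terms] = 0.0
        cfg.outcome_coefs = coefs
        orc = S.oracle_decomposition(cfg)
        assert np.allclose(orc.table["rd_natural"], orc.table["rd_counterfactual"],
                           atol=1e-10)

    def test_gender_free_mediator_gives_zero_percent_change(self):
        cfg = e.null_gender_mediator_config(10)
        orc = S.oracle_decomposition(cfg)
        assert np.allclose(orc.table["pct_change"].to_numpy(), 0.0, atol=1e-9)

    def test_hand_enumeration_binary_scenario(self):
        orc = S.oracle_decomposition(binary_scenario_config())
        nat = orc.prevalences["natural"]
        cf = orc.prevalences["counterfactual"]
        assert nat.loc["woman", "y1"] == pytest.approx(0.60, abs=1e-12)
        assert nat.loc["man", "y1"] == pytest.approx(0.66, abs=1e-12)
        assert cf.loc["woman", "y1"] == pytest.approx(0.76, abs=1e-12)
        assert orc.table.loc["y1", "rd_natural"] == pytest.approx(-60.0, abs=1e-9)
        assert orc.table.loc["y1", "rd_counterfactual"] == pytest.approx(100.0, abs=1e-9)


def test_backfilled_items_consistent_with_categories(full_cohort):
    df = full_cohort.truth
    employed = df["employment_profile"].isin(
        list(full_cohort.config.quartile_score_ranges))
    # work-status items encode the category
    assert ((df.loc[~employed, "worked_past_2wk"] == "no")
            & (df.loc[~employed, "absent_sick_or_leave"] == "no")).all()
    assert (df.loc[df["employment_profile"] == "Unemployed_unable",
                   "unable_to_work"] == "yes").all()
    assert (df.loc[df["employment_profile"] == "Unemployed_looking",
                   "looking_for_work"] == "yes").all()
    # Likert sums fall in the declared per-quartile score ranges
    from empdecomp.employment import job_control_score
    scores = job_control_score(df)
    for q, (lo, hi) in full_cohort.config.quartile_score_ranges.items():
        s = scores[df["employment_profile"] == q]
        assert s.between(lo, hi).all()
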