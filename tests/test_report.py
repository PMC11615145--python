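"""Descriptive tables, standardized differences, and the pipeline driver."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import empdecomp as e
from empdecomp import report as R
from empdecomp.bootmi import UncertaintySpec


def gendered_frame(counts: dict[str, dict[str, int]], var="mh_profile"):
    rows = []
    for g, cats in counts.items():
        for cat, n in cats.items():
            rows += [{"gender": g, var: cat}] * n
    return pd.DataFrame(rows)


class TestCrosstab:
    def test_printed_cells(self):
        df = gendered_frame({
            "woman": {"clinical_mood_disorder": 97, "other": 1263 - 97},
            "man": {"clinical_mood_disorder": 54, "other": 1195 - 54},
        })
        tab = R.crosstab_by_gender(df, "mh_profile").set_index("category")
        assert tab.loc["clinical_mood_disorder", "woman_cell"] == "97 (7.7%)"

    def test_empty_data_all_zero(self):
        df = pd.DataFrame({"gender": pd.Series(dtype=object),
                           "x": pd.Series(dtype=object)})
        tab = R.crosstab_by_gender(df, "x")
        assert (tab[["woman_n", "man_n", "overall_n"]].to_numpy() == 0).all()

    def test_single_category_is_100_percent(self):
        df = gendered_frame({"woman": {"only": 5}, "man": {"only": 7}}, var="x")
        tab = R.crosstab_by_gender(df, "x").set_index("category")
        assert tab.loc["only", "woman_pct"] == 100.0
        assert tab.loc["only", "man_pct"] == 100.0

    def test_missing_reported_separately_and_counts_consistent(self, full_cohort):
        df = full_cohort.truth.copy()
        df.loc[df.index[:50], "mh_profile"] = np.nan
        tab = R.crosstab_by_gender(df, "mh_profile")
        body = tab[tab["category"] != "(missing)"]
        miss = tab[tab["category"] == "(missing)"].iloc[0]
        for g in ("woman", "man"):
            n_g = (df["gender"] == g).sum()
            assert body[f"{g}_n"].sum() + miss[f"{g}_n"] == n_g
            # percents recompute from counts
            denom = body[f"{g}_n"].sum()
            for _, row in body.iterrows():
                assert row[f"{g}_pct"] == pytest.approx(
                    100 * row[f"{g}_n"] / denom, abs=0.05)

    def test_unknown_variable_raises(self, full_cohort):
        with pytest.raises(KeyError):
            R.crosstab_by_gender(full_cohort.truth, "nope")


class TestStandardizedDifference:
    def test_identical_distributions_zero(self):
        df = gendered_frame({"woman": {"a": 30, "b": 70},
                             "man": {"a": 30, "b": 70}}, var="x")
        assert R.standardized_difference(df, "x") == pytest.approx(0.0)

    def test_binary_hand_example(self):
        # p1=0.3, p2=0.2 -> 0.1/sqrt((0.21+0.16)/2) = 0.23250
        df = gendered_frame({"woman": {"a": 70, "b": 30},
                             "man": {"a": 80, "b": 20}}, var="x")
        assert R.standardized_difference(df, "x") == pytest.approx(0.2325, abs=2e-4)

    def test_multicategory_matches_matrix_oracle(self):
        df = gendered_frame({"woman": {"a": 50, "b": 30, "c": 20},
                             "man": {"a": 30, "b": 30, "c": 40}}, var="x")
        got = R.standardized_difference(df, "x")
        # brute-force oracle built independently from printed proportions
        p1 = np.array([0.5, 0.3, 0.2])
        p2 = np.array([0.3, 0.3, 0.4])

        def cov(p):
            q = p[:-1]
            return np.diag(q) - np.outer(q, q)

        t = (p1 - p2)[:-1]
        s = (cov(p1) + cov(p2)) / 2
        expected = float(np.sqrt(t @ np.linalg.inv(s) @ t))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_omitted_category(self):
        df = gendered_frame({"woman": {"a": 55, "b": 25, "c": 15, "d": 5},
                             "man": {"a": 35, "b": 35, "c": 20, "d": 10}}, var="x")
        base = R.standardized_difference(df, "x")
        # relabel so a different category sorts last (and is omitted)
        relab = {"a": "z_last", "b": "b", "c": "c", "d": "d"}
        df2 = df.assign(x=df["x"].map(relab))
        assert R.standardized_difference(df2, "x") == pytest.approx(base, abs=1e-10)


class TestHelpers:
    def test_working_age_filter_counts(self):
        rng = np.random.default_rng(0)
        ages = np.concatenate([rng.integers(25, 65, 2458),
                               rng.integers(15, 25, 900),
                               rng.integers(65, 90, 801)])
        df = pd.DataFrame({"age": ages})
        kept = R.filter_working_age(df)
        assert len(df) == 4159
        assert len(kept) == 4159 - 1701 == 2458

    def test_round_half_up(self):
        assert R.round_half_up(7.65, 1) == 7.7
        assert R.round_half_up(100 * 328 / 2458, 1) == 13.3

    def test_fraction_rows_missing(self):
        df = pd.DataFrame({"a": [1, np.nan, 3], "b": [np.nan, 2, 3]})
        assert R.fraction_rows_missing(df, ["a", "b"]) == pytest.approx(2 / 3)


class TestPipeline:
    def test_simulate_mode_empty_cohort(self, tmp_path):
        cfg = e.default_config(0, seed=1)
        bundle = R.run_pipeline(cfg, mode="simulate", out_dir=tmp_path)
        cohort = pd.read_csv(tmp_path / "cohort.csv")
        assert len(cohort) == 0
        assert bundle["manifest"]["rows"] == 0

    def test_full_mode_smoke_and_determinism(self, tmp_path):
        cfg = e.default_config(400, seed=2)
        us = UncertaintySpec(n_bootstrap=4, m_imputations=2, mc_reps=3,
                             impute_cycles=1, seed=2)
        a, b = tmp_path / "a", tmp_path / "b"
        R.run_pipeline(cfg, mode="full", out_dir=a, uspec=us)
        R.run_pipeline(cfg, mode="full", out_dir=b, uspec=us)
        names = ["cohort.csv", "analysis.csv", "table1.csv", "table2.csv",
                 "table3.csv"]
        for name in names:
            assert (a / name).exists()
            assert (a / name).read_bytes() == (b / name).read_bytes()
        table3 = pd.read_csv(a / "table3.csv")
        assert set(table3["outcome"]) == set(cfg.outcome_categories)
        manifest = json.loads((a / "manifest.json").read_text())
        assert manifest["rows"] == 400

    def test_unknown_mode_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            R.run_pipeline(e.default_config(5), mode="wat", out_dir=tmp_path)
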