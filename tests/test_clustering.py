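"""Gower dissimilarity, PAM, and profile labelling."""

import itertools

import numpy as np
import pandas as pd
import pytest

import empdecomp as e
from empdecomp import clustering as C
from empdecomp import synthetic as S


def mh_row(mood=0, anx=0, sub=0, schiz=0, eat=0, suic=0, srmh=5, stress=1,
           pmh="flourishing"):
    return {
        "mood_disorder": mood, "anxiety_disorder": anx,
        "substance_use_disorder": sub, "schizophrenia_psychosis": schiz,
        "eating_disorder": eat, "suicidal_thoughts_attempts": suic,
        "self_rated_mental_health": srmh, "life_stress": stress,
        "positive_mental_health": pmh,
    }


class TestGower:
    def test_identical_rows_distance_zero(self):
        a = mh_row()
        assert C.gower_distance(a, a) == 0.0

    def test_maximally_different_rows_distance_one(self):
        a = mh_row(0, 0, 0, 0, 0, 0, srmh=1, stress=1, pmh="languishing")
        b = mh_row(1, 1, 1, 1, 1, 1, srmh=5, stress=5, pmh="flourishing")
        assert C.gower_distance(a, b) == pytest.approx(1.0)

    def test_hand_example(self):
        # 3 binary mismatches + |2|/range-4 on one ordinal, equal elsewhere:
        # (3*1 + 0.5 + 5*0) / 9 = 0.38889
        a = mh_row(mood=0, anx=0, sub=0, srmh=5)
        b = mh_row(mood=1, anx=1, sub=1, srmh=3)
        assert C.gower_distance(a, b) == pytest.approx((3 + 0.5) / 9, abs=1e-12)

    def test_pairwise_deletion_renormalizes(self):
        a = mh_row(mood=1)
        b = mh_row(mood=0)
        a["life_stress"] = np.nan
        # 8 shared variables, one mismatch
        assert C.gower_distance(a, b) == pytest.approx(1 / 8)

    def test_all_missing_pair_rejected(self):
        a = {k: np.nan for k in mh_row()}
        with pytest.raises(ValueError):
            C.gower_distance(a, mh_row())

    def test_symmetry_bounds_and_triangle(self, full_cohort):
        items = full_cohort.truth.sample(40, random_state=0)
        D = C.gower_matrix(items)
        assert np.allclose(D, D.T)
        assert (D >= 0).all() and (D <= 1).all()
        assert np.allclose(np.diag(D), 0)
        # city-block Gower over complete data satisfies the triangle inequality
        for i, j, k in itertools.combinations(range(20), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


def brute_force_kmedoids(D, k):
    n = D.shape[0]
    best = (np.inf, None)
    for meds in itertools.combinations(range(n), k):
        cost = D[list(meds)].min(axis=0).sum()
        if cost < best[0] - 1e-12:
            best = (cost, meds)
    return best


class TestPam:
    def test_k_equals_n_zero_cost(self):
        df = pd.DataFrame([mh_row(srmh=s) for s in (1, 2, 3, 4, 5)])
        sol = C.pam(C.gower_matrix(df), k=5)
        assert sol.cost == 0.0
        assert sorted(sol.medoids) == list(range(5))

    def test_exact_duplicates_split_cleanly(self):
        df = pd.DataFrame([mh_row()] * 3 + [mh_row(mood=1, srmh=1, stress=5,
                                                   pmh="languishing")] * 3)
        sol = C.pam(C.gower_matrix(df), k=2)
        assert sol.cost == 0.0
        assert len({tuple(sorted(np.where(sol.labels == c)[0]))
                    for c in range(2)} & {(0, 1, 2), (3, 4, 5)}) == 2

    def test_matches_brute_force_on_small_inputs(self):
        rng = np.random.default_rng(7)
        rows = []
        for tpl in (mh_row(), mh_row(mood=1, srmh=2, stress=4, pmh="languishing")):
            for _ in range(4):
                r = dict(tpl)
                r["life_stress"] = int(np.clip(r["life_stress"] + rng.integers(-1, 2), 1, 5))
                rows.append(r)
        D = C.gower_matrix(pd.DataFrame(rows))
        sol = C.pam(D, k=2)
        opt_cost, _ = brute_force_kmedoids(D, 2)
        assert sol.cost == pytest.approx(opt_cost, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            C.pam(np.array([[0.0, 1.0], [2.0, 0.0]]), 1)  # asymmetric
        with pytest.raises(ValueError):
            C.pam(np.array([[0.0, -1.0], [-1.0, 0.0]]), 1)  # negative

    def test_partition_invariant_to_row_order(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame([mh_row(mood=int(rng.random() < 0.5),
                                  srmh=int(rng.integers(1, 6)),
                                  stress=int(rng.integers(1, 6)))
                           for _ in range(30)])
        D = C.gower_matrix(df)
        sol = C.pam(D, k=3)
        perm = rng.permutation(30)
        sol_p = C.pam(D[np.ix_(perm, perm)], k=3)
        # same partition up to label names
        a = sol.labels[perm]
        b = sol_p.labels
        table = pd.crosstab(a, b).to_numpy()
        assert (table > 0).sum() == len(np.unique(a))  # one block per cluster


class TestLabelling:
    def test_pure_mood_cluster_is_clinical(self):
        df = pd.DataFrame([mh_row()] * 3
                          + [mh_row(srmh=4, stress=3)] * 3
                          + [mh_row(srmh=3, stress=3, pmh="moderate")] * 3
                          + [mh_row(mood=1, srmh=1, stress=4, pmh="languishing")] * 3)
        sol = C.pam(C.gower_matrix(df), k=4)
        sol = C.label_clusters(sol, df)
        named = sol.named_labels()
        assert (named[9:] == "clinical_mood_disorder").all()
        assert (named[:3] == "flourishing_no_stress").all()
        assert (named[3:6] == "flourishing_some_stress").all()
        assert (named[6:9] == "moderate_mh_stress").all()

    def test_tie_raises(self):
        df = pd.DataFrame([mh_row(srmh=s, stress=s, pmh="moderate") for s in
                           (1, 2, 4, 5)] * 2)
        sol = C.pam(C.gower_matrix(df), k=4)
        stats = C.cluster_statistics(sol, df)
        assert (stats["mood_disorder"] == 0).all()
        with pytest.raises(ValueError, match="tie"):
            C.label_clusters(sol, df)

    def test_recovers_default_generator_profiles(self):
        """On the stock 4-profile config the Gower+PAM pipeline reproduces the
        generating profile for at least 95% of rows at n=1000."""
        cfg = e.default_config(1000, seed=9)
        co = S.assign_mental_health(S.assign_employment(S.generate_cohort(cfg)))
        mh, report = C.derive_mh_profiles(co.truth)
        assert (mh == co.truth["mh_profile"]).mean() >= 0.95
        assert set(report.index) == set(C.PROFILE_LABELS)

    def test_two_template_recovery(self):
        """60 rows from 2 noisy templates: PAM separates them >= 95%."""
        rng = np.random.default_rng(11)
        rows, truth = [], []
        for i, tpl in enumerate((mh_row(), mh_row(mood=1, anx=1, srmh=1,
                                                  stress=5, pmh="languishing"))):
            for _ in range(30):
                r = dict(tpl)
                if rng.random() < 0.05:
                    r["anxiety_disorder"] = 1 - r["anxiety_disorder"]
                rows.append(r)
                truth.append(i)
        sol = C.pam(C.gower_matrix(pd.DataFrame(rows)), k=2)
        truth = np.asarray(truth)
        agree = max((sol.labels == truth).mean(), (sol.labels == 1 - truth).mean())
        assert agree >= 0.95
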