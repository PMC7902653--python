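"""Characterization suite: RF reports, borderline analysis, contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from scdpipe import characterize as chz
from scdpipe import cohort as cohort_mod
from scdpipe import operationalize as op
from scdpipe import simulate


class TestErrorByChance:
    @pytest.mark.parametrize("k,expected", [(5, 80.0), (2, 50.0), (4, 75.0)])
    def test_matches_uniform_guesser_rate(self, k, expected):
        assert chz.error_by_chance(k) == expected

    def test_matches_enumeration_over_balanced_classes(self):
        # exact enumeration: over all (true, guess) pairs of a uniform
        # guesser on k balanced classes, the error fraction is (k-1)/k
        for k in range(2, 7):
            pairs = [(t, g) for t in range(k) for g in range(k)]
            err = 100.0 * sum(t != g for t, g in pairs) / len(pairs)
            assert err == pytest.approx(chz.error_by_chance(k), abs=1e-12)


class TestRFClassification:
    def test_null_labels_give_error_at_or_above_chance(self, study_cohort):
        rng = np.random.default_rng(0)
        errs = []
        for seed in range(3):
            labels = pd.Series(rng.permutation(
                np.repeat(["A", "B"], len(study_cohort) // 2 + 1)[:len(study_cohort)]),
                index=study_cohort.df.index)
            report = chz.rf_group_vs_hc(study_cohort, labels, n_trees=100,
                                        seed=seed)
            errs.append(np.mean(list(report.class_errors.values())))
        # labels independent of predictors: mean per-class OOB error cannot
        # sit meaningfully below chance
        assert np.mean(errs) > report.error_by_chance - 10.0

    def test_report_shape_and_reproducibility(self, study_cohort):
        labels = op.classify_clinical(study_cohort)
        a = chz.rf_group_vs_hc(study_cohort, labels, n_trees=60, seed=3)
        b = chz.rf_group_vs_hc(study_cohort, labels, n_trees=60, seed=3)
        assert a.class_errors == b.class_errors
        assert a.importance.equals(b.importance)
        assert a.error_by_chance == 80.0  # five clinical labels
        assert len(a.top_predictors) == 5

    def test_small_class_rejected(self, study_cohort):
        labels = pd.Series("A", index=study_cohort.df.index)
        labels.iloc[:3] = "B"
        with pytest.raises(ValueError, match="< 5"):
            chz.rf_group_vs_hc(study_cohort, labels, n_trees=10, seed=0)


@pytest.fixture(scope="module")
def smri_cohort():
    table = simulate.generate_cohort(simulate.SimulationParams(
        n_subjects=500, seed=21))
    table = simulate.attach_smri_to_cohort(table, severity_link=0.5,
                                           wmsa_link=0.5, seed=2)
    table = cohort_mod.impute_missing(table, seed=0)
    return cohort_mod.combine_depression(table)


class TestRFBiomarkerRegression:
    def test_covariate_switch_per_outcome(self, smri_cohort):
        wmsa = chz.rf_biomarker_regression(smri_cohort, "wmsa", n_trees=50,
                                           seed=0)
        hip = chz.rf_biomarker_regression(smri_cohort, "vol_left_hippocampus",
                                          n_trees=50, seed=0)
        assert "icv" in wmsa.importance.index and "age" in wmsa.importance.index
        assert "icv" not in hip.importance.index
        assert "age" not in hip.importance.index
        assert (wmsa.importance >= 0).all()  # zero-floored for display

    def test_memory_complaint_predicts_planted_atrophy_link(self, smri_cohort):
        # memory complaint tracks the severity factor that drives atrophy
        report = chz.rf_biomarker_regression(
            smri_cohort, "vol_left_hippocampus", n_trees=200, seed=1)
        complaints = [i for i in report.importance.index
                      if i in ("memory", "orientation", "word_finding",
                               "writing", "lang_production",
                               "lang_comprehension", "reading",
                               "face_recognition", "executive")]
        top2 = report.importance[complaints].nlargest(2).index
        assert "memory" in top2

    def test_zero_variance_outcome_rejected(self, smri_cohort):
        table = smri_cohort.with_df(smri_cohort.df.assign(wmsa=1.0))
        with pytest.raises(ValueError, match="zero variance"):
            chz.rf_biomarker_regression(table, "wmsa", n_trees=10, seed=0)


class TestBorderline:
    def test_reference_flags_ten_percent_by_construction(self):
        rng = np.random.default_rng(5)
        n = 400
        scores = pd.DataFrame({"PC1": rng.standard_normal(n)})
        cov = pd.DataFrame({"age": rng.uniform(50, 80, n),
                            "sex": rng.integers(0, 2, n),
                            "wais_info": rng.normal(15, 6, n)})
        groups = pd.Series(rng.choice(["HC", "SCD"], n))
        report = chz.borderline_performance(scores, cov, groups, pct=10)
        flagged = int(np.ceil(0.1 * n))
        total_flagged = (report.percent_below["PC1"] / 100
                         * groups.value_counts()[report.percent_below.index]).sum()
        assert round(total_flagged) == flagged

    def test_null_groups_flag_near_ten_percent_each(self):
        rng = np.random.default_rng(6)
        n = 3000
        scores = pd.DataFrame({"PC1": rng.standard_normal(n)})
        cov = pd.DataFrame({"age": rng.uniform(50, 80, n)})
        groups = pd.Series(rng.choice(["a", "b", "c"], n))
        report = chz.borderline_performance(scores, cov, groups, pct=10)
        for pct in report.percent_below["PC1"]:
            assert abs(pct - 10.0) < 3.0  # binomial tolerance at n~1000

    def test_planted_deficit_raises_group_flag_rate(self):
        rng = np.random.default_rng(7)
        n = 900
        groups = pd.Series(["impaired"] * 300 + ["other"] * 600)
        base = rng.standard_normal(n)
        base[:300] -= 1.0  # planted deficit in one group
        scores = pd.DataFrame({"PC1": base})
        cov = pd.DataFrame({"age": rng.uniform(50, 80, n)})
        report = chz.borderline_performance(scores, cov, groups, pct=10)
        assert (report.percent_below.loc["impaired", "PC1"]
                > report.percent_below.loc["other", "PC1"] + 10)


class TestEqualProportionChisq:
    def test_symmetry_gives_zero(self):
        chi2, p = chz.equal_proportion_chisq(57, 57)
        assert chi2 == 0.0 and p == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            chz.equal_proportion_chisq(-1, 5)

    @given(st.integers(min_value=0, max_value=200),
           st.integers(min_value=0, max_value=200))
    @settings(max_examples=200, deadline=None)
    def test_matches_two_cell_pearson_oracle(self, a, b):
        if a + b == 0:
            return
        chi2, p = chz.equal_proportion_chisq(a, b)
        # explicit expected-count oracle: two cells, equal expectation
        expected = (a + b) / 2
        oracle = sum((obs - expected) ** 2 / expected for obs in (a, b))
        assert chi2 == pytest.approx(oracle, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(oracle, 1), abs=1e-12)


class TestHochberg:
    def test_single_p_unchanged(self):
        assert chz.hochberg_adjust([0.037])[0] == pytest.approx(0.037)

    def test_all_equal_p_stay_equal(self):
        adj = chz.hochberg_adjust([0.02] * 5)
        assert np.allclose(adj, 0.02)

    def test_step_up_worked_example(self):
        adj = chz.hochberg_adjust([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            chz.hochberg_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=12))
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_step_up_oracle(self, pvals):
        adj = chz.hochberg_adjust(pvals)
        order = np.argsort(pvals)
        m = len(pvals)
        # brute force: adj of the i-th smallest = min over j >= i of
        # (m - j) * p_(j), capped at 1
        sorted_p = np.asarray(pvals)[order]
        expected = np.empty(m)
        for i in range(m):
            expected[i] = min(min((m - j) * sorted_p[j] for j in range(i, m)), 1.0)
        assert np.allclose(np.asarray(adj)[order], expected, atol=1e-12)
        assert (np.asarray(adj) >= np.asarray(pvals) - 1e-12).all()


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(200)
        y = 0.4 * x + rng.standard_normal(200)
        r, p = chz.partial_correlation(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)

    def test_identical_variables_give_unit_correlation(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(50)
        cov = rng.standard_normal((50, 2))
        r, _ = chz.partial_correlation(x, x, cov)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_known_trivariate_partial_correlation_recovered(self):
        # x and y share a confounder z plus a direct link chosen so the
        # partial correlation given z is 0.5
        rng = np.random.default_rng(10)
        n = 10000
        z = rng.standard_normal(n)
        x = z + rng.standard_normal(n)
        y = z + x - z + rng.standard_normal(n) * np.sqrt(3)  # r_xy.z = 0.5
        r, p = chz.partial_correlation(x, y, z)
        assert abs(r - 0.5) < 0.03
        assert p < 1e-10

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.standard_normal((120, 4)),
                          columns=["x", "y", "c1", "c2"])
        df["y"] += 0.5 * df["x"] + 0.3 * df["c1"]
        r, p = chz.partial_correlation(df["x"], df["y"], df[["c1", "c2"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_rank_deficient_covariates_rejected(self):
        x = np.arange(30.0)
        cov = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(ValueError, match="rank"):
            chz.partial_correlation(x, x, cov)


class TestGroupContrasts:
    def test_two_group_anova_equals_squared_t(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"v": rng.standard_normal(80)})
        labels = pd.Series(["a"] * 40 + ["b"] * 40)
        table = chz.group_contrasts(df, labels, ["v"], family="anova")
        f_stat = table.loc[0, "statistic"]
        t_stat, _ = stats.ttest_ind(df["v"][:40], df["v"][40:])
        assert f_stat == pytest.approx(t_stat ** 2, rel=1e-10)

    def test_permuted_labels_type_i_error_calibrated(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({"v": rng.standard_normal(120)})
        raw_p = []
        for _ in range(200):
            labels = pd.Series(rng.permutation(["a", "b", "c"] * 40))
            table = chz.group_contrasts(df, labels, ["v"], family="anova")
            raw_p.append(table.loc[0, "p"])
        rate = np.mean(np.asarray(raw_p) < 0.05)
        assert 0.01 < rate < 0.10  # ~5% nominal

    def test_ancova_adjusts_for_covariate(self):
        rng = np.random.default_rng(14)
        n = 300
        age = rng.uniform(50, 85, n)
        labels = pd.Series(np.where(age > 68, "old", "young"))
        # outcome depends on age only; ANCOVA should absorb the group gap
        df = pd.DataFrame({"v": 0.1 * age + rng.standard_normal(n) * 0.5,
                           "age": age})
        anova = chz.group_contrasts(df, labels, ["v"], family="anova")
        ancova = chz.group_contrasts(df, labels, ["v"], family="ancova",
                                     covariates=["age"])
        assert anova.loc[0, "p"] < 0.001        # confounded contrast fires
        assert ancova.loc[0, "p"] > anova.loc[0, "p"]

    def test_pairwise_posthoc_hochberg_adjusted(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame({"v": np.concatenate([
            rng.standard_normal(50), rng.standard_normal(50) + 1,
            rng.standard_normal(50) + 2])})
        labels = pd.Series(["a"] * 50 + ["b"] * 50 + ["c"] * 50)
        table = chz.group_contrasts(df, labels, ["v"], family="anova",
                                    pairwise=True)
        posthoc = table[table["test"] == "posthoc_anova"]
        assert len(posthoc) == 3
        assert (posthoc["p_adjusted"] >= posthoc["p"] - 1e-15).all()
        assert (posthoc["p_adjusted"] <= 1).all()

    def test_nonparametric_families(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame({"v": rng.exponential(1, 90)})
        labels3 = pd.Series(["a", "b", "c"] * 30)
        kruskal = chz.group_contrasts(df, labels3, ["v"], family="kruskal")
        assert kruskal.loc[0, "test"] == "kruskal"
        labels2 = pd.Series(["a", "b"] * 45)
        mw = chz.group_contrasts(df, labels2, ["v"], family="mannwhitney")
        h, p = stats.kruskal(*[df["v"][labels3 == g] for g in "abc"])
        assert kruskal.loc[0, "statistic"] == pytest.approx(h)
        u, p_ref = stats.mannwhitneyu(df["v"][labels2 == "a"],
                                      df["v"][labels2 == "b"],
                                      alternative="two-sided")
        assert mw.loc[0, "p"] == pytest.approx(p_ref)
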