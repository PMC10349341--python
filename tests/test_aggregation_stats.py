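"""Per-drug statistics, comparisons, activity codes, and validation metrics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from trialspend import (GeneratorConfig, InflationIndex, build_ledger,
                        classify_activity_code, classify_corpus, cohen_kappa,
                        designation_comparisons, generate, industry_comparison,
                        mannwhitney_two_tailed, mean_per_funded_drug,
                        paired_t_two_tailed, per_drug_profiles,
                        percent_of_industry, validation_metrics)


def exact_mw_p(x, y):
    """Brute-force two-sided p over all rank assignments (no ties)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mean_u = n1 * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_multisets_give_p_one(self):
        res = mannwhitney_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_all_values_identical_is_vacuous(self):
        res = mannwhitney_two_tailed([5.0] * 4, [5.0] * 6)
        assert res.p_value == 1.0

    def test_small_sample_matches_exact_permutation_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            x = rng.normal(0, 1, 5)
            y = rng.normal(1, 1, 5)
            res = mannwhitney_two_tailed(x, y)
            assert res.p_value == pytest.approx(exact_mw_p(x, y), abs=1e-9)

    def test_normal_approximation_close_to_exact_at_small_n(self):
        rng = np.random.default_rng(7)
        for n1, n2 in [(4, 5), (6, 6), (8, 7), (8, 8)]:
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.8, 1, n2)
            exact = exact_mw_p(x, y)
            approx = sps.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic").pvalue
            assert abs(approx - exact) <= 0.02

    def test_reports_median_and_iqr_per_group(self):
        res = mannwhitney_two_tailed([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.group_summaries["x"]["median"] == 2.5
        assert res.group_summaries["y"]["iqr"] == 15.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney_two_tailed([], [1.0])

    def test_detects_injected_location_shift_between_strata(self):
        """First-in-class drugs funded at a large multiple are significant."""
        cfg = GeneratorConfig(n_drugs=80, n_projects=400, seed=21,
                              first_in_class_cost_multiplier=8.0)
        corpus, _ = generate(cfg)
        index = InflationIndex.from_frame(corpus.inflation, 2018)
        led = build_ledger(classify_corpus(corpus), corpus, index)
        profiles = per_drug_profiles(led.drug_phase_totals(),
                                     corpus.industry_costs, corpus.drugs)
        table = designation_comparisons(profiles).set_index("designation")
        assert table.loc["first_in_class", "p_value"] < 0.05
        assert table.loc["first_in_class", "median_yes"] > \
            table.loc["first_in_class", "median_no"]


class TestPairedT:
    def test_known_differences_match_closed_form(self):
        # differences 1,2,3,4: mean 2.5, sd sqrt(5/3), CI from t(3)
        first = np.zeros(4)
        second = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t_two_tailed(first, second)
        sd = math.sqrt(5 / 3)
        se = sd / 2
        t975 = sps.t.ppf(0.975, 3)
        assert res.estimate == pytest.approx(2.5)
        assert res.ci_low == pytest.approx(2.5 - t975 * se)
        assert res.ci_high == pytest.approx(2.5 + t975 * se)
        assert res.statistic == pytest.approx(2.5 / se)
        assert res.p_value == pytest.approx(
            float(sps.ttest_rel(second, first).pvalue))

    def test_all_zero_differences_vacuous(self):
        res = paired_t_two_tailed([1.0, 2.0], [1.0, 2.0])
        assert res.estimate == 0.0
        assert res.p_value == 1.0

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t_two_tailed([1.0], [2.0])

    def test_recovers_known_shift_in_simulation(self):
        rng = np.random.default_rng(3)
        delta = 40.0
        nih = rng.gamma(2.0, 10.0, 60)
        industry = nih + delta + rng.normal(0, 15.0, 60)
        res = paired_t_two_tailed(nih, industry)
        assert res.ci_low <= delta <= res.ci_high


class TestRatiosAndMeans:
    def test_mean_per_funded_drug(self):
        assert mean_per_funded_drug(1460.0, 105) == pytest.approx(13.9, abs=0.05)
        assert mean_per_funded_drug(42.0, 1) == 42.0
        assert mean_per_funded_drug(0.0, 0) is None

    def test_percent_of_industry_cells(self):
        assert percent_of_industry(10.5, 54.9) == 19.1
        assert percent_of_industry(54.9, 456.7) == 12.0
        assert percent_of_industry(7.0, 7.0) == 100.0

    def test_nonpositive_industry_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_of_industry(1.0, 0.0)


class TestActivityCodes:
    @pytest.mark.parametrize("code,category", [
        ("U01", "cooperative_agreement"),
        ("UL1", "cooperative_agreement"),
        ("M01", "program_projects_centers"),
        ("P30", "program_projects_centers"),
        ("R01", "research_project"),
        ("r21", "research_project"),
        ("K08", "training_career"),
        ("T32", "training_career"),
        ("F32", "training_career"),
        ("S10", "other"),
        ("G12", "other"),
    ])
    def test_code_families(self, code, category):
        assert classify_activity_code(code) == category

    def test_empty_code_rejected(self):
        with pytest.raises(ValueError):
            classify_activity_code("  ")


class TestValidationMetrics:
    def test_constructed_confusion_counts(self):
        # TP=50, FN=3, TN=47, FP=4 with perfectly agreeing readers
        gold = [True] * 53 + [False] * 51
        predicted = [True] * 50 + [False] * 3 + [False] * 47 + [True] * 4
        m = validation_metrics(predicted, gold, gold)
        assert m.sensitivity == pytest.approx(50 / 53, abs=5e-4)  # 0.943
        assert m.specificity == pytest.approx(47 / 51, abs=5e-4)  # 0.922
        assert m.kappa == 1.0

    def test_identical_readers_kappa_one(self):
        labels = [True, False, True, True, False]
        assert cohen_kappa(labels, labels) == 1.0

    def test_independent_readers_kappa_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.random(20000) < 0.5
        b = rng.random(20000) < 0.5
        assert abs(cohen_kappa(a, b)) < 0.02

    def test_matches_reference_kappa_implementation(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(1)
        a = rng.random(500) < 0.4
        b = (rng.random(500) < 0.8) == a
        assert cohen_kappa(a, b) == pytest.approx(
            cohen_kappa_score(a, b), rel=1e-9)

    def test_no_positive_gold_reports_absent_with_warning(self):
        with pytest.warns(UserWarning):
            m = validation_metrics([False, False], [False, False], [False, False])
        assert m.sensitivity is None
        assert m.specificity == 1.0


class TestProfilesAndTables:
    def test_phase_means_match_brute_force_recomputation(self, corpus, truth):
        index = InflationIndex.from_frame(corpus.inflation, 2018)
        led = build_ledger(classify_corpus(corpus), corpus, index)
        profiles = per_drug_profiles(led.drug_phase_totals(),
                                     corpus.industry_costs, corpus.drugs)
        by_drug = truth.drug_costs[truth.drug_costs.phase == "P2"]
        expected = by_drug.adjusted_cost.mean()
        observed = profiles.loc[profiles.nih_P2 > 0, "nih_P2"].mean()
        assert observed == pytest.approx(expected, rel=1e-9)

    def test_unfunded_drugs_absent_from_profiles(self, corpus, truth):
        index = InflationIndex.from_frame(corpus.inflation, 2018)
        led = build_ledger(classify_corpus(corpus), corpus, index)
        profiles = per_drug_profiles(led.drug_phase_totals(),
                                     corpus.industry_costs, corpus.drugs)
        assert set(profiles.drug_id) == set(truth.drug_totals.drug_id)
        assert (profiles.nih_total > 0).all()

    def test_industry_comparison_pairs_drop_missing_and_zero_fill(self, corpus):
        index = InflationIndex.from_frame(corpus.inflation, 2018)
        led = build_ledger(classify_corpus(corpus), corpus, index)
        profiles = per_drug_profiles(led.drug_phase_totals(),
                                     corpus.industry_costs, corpus.drugs)
        table = industry_comparison(profiles)
        n_paired = profiles.industry_total.notna().sum()
        assert (table.n_drugs == n_paired).all()
        total = table[table.phase == "total_P1_P3"].iloc[0]
        assert total.nih_mean == pytest.approx(
            profiles.loc[profiles.industry_total.notna(),
                         ["nih_P1", "nih_P2", "nih_P3"]].sum(axis=1).mean())

    def test_activity_category_shares_sum_to_total(self, corpus):
        index = InflationIndex.from_frame(corpus.inflation, 2018)
        led = build_ledger(classify_corpus(corpus), corpus, index)
        activity = led.activity_category_totals()
        cats = led.category_totals().set_index("category")
        assert activity.adjusted_cost.sum() == pytest.approx(
            cats.adjusted_cost["development"], rel=1e-12)
        assert activity.project_years.sum() == cats.project_years["development"]
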