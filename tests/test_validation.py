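"""Validation-pipeline tests: ROC/AUC oracles, cut-offs, CIs, subgroups."""

import math

import numpy as np
import pytest

from coascore import (
    CohortRecord,
    CutoffCriterion,
    FetalEchoExam,
    SingleClassError,
    compare_groups,
    diagnostic_metrics,
    empirical_roc,
    probability_bands,
    proportion_percent,
    roc_from_scores,
    select_cutoff,
    split_by_onset,
    summarize_probabilities,
    wilson_ci,
)
from coascore.validation import InsufficientDataError

from conftest import toy_records


def brute_force_auc(pos, neg):
    """Pairwise-comparison AUC oracle: wins + half-ties over all pairs."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def closed_form_wilson(k, n, z=1.959963984540054):
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    return centre - half, centre + half


class TestRoc:
    def test_perfect_separation(self, make_records):
        roc = empirical_roc(make_records([0.8, 0.9], [0.1, 0.2]))
        assert roc.auc == 1.0

    def test_all_ties(self, make_records):
        roc = empirical_roc(make_records([0.5, 0.5], [0.5, 0.5]))
        assert roc.auc == 0.5

    def test_four_pair_example(self, make_records):
        # positives {0.9, 0.8}, negatives {0.7, 0.85}: 3 wins of 4 pairs
        roc = empirical_roc(make_records([0.9, 0.8], [0.7, 0.85]))
        assert roc.auc == pytest.approx(0.75)

    def test_single_class_raises(self, make_records):
        with pytest.raises(SingleClassError):
            empirical_roc(make_records([0.9, 0.8], []))

    def test_sensitivity_non_increasing_in_threshold(self, paper_like_records):
        roc = empirical_roc(paper_like_records)
        sns = [sn for sn, _ in roc.points]
        assert all(b <= a for a, b in zip(sns, sns[1:]))
        assert list(roc.thresholds) == sorted(set(roc.thresholds))

    def test_discrete_score_has_at_most_16_thresholds(self, paper_like_records):
        roc = empirical_roc(paper_like_records)
        assert len(roc.thresholds) <= 16

    def test_trapezoid_equals_mann_whitney_on_random_cohorts(self):
        """Tie-handling equivalence of the two AUC constructions."""
        rng = np.random.default_rng(42)
        for _ in range(500):
            n1 = rng.integers(2, 30)
            n0 = rng.integers(2, 30)
            # coarse grid forces heavy ties
            pos = rng.choice(np.linspace(0.05, 0.95, 7), n1)
            neg = rng.choice(np.linspace(0.05, 0.95, 7), n0)
            roc = roc_from_scores(
                np.concatenate([pos, neg]),
                np.concatenate([np.ones(n1, bool), np.zeros(n0, bool)]),
            )
            assert abs(roc.auc - roc.auc_trapezoid) < 1e-12
            assert roc.auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_delong_ci_contains_auc_and_shrinks_with_n(self):
        widths = []
        for n in (50, 500):
            rng = np.random.default_rng(7)  # fixed generator seed family
            pos = rng.normal(1.0, 1.0, n)
            neg = rng.normal(0.0, 1.0, n)
            roc = roc_from_scores(
                np.concatenate([pos, neg]),
                np.concatenate([np.ones(n, bool), np.zeros(n, bool)]),
            )
            lo, hi = roc.auc_ci
            assert lo <= roc.auc <= hi
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_delong_point_auc_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        scores = rng.choice(np.linspace(0, 1, 9), 200)
        labels = rng.random(200) < 0.3
        labels[0], labels[1] = True, False  # both classes present
        roc = roc_from_scores(scores, labels)
        assert roc.auc == pytest.approx(
            sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12
        )


class TestSelectCutoff:
    def test_best_balance_prefers_higher_youden(self, make_records):
        # one threshold gives Sn 1.0 / Sp 0.8 (J .8); another Sn 0.9 / Sp 0.85
        records = make_records(
            [0.30] + [0.6] * 9,
            [0.1] * 16 + [0.35] * 1 + [0.7] * 3,
        )
        report = select_cutoff(empirical_roc(records), records, "best_balance")
        assert report.metrics.sensitivity.value == pytest.approx(1.0)
        assert report.metrics.specificity.value == pytest.approx(0.8)

    def test_perfect_separation_all_criteria_agree(self, make_records):
        records = make_records([0.8, 0.9, 0.95], [0.1, 0.2, 0.3])
        roc = empirical_roc(records)
        thresholds = {
            select_cutoff(roc, records, c).threshold for c in CutoffCriterion
        }
        assert thresholds == {0.8}
        for c in CutoffCriterion:
            m = select_cutoff(roc, records, c).metrics
            assert m.sensitivity.value == 1.0 and m.specificity.value == 1.0

    def test_max_sensitivity_attains_full_sensitivity(self, paper_like_records):
        roc = empirical_roc(paper_like_records)
        report = select_cutoff(roc, paper_like_records, "max_sensitivity")
        assert report.metrics.sensitivity.value == 1.0

    def test_youden_matches_exhaustive_search_on_random_cohorts(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            pos = rng.choice(np.linspace(0.1, 0.9, 6), rng.integers(3, 25))
            neg = rng.choice(np.linspace(0.1, 0.9, 6), rng.integers(3, 25))
            records = toy_records(pos, neg)
            roc = empirical_roc(records)
            report = select_cutoff(roc, records, "best_balance")
            best_j = max(sn + sp - 1.0 for sn, sp in roc.points)
            j = (
                report.metrics.sensitivity.value
                + report.metrics.specificity.value
                - 1.0
            )
            assert j == pytest.approx(best_j, abs=1e-12)

    def test_threshold_is_attained_value_with_display_percent(self, paper_like_records):
        roc = empirical_roc(paper_like_records)
        report = select_cutoff(roc, paper_like_records, "best_balance")
        assert report.threshold in {r.predicted_probability for r in paper_like_records}
        assert report.threshold_percent == round(100 * report.threshold)


class TestDiagnosticMetrics:
    def test_constructed_2x2(self):
        pred = [True] * 36 + [False] * 3 + [True] * 28 + [False] * 112
        out = [True] * 39 + [False] * 140
        m = diagnostic_metrics(pred, out)
        assert (m.tp, m.fn, m.fp, m.tn) == (36, 3, 28, 112)
        assert m.sensitivity.value == pytest.approx(36 / 39)
        assert m.specificity.value == pytest.approx(0.800)
        assert m.n == 179

    def test_all_correct(self):
        m = diagnostic_metrics([True, False, True], [True, False, True])
        for metric in (m.sensitivity, m.specificity, m.npv, m.ppv):
            assert metric.value == 1.0

    def test_zero_denominator_flagged_not_zero(self):
        m = diagnostic_metrics([False, False], [False, False])
        assert not m.sensitivity.defined and m.sensitivity.value is None
        assert m.specificity.value == 1.0

    def test_counts_partition_n(self, paper_like_records):
        pred = [r.predicted_probability >= 0.5 for r in paper_like_records]
        out = [r.outcome_coao for r in paper_like_records]
        m = diagnostic_metrics(pred, out)
        assert m.tp + m.fp + m.tn + m.fn == len(paper_like_records)
        assert m.tp + m.fn == sum(out)

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            diagnostic_metrics([], [])


class TestWilson:
    @pytest.mark.parametrize("k,n", [(0, 40), (50, 100), (40, 40), (7, 19)])
    def test_matches_closed_form(self, k, n):
        lo, hi = wilson_ci(k, n)
        exp_lo, exp_hi = closed_form_wilson(k, n)
        assert lo == pytest.approx(max(0.0, exp_lo), abs=1e-9)
        assert hi == pytest.approx(min(1.0, exp_hi), abs=1e-9)

    def test_boundary_cases(self):
        assert wilson_ci(40, 40)[1] == 1.0
        assert wilson_ci(0, 40)[0] == 0.0
        lo, hi = wilson_ci(50, 100)
        assert (lo, hi) == (pytest.approx(0.404, abs=1e-3), pytest.approx(0.596, abs=1e-3))

    def test_complement_symmetry(self):
        for k, n in [(3, 17), (0, 9), (12, 12), (25, 80)]:
            lo, hi = wilson_ci(k, n)
            lo_c, hi_c = wilson_ci(n - k, n)
            assert lo == pytest.approx(1 - hi_c, abs=1e-12)
            assert hi == pytest.approx(1 - lo_c, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            wilson_ci(5, 4)


class TestSubgroupsAndBands:
    def test_split_by_onset_boundary(self):
        exam_28 = FetalEchoExam(ga_weeks=28.0, aao_z=0.0, isthmus_3vt_z=0.0, pv_mm=4.0, av_mm=4.0)
        exam_281 = FetalEchoExam(ga_weeks=28.1, aao_z=0.0, isthmus_3vt_z=0.0, pv_mm=4.0, av_mm=4.0)
        records = [
            CohortRecord("a", exam_28, 0.5, True),
            CohortRecord("b", exam_281, 0.5, False),
        ]
        early, late = split_by_onset(records)
        assert [r.record_id for r in early] == ["a"]
        assert [r.record_id for r in late] == ["b"]
        assert split_by_onset([]) == ([], [])

    def test_bands_partition_and_half_open_edges(self, make_records):
        records = make_records([0.35, 0.96, 0.5], [0.1, 0.349999, 0.959999])
        analysis = probability_bands(records)
        assert analysis.total == len(records)
        low, mid, high = analysis.bands
        assert low.count == 2  # 0.1 and 0.349999
        assert mid.count == 3  # 0.35 (inclusive), 0.5, 0.959999
        assert high.count == 1  # 0.96 inclusive

    def test_lower_band_clean_when_cases_score_high(self, make_records):
        records = make_records([0.6, 0.97], [0.1, 0.2, 0.5])
        analysis = probability_bands(records)
        assert analysis.bands[0].coao_count == 0
        assert analysis.bands[0].coao_rate == 0.0

    def test_invalid_band_edges(self, make_records):
        with pytest.raises(ValueError):
            probability_bands(make_records([0.6], [0.1]), low=0.9, high=0.5)

    def test_subgroup_sizes_sum(self, paper_like_records):
        early, late = split_by_onset(paper_like_records)
        assert len(early) + len(late) == len(paper_like_records)


class TestGroupComparisons:
    def test_fisher_no_association_balanced_table(self, model):
        exam_pos = FetalEchoExam(ga_weeks=30, aao_z=0.0, isthmus_3vt_z=0.0,
                                 pv_mm=4.0, av_mm=4.0, plsvc=True)
        exam_neg = exam_pos.with_updates(plsvc=False)
        records = []
        for i in range(4):  # expected cell counts of 4 select Fisher
            records.append(CohortRecord(f"a{i}", exam_pos, 0.5, True))
            records.append(CohortRecord(f"b{i}", exam_neg, 0.5, True))
            records.append(CohortRecord(f"c{i}", exam_pos, 0.5, False))
            records.append(CohortRecord(f"d{i}", exam_neg, 0.5, False))
        comparison = compare_groups(records, "plsvc")
        assert comparison.test == "fisher"
        assert comparison.p_value == pytest.approx(1.0)

    def test_fisher_perfect_association(self):
        exam_pos = FetalEchoExam(ga_weeks=30, aao_z=0.0, isthmus_3vt_z=0.0,
                                 pv_mm=4.0, av_mm=4.0, rfop=True)
        exam_neg = exam_pos.with_updates(rfop=False)
        # 8 vs 12 gives a smallest expected cell of 3.2, selecting Fisher
        records = [CohortRecord(f"a{i}", exam_pos, 0.5, True) for i in range(8)]
        records += [CohortRecord(f"b{i}", exam_neg, 0.5, False) for i in range(12)]
        comparison = compare_groups(records, "rfop")
        assert comparison.test == "fisher"
        assert comparison.p_value < 0.001

    def test_degenerate_constant_variable_flagged(self, make_records):
        records = make_records([0.5, 0.5], [0.5, 0.5])
        comparison = compare_groups(records, "predicted_probability")
        assert comparison.degenerate
        assert comparison.p_value is None

    def test_continuous_comparison_on_cohort(self, paper_like_records):
        comparison = compare_groups(paper_like_records, "ga_weeks")
        assert comparison.test in ("welch_t", "mann_whitney")
        assert 0.0 <= comparison.p_value <= 1.0
        # CoAo fetuses are detected earlier under the generating conditions
        assert (
            comparison.group_summaries["coao"].mean
            < comparison.group_summaries["no_coao"].mean
        )

    def test_insufficient_data_error(self, make_records):
        records = make_records([0.5], [0.4, 0.3])
        with pytest.raises(InsufficientDataError):
            compare_groups(records, "predicted_probability")


class TestSummarizeProbabilities:
    def test_two_point_hand_computation(self, make_records):
        records = make_records([0.2, 0.4], [0.2, 0.4])
        summary = summarize_probabilities(records)
        for stats in summary.values():
            assert stats.mean == pytest.approx(30.0)
            assert stats.sd == pytest.approx(math.sqrt(200.0), abs=1e-9)  # ~14.14

    def test_identical_values_zero_sd(self, make_records):
        summary = summarize_probabilities(make_records([0.3, 0.3], [0.2, 0.2]))
        assert summary["coao"].sd == 0.0

    def test_singleton_group_sd_undefined(self, make_records):
        summary = summarize_probabilities(make_records([0.3], [0.2, 0.4]))
        assert summary["coao"].sd is None
        assert summary["coao"].mean == pytest.approx(30.0)

    def test_empty_group_rejected(self, make_records):
        with pytest.raises(InsufficientDataError):
            summarize_probabilities(make_records([], [0.2]))


class TestProportionPercent:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(39, 179, 21.8), (102, 179, 57.0), (18, 68, 26.5),
         (84, 111, 75.7), (32, 53, 60.4), (6, 35, 17.1)],
    )
    def test_display_rounding(self, k, n, expected):
        assert proportion_percent(k, n) == expected
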