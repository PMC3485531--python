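import numpy as np
import pytest
from scipy import stats

from dyssync.cohort import (
    DEFAULT_DIRECTIONS,
    PatientRecord,
    bland_altman,
    classify_response,
    compare_auc_paired,
    correlate_remodelling,
    evaluate_cohort,
    group_compare,
    hanley_mcneil_ci,
    optimal_cutoff,
    roc_curve,
)
from dyssync.errors import DegenerateDataError, ValidationError

from conftest import fake_report


def brute_force_auc(pos, neg):
    """Concordant-pair fraction with ties counted 1/2 (independent oracle)."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestClassifyResponse:
    def test_table_like_reduction(self):
        responder, delta = classify_response(152.0, 130.0)
        assert responder
        assert delta == pytest.approx(100 * (130 - 152) / 152)
        assert round(-delta, 1) == 14.5

    def test_boundary_is_inclusive(self):
        assert classify_response(100.0, 90.0) == (True, pytest.approx(-10.0))

    def test_increase_is_non_response(self):
        responder, delta = classify_response(100.0, 101.0)
        assert not responder and delta == pytest.approx(1.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValidationError):
            classify_response(0.0, 50.0)


class TestRoc:
    def test_perfect_separation(self):
        scores = [1, 2, 3, 4, 5]
        labels = [False, False, True, True, True]
        roc = roc_curve(scores, labels)
        assert roc.auc == 1.0
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1

    def test_half_concordant(self):
        # responders [1, 3], non-responder [2]: one of two pairs concordant
        roc = roc_curve([1, 3, 2], [True, True, False])
        assert roc.auc == pytest.approx(0.5)

    def test_direction_reversal_complements_auc(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        a = roc_curve(scores, labels, "higher_is_positive").auc
        b = roc_curve(scores, labels, "lower_is_positive").auc
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError, match="single class"):
            roc_curve([1, 2, 3], [True, True, True])

    def test_auc_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n_pos = int(rng.integers(1, 9))
            n_neg = int(rng.integers(1, 9))
            pos = rng.integers(0, 5, n_pos).astype(float)
            neg = rng.integers(0, 5, n_neg).astype(float)
            scores = np.r_[pos, neg]
            labels = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
            roc = roc_curve(scores, labels)
            assert roc.auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_auc_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.3
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(
            sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12
        )

    def test_monotone_curve(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 4, 40).astype(float)
        labels = rng.random(40) < 0.5
        roc = roc_curve(scores, labels)
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_hanley_mcneil_ci_brackets_auc(self):
        lo, hi = hanley_mcneil_ci(0.93, 18, 9)
        assert 0.0 <= lo < 0.93 < hi <= 1.0


class TestOptimalCutoff:
    def test_perfect_separation_all_100(self):
        scores = [1, 2, 3, 4, 5]
        labels = [False, False, True, True, True]
        roc = roc_curve(scores, labels)
        cut = optimal_cutoff(roc, scores, labels)
        assert (cut.sensitivity, cut.specificity, cut.npv, cut.ppv) == (100, 100, 100, 100)
        assert cut.cutoff == 3

    def test_two_by_two_arithmetic(self):
        # TP=17 FN=1 TN=7 FP=2 -> sens 94.4, spec 77.8, ppv 89.5, npv 87.5
        scores = [2.0] * 17 + [0.0] + [0.0] * 7 + [2.0] * 2
        labels = [True] * 18 + [False] * 9
        roc = roc_curve(scores, labels)
        cut = optimal_cutoff(roc, scores, labels)
        assert (cut.tp, cut.fn, cut.tn, cut.fp) == (17, 1, 7, 2)
        assert round(cut.sensitivity, 1) == 94.4
        assert round(cut.specificity, 1) == 77.8
        assert round(cut.ppv, 1) == 89.5
        assert round(cut.npv, 1) == 87.5

    def test_degenerate_equal_scores(self):
        scores = [1.0] * 10
        labels = [True] * 6 + [False] * 4
        roc = roc_curve(scores, labels)
        cut = optimal_cutoff(roc, scores, labels)
        # tie in Youden resolved toward higher sensitivity
        assert cut.sensitivity == 100.0 and cut.specificity == 0.0

    def test_bayes_consistency_of_predictive_values(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(10, 40))
            scores = rng.normal(size=n)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            roc = roc_curve(scores, labels)
            cut = optimal_cutoff(roc, scores, labels)
            sens, spec = cut.sensitivity / 100, cut.specificity / 100
            prev = labels.mean()
            denom_p = sens * prev + (1 - spec) * (1 - prev)
            denom_n = spec * (1 - prev) + (1 - sens) * prev
            if denom_p > 0:
                assert cut.ppv == pytest.approx(100 * sens * prev / denom_p, abs=1e-9)
            if denom_n > 0:
                assert cut.npv == pytest.approx(100 * spec * (1 - prev) / denom_n, abs=1e-9)


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        assert compare_auc_paired(scores, scores, labels) == 1.0

    def test_informative_vs_random_scores_small_p(self):
        rng = np.random.default_rng(6)
        n = 80
        labels = np.r_[np.ones(n // 2, bool), np.zeros(n // 2, bool)]
        scores_a = labels + 0.1 * rng.normal(size=n)  # near-perfect
        scores_b = rng.normal(size=n)  # uninformative
        assert compare_auc_paired(scores_a, scores_b, labels) < 0.01

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            compare_auc_paired([1, 2], [2, 1], [True, True])


class TestBlandAltman:
    def test_identity_observers(self):
        x = np.array([3.0, 5.0, 9.0])
        ba = bland_altman(x, x)
        assert ba.bias == 0.0 and ba.loa_lower == 0.0 and ba.loa_upper == 0.0

    def test_hand_computed_three_pairs(self):
        ba = bland_altman([10, 20, 30], [12, 18, 30])
        assert ba.bias == pytest.approx(0.0)
        assert ba.sd_diff == pytest.approx(2.0)
        assert ba.loa_lower == pytest.approx(-3.92)
        assert ba.loa_upper == pytest.approx(3.92)

    def test_constant_shift_moves_bias_not_width(self):
        rng = np.random.default_rng(7)
        a = rng.normal(10, 2, 50)
        b = a + rng.normal(0, 1, 50)
        ba = bland_altman(a, b)
        ba_shift = bland_altman(a + 5, b)
        assert ba_shift.bias == pytest.approx(ba.bias + 5)
        assert (ba_shift.loa_upper - ba_shift.loa_lower) == pytest.approx(
            ba.loa_upper - ba.loa_lower
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1, 2, 3], [1, 2])


def _cohort_records(resp_vals, non_vals, fu_shift=0.0):
    records = []
    for i, v in enumerate(resp_vals):
        records.append(
            PatientRecord(f"R{i}", fake_report(pre_stv=v),
                          fake_report(pre_stv=v + fu_shift, esv=120.0),
                          delta_esv_pct=-20.0, responder=True)
        )
    for i, v in enumerate(non_vals):
        records.append(
            PatientRecord(f"N{i}", fake_report(pre_stv=v),
                          fake_report(pre_stv=v + fu_shift, esv=152.0),
                          delta_esv_pct=1.3, responder=False)
        )
    return records


class TestGroupCompare:
    def test_identical_groups_give_p_one(self):
        vals = [10.0, 12.0, 14.0, 16.0]
        gc = group_compare(_cohort_records(vals, vals), "pre_stv")
        assert gc.p_between_baseline == pytest.approx(1.0)

    def test_pooled_t_matches_independent_implementation(self):
        sm = pytest.importorskip("statsmodels.stats.weightstats")
        rng = np.random.default_rng(8)
        a = list(rng.normal(30, 10, 12))
        b = list(rng.normal(10, 8, 7))
        gc = group_compare(_cohort_records(a, b), "pre_stv")
        _, p_ref, _ = sm.ttest_ind(np.array(a), np.array(b), usevar="pooled")
        assert gc.p_between_baseline == pytest.approx(p_ref, rel=1e-9)

    def test_welch_variant_differs_under_unequal_variance(self):
        rng = np.random.default_rng(9)
        a = list(rng.normal(30, 25, 12))
        b = list(rng.normal(20, 2, 6))
        recs = _cohort_records(a, b)
        p_student = group_compare(recs, "pre_stv", t_test="student").p_between_baseline
        p_welch = group_compare(recs, "pre_stv", t_test="welch").p_between_baseline
        assert p_student != p_welch

    def test_paired_followup_change_detected(self):
        rng = np.random.default_rng(10)
        a = list(rng.normal(50, 10, 15))
        gc = group_compare(_cohort_records(a, list(rng.normal(5, 2, 6)), fu_shift=-30.0),
                           "pre_stv")
        assert gc.p_paired_responders < 0.001

    def test_small_group_suppressed_to_nan(self):
        gc = group_compare(_cohort_records([10.0, 20.0, 30.0], [5.0]), "pre_stv")
        assert np.isnan(gc.p_between_baseline)


class TestCorrelation:
    def test_perfect_correlations(self):
        d = np.array([-30.0, -20.0, -10.0, 0.0, 5.0])
        assert correlate_remodelling(d, d)[0] == pytest.approx(1.0)
        assert correlate_remodelling(-d, d)[0] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            correlate_remodelling([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_estimator_unbiased_at_moderate_negative_rho(self):
        # bivariate normal with rho = -0.55, n = 28: the mean estimate over
        # 300 replicates must sit within +-0.05 of the true correlation
        rng = np.random.default_rng(11)
        rho = -0.55
        cov = [[1, rho], [rho, 1]]
        rs = []
        for _ in range(300):
            xy = rng.multivariate_normal([0, 0], cov, size=28)
            rs.append(correlate_remodelling(xy[:, 0], xy[:, 1])[0])
        assert np.mean(rs) == pytest.approx(rho, abs=0.05)


class TestEvaluateCohort:
    def test_full_evaluation_structure(self):
        rng = np.random.default_rng(12)
        recs = []
        for i in range(28):
            responder = i < 20
            loc = 50 if responder else 5
            rep = fake_report(
                pre_stv=rng.normal(loc, 10),
                post_stv=rng.normal(8, 3),
                sdi=rng.normal(12 if responder else 7, 2),
                le=rng.normal(40 if responder else 25, 8),
            )
            recs.append(
                PatientRecord(f"P{i}", rep, fake_report(esv=120.0),
                              delta_esv_pct=rng.normal(-20 if responder else 0, 4),
                              responder=responder)
            )
        ev = evaluate_cohort(recs)
        assert set(ev) == set(DEFAULT_DIRECTIONS)
        pre = ev["pre_stv"]
        assert pre["roc"].auc > 0.9
        assert 0 <= pre["cutoff"].sensitivity <= 100
        assert pre["groups"].n_responders == 20
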