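"""Confusion matrices, one-vs-rest metrics, macro averaging and ROC/AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn import metrics as skm

from chipcnn.evaluate import (ConfusionMatrix, OneVsRestCounts,
                              confusion_matrix, evaluate_predictions,
                              macro_summary, metrics, one_vs_rest, roc_auc,
                              summarize_folds)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.repeat([0, 1, 2, 3], 112)
        cm = confusion_matrix(y, y)
        np.testing.assert_array_equal(cm.counts, np.eye(4) * 112)

    def test_collapse_to_level0_fills_first_column(self):
        y = np.repeat([0, 1, 2, 3], 5)
        cm = confusion_matrix(y, np.zeros_like(y))
        np.testing.assert_array_equal(cm.counts[:, 0], [5, 5, 5, 5])
        assert cm.counts[:, 1:].sum() == 0

    def test_row_sums_conserved_under_any_predictions(self, rng):
        y = np.repeat([0, 1, 2, 3], 112)
        pred = rng.integers(0, 4, size=y.size)
        cm = confusion_matrix(y, pred)
        np.testing.assert_array_equal(cm.counts.sum(axis=1), [112] * 4)

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 4], [0, 0])

    def test_matches_sklearn(self, rng):
        y = rng.integers(0, 4, 200)
        p = rng.integers(0, 4, 200)
        np.testing.assert_array_equal(confusion_matrix(y, p).counts,
                                      skm.confusion_matrix(y, p, labels=range(4)))


class TestOneVsRest:
    def test_fold_averaged_level0_worked_counts(self):
        """The fold-averaged matrix with 111.6 correct level-0 calls and 0.4
        leaking into level 1 reduces to TP=111.6, FN=0.4."""
        counts = np.diag([111.6, 92.7, 101.8, 99.2])
        counts[0, 1] = 0.4
        counts[1, 0] = 19.3
        counts[2, 3] = 10.2
        counts[3, 2] = 12.8
        ovr = one_vs_rest(ConfusionMatrix(counts), 0)
        assert ovr.TP == pytest.approx(111.6)
        assert ovr.FN == pytest.approx(0.4)

    def test_scaled_identity_matrix(self):
        ovr = one_vs_rest(ConfusionMatrix(np.eye(4) * 7), 2)
        assert (ovr.TP, ovr.FN, ovr.FP) == (7, 0, 0)

    @pytest.mark.parametrize("level", range(4))
    def test_counts_conserve_matrix_total(self, level, rng):
        cm = ConfusionMatrix(rng.integers(0, 50, (4, 4)))
        ovr = one_vs_rest(cm, level)
        assert ovr.TP + ovr.FN + ovr.FP + ovr.TN == cm.total
        assert ovr.TP + ovr.FN == cm.counts[level].sum()


class TestMetrics:
    def test_worked_sensitivity_99_6(self):
        """TP=111.6, FN=0.4 out of 112 -> sensitivity 111.6/112 = 99.6%."""
        m = metrics(OneVsRestCounts(TP=111.6, FN=0.4, FP=2.0, TN=334.0))
        assert round(m["sensitivity"], 1) == 99.6

    def test_perfect_counts_give_all_100(self):
        m = metrics(OneVsRestCounts(TP=50, FN=0, FP=0, TN=50))
        assert all(v == pytest.approx(100.0) for v in m.values())

    def test_f1_harmonic_mean(self):
        # precision 50%, recall 100% -> F1 = 2*0.5*1/(1.5) = 66.7%
        m = metrics(OneVsRestCounts(TP=10, FN=0, FP=10, TN=20))
        assert m["precision"] == pytest.approx(50.0)
        assert m["recall"] == pytest.approx(100.0)
        assert round(m["f1"], 1) == 66.7

    def test_sensitivity_equals_recall_always(self, rng):
        for _ in range(20):
            tp, fn, fp, tn = rng.integers(0, 30, 4)
            m = metrics(OneVsRestCounts(float(tp), float(fn), float(fp), float(tn)))
            if not np.isnan(m["recall"]):
                assert m["sensitivity"] == m["recall"]

    def test_zero_denominator_flagged_undefined(self):
        m = metrics(OneVsRestCounts(TP=0, FN=0, FP=0, TN=10))
        assert np.isnan(m["precision"]) and np.isnan(m["recall"])
        assert m["specificity"] == pytest.approx(100.0)


class TestRocAuc:
    def test_perfect_separation_auc_1(self):
        pts, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(1.0)

    def test_inverted_scores_auc_0(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert auc == pytest.approx(0.0)

    def test_curve_runs_from_origin_to_one_one(self, rng):
        pts, _ = roc_auc(rng.random(50), rng.integers(0, 2, 50))
        np.testing.assert_allclose(pts[0], [0.0, 0.0])
        np.testing.assert_allclose(pts[-1], [1.0, 1.0])

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        _, a = roc_auc(scores, labels)
        _, b = roc_auc(np.exp(3 * scores) - 1, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_matches_sklearn_with_ties(self, seed):
        """Independent oracle: sklearn's roc_curve/auc on tied, coarse scores."""
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, 40) / 4.0
        labels = rng.integers(0, 2, 40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pts, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(skm.roc_auc_score(labels, scores), abs=1e-12)
        # keep every threshold (no collinear-point pruning) for comparison
        fpr, tpr, _ = skm.roc_curve(labels, scores, drop_intermediate=False)
        np.testing.assert_allclose(pts[:, 0], fpr, atol=1e-12)
        np.testing.assert_allclose(pts[:, 1], tpr, atol=1e-12)


class TestMacroSummary:
    def _report(self, y, pred_scores, fold):
        return evaluate_predictions(y, pred_scores, fold_id=fold)

    def test_single_fold_sd_zero(self, rng):
        y = np.repeat([0, 1, 2, 3], 10)
        scores = np.eye(4)[y] + rng.random((40, 4)) * 0.01
        summary = summarize_folds([self._report(y, scores, 0)])
        assert (summary["sd"] == 0).all()

    def test_two_fold_mean_and_sd_hand_computed(self):
        y = np.repeat([0, 1, 2, 3], 5)
        perfect = np.eye(4)[y]
        off = perfect.copy()
        # one level-1 sample called level 2 in the second fold
        off[5] = np.eye(4)[2]
        reports = [self._report(y, perfect, 0), self._report(y, off, 1)]
        summary = summarize_folds(reports)
        a0, a1 = reports[0].macro["recall"], reports[1].macro["recall"]
        assert summary.loc["recall", "mean"] == pytest.approx((a0 + a1) / 2)
        assert summary.loc["recall", "sd"] == pytest.approx(
            np.std([a0, a1], ddof=1))

    def test_mean_confusion_preserves_row_sums(self, rng):
        y = np.repeat([0, 1, 2, 3], 28)
        reports = [self._report(y, rng.random((112, 4)), f) for f in range(3)]
        mean_cm = macro_summary(reports)["mean_confusion"]
        np.testing.assert_allclose(mean_cm.counts.sum(axis=1), [28] * 4)

    def test_specificity_complements_roc_fpr(self, rng):
        """1 - specificity at the argmax operating point lies on the ROC's
        FPR axis scale: spot-check the identity specificity = 1 - FPR."""
        y = np.repeat([0, 1, 2, 3], 25)
        scores = np.eye(4)[y] * 0.5 + rng.random((100, 4))
        rep = evaluate_predictions(y, scores)
        for lv in range(4):
            ovr = one_vs_rest(rep.cm, lv)
            fpr = ovr.FP / (ovr.FP + ovr.TN)
            assert rep.per_level.loc[lv, "specificity"] == pytest.approx(
                100 * (1 - fpr))
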