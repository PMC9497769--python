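"""Confusion metrics, ROC AUC, macro-averaging, error maps.

The metric formulas are cross-checked against scikit-learn and against an
exhaustive pairwise brute force for the AUC.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from hsitissue.evaluation import (
    ConfusionCounts,
    confusion,
    error_map,
    image_metrics,
    macro_average,
    metrics_from_counts,
    misclassified_count,
    roc_auc,
)
from hsitissue.model import PredictionMap


class TestConfusion:
    def test_perfect_prediction_has_no_errors(self):
        t = np.array([1, 1, 2, 2, 1])
        c = confusion(t, t, positive_class=1)
        assert (c.fp, c.fn) == (0, 0)
        assert c.total == 5

    def test_inverted_prediction_has_no_hits(self):
        t = np.array([1, 1, 2, 2])
        p = np.array([2, 2, 1, 1])
        c = confusion(t, p, positive_class=1)
        assert (c.tp, c.tn) == (0, 0)

    def test_hand_enumerated_example(self):
        c = confusion(np.array([1, 1, 1, 2]), np.array([1, 1, 2, 2]),
                      positive_class=1)
        assert (c.tp, c.fn, c.tn, c.fp) == (2, 1, 1, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion(np.array([1, 2]), np.array([1]), positive_class=1)


class TestMetricsFromCounts:
    def test_worked_example(self):
        m = metrics_from_counts(ConfusionCounts(tp=8, fn=2, tn=5, fp=5))
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["specificity"] == pytest.approx(0.5)
        assert m["f1"] == pytest.approx(16 / 23, abs=1e-4)
        assert m["mcc"] == pytest.approx(30 / np.sqrt(9100), abs=1e-4)

    def test_perfect_counts_score_one(self):
        m = metrics_from_counts(ConfusionCounts(tp=10, fn=0, tn=4, fp=0))
        assert all(m[k] == 1.0 for k in ("sensitivity", "specificity", "f1", "mcc"))

    def test_truth_independent_prediction_has_zero_mcc(self):
        # predictions split 50/50 regardless of the truth
        m = metrics_from_counts(ConfusionCounts(tp=30, fn=30, fp=10, tn=10))
        assert m["mcc"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_denominator_yields_nan_sentinel(self):
        m = metrics_from_counts(ConfusionCounts(tp=5, fn=0, tn=0, fp=0))
        assert np.isnan(m["specificity"])
        assert np.isnan(m["mcc"])
        assert m["sensitivity"] == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_sklearn_on_random_tables(self, seed):
        """1,000 random confusion tables against the reference implementation."""
        rng = np.random.default_rng(seed)
        for _ in range(250):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 40, 4))
            if tp + fn == 0 or tn + fp == 0:
                continue
            truth = np.array([1] * (tp + fn) + [2] * (tn + fp))
            pred = np.array([1] * tp + [2] * fn + [1] * fp + [2] * tn)
            m = metrics_from_counts(confusion(truth, pred, positive_class=1))
            sk_mcc = matthews_corrcoef(truth, pred)
            if not np.isnan(m["mcc"]):
                assert m["mcc"] == pytest.approx(sk_mcc, abs=1e-10)
            recalls = {c: np.mean(pred[truth == c] == c) for c in (1, 2)}
            assert m["sensitivity"] == pytest.approx(recalls[1], abs=1e-12)
            assert m["specificity"] == pytest.approx(recalls[2], abs=1e-12)


class TestRocAuc:
    def test_perfectly_ordered_scores(self):
        assert roc_auc(np.array([1, 1, 2, 2]), np.array([0.9, 0.8, 0.2, 0.1])) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc(np.array([1, 2, 1, 2]), np.full(4, 0.3)) == 0.5

    def test_worked_pairwise_example(self):
        # wins 3 of 4 positive-negative pairs
        auc = roc_auc(np.array([1, 1, 2, 2]), np.array([0.9, 0.4, 0.6, 0.2]))
        assert auc == pytest.approx(0.75)

    def test_single_class_truth_gives_nan(self):
        assert np.isnan(roc_auc(np.array([1, 1]), np.array([0.2, 0.9])))

    @given(st.data())
    @settings(max_examples=120, derandomize=True, deadline=None)
    def test_matches_exhaustive_pairwise_brute_force(self, data):
        n = data.draw(st.integers(2, 40))
        truth = np.array(data.draw(
            st.lists(st.sampled_from([1, 2]), min_size=n, max_size=n)))
        scores = np.array(data.draw(st.lists(
            st.floats(0, 1, allow_nan=False, width=32), min_size=n, max_size=n)))
        pos, neg = scores[truth == 1], scores[truth == 2]
        if len(pos) == 0 or len(neg) == 0:
            return
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        expected = wins / (len(pos) * len(neg))
        assert roc_auc(truth, scores) == pytest.approx(expected, abs=1e-12)
        assert roc_auc(truth, scores) == pytest.approx(
            roc_auc_score(truth == 1, scores), abs=1e-12)


class TestImageMetrics:
    def test_two_class_mirror_identity(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(1, 3, 200)
        pred = rng.integers(1, 3, 200)
        scores = rng.random(200)
        im = image_metrics(truth, pred, scores)
        assert im.per_class[1]["sensitivity"] == im.per_class[2]["specificity"]
        assert im.per_class[2]["sensitivity"] == im.per_class[1]["specificity"]
        assert im.per_class[1]["mcc"] == pytest.approx(im.per_class[2]["mcc"],
                                                       abs=1e-12)
        assert im.per_class[1]["roc_auc"] == pytest.approx(
            im.per_class[2]["roc_auc"], abs=1e-12)


class TestMacroAverage:
    @staticmethod
    def _image(aid, sens):
        truth = np.array([1] * 10 + [2] * 10)
        k = int(round(sens * 10))
        pred = np.array([1] * k + [2] * (10 - k) + [2] * 10)
        return image_metrics(truth, pred, animal_id=aid)

    def test_identical_images_have_zero_sd(self):
        cm = macro_average([self._image("a", 0.8), self._image("b", 0.8)])
        assert cm.mean[1]["sensitivity"] == pytest.approx(0.8)
        assert cm.sd[1]["sensitivity"] == 0.0

    def test_hand_computed_mean_and_population_sd(self):
        cm = macro_average([self._image("a", 0.8), self._image("b", 1.0)])
        assert cm.mean[1]["sensitivity"] == pytest.approx(0.9)
        assert cm.sd[1]["sensitivity"] == pytest.approx(0.1)

    def test_sample_sd_option(self):
        cm = macro_average([self._image("a", 0.8), self._image("b", 1.0)], ddof=1)
        assert cm.sd[1]["sensitivity"] == pytest.approx(0.1 * np.sqrt(2))

    def test_nan_metrics_excluded_and_counted(self):
        truth_single = np.array([1] * 8)  # no negatives: specificity undefined
        im_single = image_metrics(truth_single, truth_single, animal_id="s")
        cm = macro_average([self._image("a", 0.8), im_single])
        assert cm.n_excluded[1]["specificity"] == 1
        assert cm.mean[1]["sensitivity"] == pytest.approx(0.9)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="no image"):
            macro_average([])

    def test_report_frame_shape(self):
        frame = macro_average([self._image("a", 0.8)]).to_frame()
        assert frame.shape[0] == 2  # one row per tissue class


class TestErrorMap:
    @staticmethod
    def _prediction(truth, pred_labels):
        class_map = pred_labels.astype(np.uint8)
        score = np.zeros((*truth.shape, 2), dtype=np.float32)
        score[..., 0] = (class_map == 1).astype(np.float32)
        score[..., 1] = 1 - score[..., 0]
        return PredictionMap(class_map, score, "x")

    def test_perfect_prediction_has_no_misclassified(self):
        truth = np.zeros((8, 8), dtype=np.uint8)
        truth[2:5, 2:5] = 1
        pm = self._prediction(truth, truth)
        assert misclassified_count(truth, pm) == 0

    def test_inverted_prediction_flags_all_annotated(self):
        truth = np.zeros((8, 8), dtype=np.uint8)
        truth[2:5, 2:5] = 1
        truth[6, 1:7] = 2
        inverted = np.where(truth == 1, 2, np.where(truth == 2, 1, 0))
        pm = self._prediction(truth, inverted)
        assert misclassified_count(truth, pm) == int((truth > 0).sum())

    def test_injected_error_count_recovered(self):
        rng = np.random.default_rng(7)
        truth = np.zeros((12, 12), dtype=np.uint8)
        truth[3:9, 3:9] = 1
        pred = truth.copy()
        flips = [(4, 4), (5, 7), (8, 3)]
        for r, c in flips:
            pred[r, c] = 2
        pm = self._prediction(truth, pred)
        assert misclassified_count(truth, pm) == len(flips)
        rgb = error_map(truth, pm)
        from hsitissue.evaluation import ERROR_MAP_COLORS

        n_red = int(np.all(rgb == ERROR_MAP_COLORS["misclassified"], axis=-1).sum())
        assert n_red == len(flips)

    def test_shape_mismatch_rejected(self):
        truth = np.zeros((4, 4), dtype=np.uint8)
        pm = self._prediction(np.zeros((5, 5), dtype=np.uint8),
                              np.zeros((5, 5), dtype=np.uint8))
        with pytest.raises(ValueError, match="shape"):
            error_map(truth, pm)
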