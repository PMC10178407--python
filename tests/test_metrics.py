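"""Metric correctness against brute-force oracles.

Oracles are written independently of the implementation: per-pixel loops for
the confusion table, an explicit threshold sweep for average precision, and
the rank statistic (probability that a random positive outranks a random
negative) for AUC.  scikit-learn serves as an additional independent
cross-check.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from woundseg.metrics import (
    ConfusionCounts,
    average_precision,
    confusion,
    dice,
    evaluate_set,
    iou,
    map_over_set,
    miou,
    recall,
    roc_auc,
)

RNG = np.random.default_rng(314159)


# -- oracles -------------------------------------------------------------------


def confusion_oracle(pred, gt):
    tp = fp = fn = tn = 0
    for p, g in zip(pred.ravel(), gt.ravel()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def ap_oracle(scores, labels):
    """Explicit threshold sweep: AP = Σ (R_k − R_{k−1}) P_k over descending
    distinct thresholds."""
    scores, labels = scores.ravel(), labels.ravel().astype(bool)
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = (pred & labels).sum()
        prec = tp / pred.sum()
        rec = tp / n_pos
        ap += (rec - prev_recall) * prec
        prev_recall = rec
    return ap


def auc_rank_oracle(scores, labels):
    """P(random positive > random negative) + ½·P(tie)."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    wins = ties = 0
    for p in pos:
        wins += (p > neg).sum()
        ties += (p == neg).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def miou_oracle(table):
    vals = []
    k = table.shape[0]
    for i in range(k):
        union = table[i, :].sum() + table[:, i].sum() - table[i, i]
        if union:
            vals.append(table[i, i] / union)
    return float(np.mean(vals))


# -- tests ---------------------------------------------------------------------


class TestConfusionAndRatios:
    def test_matches_pixel_loop_on_random_instances(self):
        for _ in range(20):
            pred = (RNG.random((16, 16)) > 0.5).astype(np.uint8)
            gt = (RNG.random((16, 16)) > 0.5).astype(np.uint8)
            c = confusion(pred, gt)
            assert (c.tp, c.fp, c.fn, c.tn) == confusion_oracle(pred, gt)
            assert c.total == 256

    def test_perfect_prediction_counts(self):
        gt = np.zeros((4, 4), np.uint8)
        gt[:2] = 1
        c = confusion(gt, gt)
        assert (c.tp, c.fp, c.fn, c.tn) == (8, 0, 0, 8)

    def test_all_positive_prediction_on_half_positive_truth(self):
        gt = np.array([[1, 1], [0, 0]], np.uint8)
        c = confusion(np.ones_like(gt), gt)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 2, 0, 0)

    def test_shape_and_binarity_enforced(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2)), np.zeros((2, 3)))
        with pytest.raises(ValueError, match="binary"):
            confusion(np.full((2, 2), 2), np.zeros((2, 2)))

    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(2, 0, 2, 0), 0.5),
            (ConfusionCounts(5, 3, 0, 0), 1.0),
            (ConfusionCounts(0, 0, 4, 0), 0.0),
        ],
    )
    def test_recall_values(self, counts, expected):
        assert recall(counts) == expected

    def test_undefined_metrics_are_missing_not_zero(self):
        empty = ConfusionCounts(0, 0, 0, 10)
        assert recall(empty) is None
        assert dice(empty) is None
        assert iou(empty) is None

    def test_dice_iou_on_known_overlap(self):
        # |A|=4, |B|=4, overlap 2 → IoU 1/3, dice 1/2
        pred = np.array([[1, 1, 1, 1, 0, 0]], np.uint8)
        gt = np.array([[0, 0, 1, 1, 1, 1]], np.uint8)
        c = confusion(pred, gt)
        assert iou(c) == pytest.approx(1 / 3)
        assert dice(c) == pytest.approx(0.5)

    @given(
        st.tuples(
            st.integers(0, 200), st.integers(0, 200), st.integers(0, 200),
            st.integers(0, 200),
        )
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_dice_iou_identity_over_random_tables(self, tfpn):
        c = ConfusionCounts(*tfpn)
        d, j = dice(c), iou(c)
        if d is None:
            assert j is None
        else:
            assert d == pytest.approx(2 * j / (1 + j))


class TestMiou:
    def test_perfect_two_class_prediction(self):
        assert miou(np.array([[10, 0], [0, 6]])) == 1.0

    def test_matches_oracle_on_random_tables(self):
        for _ in range(20):
            t = RNG.integers(0, 50, size=(2, 2))
            if t.sum() == 0 or (t[0].sum() + t[:, 0].sum()) == 0:
                continue
            assert miou(t) == pytest.approx(miou_oracle(t), abs=1e-12)

    def test_single_class_predicted_everywhere(self):
        # truth balanced, everything predicted background
        t = np.array([[8, 0], [8, 0]])
        assert miou(t) == pytest.approx(miou_oracle(t), abs=1e-12)

    def test_absent_class_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            val = miou(np.array([[5, 0], [0, 0]]))
        assert val == 1.0


class TestAveragePrecision:
    def test_perfect_separation_gives_one(self):
        gt = np.array([[0, 0, 1, 1]], np.uint8)
        probs = np.array([[0.1, 0.2, 0.8, 0.9]])
        assert average_precision(probs, gt) == pytest.approx(1.0)

    def test_matches_threshold_sweep_oracle(self):
        for _ in range(100):
            gt = (RNG.random((16, 16)) > 0.6).astype(np.uint8)
            if gt.sum() == 0:
                continue
            probs = RNG.random((16, 16))
            assert average_precision(probs, gt) == pytest.approx(
                ap_oracle(probs, gt), abs=1e-9
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import average_precision_score

        for _ in range(20):
            gt = (RNG.random(200) > 0.5).astype(np.uint8)
            probs = RNG.random(200)
            assert average_precision(probs, gt) == pytest.approx(
                average_precision_score(gt, probs), abs=1e-9
            )

    def test_anti_ranked_scores_approach_prevalence(self):
        gt = np.r_[np.ones(20), np.zeros(80)].astype(np.uint8)
        probs = np.linspace(0, 1, 100)  # positives get the lowest scores
        ap = average_precision(probs, gt)
        assert ap == pytest.approx(ap_oracle(probs, gt), abs=1e-9)
        assert 0.2 * 0.5 < ap < 0.35  # near (worst-case) positive prevalence

    def test_empty_ground_truth_is_missing(self):
        assert average_precision(np.ones((2, 2)), np.zeros((2, 2), np.uint8)) is None

    def test_map_is_the_mean_of_per_image_ap(self):
        gt1 = np.array([[0, 1]], np.uint8)
        item_ap1 = (np.array([[0.1, 0.9]]), gt1)          # AP = 1
        item_ap05 = (np.array([[0.9, 0.5]]), gt1)         # AP = 0.5
        assert map_over_set([item_ap1, item_ap05]) == pytest.approx(0.75)


class TestRocAuc:
    def test_perfect_separation(self):
        gt = np.array([[0, 0, 1, 1]], np.uint8)
        probs = np.array([[0.1, 0.2, 0.8, 0.9]])
        _, auc = roc_auc(probs, gt)
        assert auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        gt = np.array([[0, 1, 0, 1]], np.uint8)
        _, auc = roc_auc(np.full((1, 4), 0.5), gt)
        assert auc == pytest.approx(0.5)

    def test_matches_rank_statistic_oracle(self):
        for _ in range(100):
            gt = (RNG.random(64) > 0.5).astype(np.uint8)
            if gt.sum() in (0, 64):
                continue
            probs = np.round(RNG.random(64), 2)  # force ties
            _, auc = roc_auc(probs.reshape(8, 8), gt.reshape(8, 8))
            assert auc == pytest.approx(auc_rank_oracle(probs, gt), abs=1e-9)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        gt = (RNG.random(500) > 0.5).astype(np.uint8)
        probs = RNG.random(500)
        _, auc = roc_auc(probs.reshape(20, 25), gt.reshape(20, 25))
        assert auc == pytest.approx(roc_auc_score(gt, probs), abs=1e-9)

    def test_random_scores_near_half(self):
        gt = (RNG.random(10_000) > 0.5).astype(np.uint8)
        probs = RNG.random(10_000)
        _, auc = roc_auc(probs.reshape(100, 100), gt.reshape(100, 100))
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones((2, 2)) * 0.5, np.ones((2, 2), np.uint8))

    def test_permutation_invariance(self):
        gt = (RNG.random(144) > 0.5).astype(np.uint8)
        probs = RNG.random(144)
        perm = RNG.permutation(144)
        _, a1 = roc_auc(probs.reshape(12, 12), gt.reshape(12, 12))
        _, a2 = roc_auc(probs[perm].reshape(12, 12), gt[perm].reshape(12, 12))
        assert a1 == pytest.approx(a2, abs=1e-12)


def test_evaluate_set_aggregates_per_image_means():
    gts = [(RNG.random((12, 12)) > 0.5).astype(np.uint8) for _ in range(3)]
    # probabilities correlated with the truth
    probs = [np.clip(g + RNG.normal(0, 0.3, g.shape), 0, 1) for g in gts]
    report = evaluate_set(probs, gts)
    assert report.n_items == 3
    for value in (report.map, report.miou, report.recall, report.dice, report.auc):
        assert 0.0 <= value <= 1.0
    assert report.dice == pytest.approx(report.per_image["dice"].mean())
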