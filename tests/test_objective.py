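"""Loss closed forms and WT/TC/ET metric behaviour."""

import numpy as np
import pytest

from fusionseg.nn import Tensor, softmax
from fusionseg.objective import (
    LossWeights,
    cross_entropy,
    dice_loss,
    evaluate,
    hd95,
    mean_region_scores,
    region_masks,
    seg_loss,
    total_loss,
)


def _one_hot_logits(labels, k=4, scale=50.0):
    n, h, w = labels.shape
    logits = np.full((n, k, h, w), 0.0, dtype=np.float32)
    for c in range(k):
        logits[:, c][labels == c] = scale
    return logits


class TestDiceLoss:
    def test_perfect_one_hot_prediction_scores_zero(self):
        labels = np.random.default_rng(0).integers(0, 4, (1, 8, 8))
        probs = softmax(Tensor(_one_hot_logits(labels)), axis=1)
        assert dice_loss(probs, labels).item() < 1e-3

    def test_fully_disjoint_prediction_scores_one(self):
        """Truth uses classes {0,1}, prediction {2,3}: every class overlap is 0."""
        labels = np.zeros((1, 8, 8), dtype=np.int64)
        labels[:, 4:] = 1
        wrong = np.full((1, 8, 8), 2, dtype=np.int64)
        wrong[:, 4:] = 3
        probs = softmax(Tensor(_one_hot_logits(wrong)), axis=1)
        assert dice_loss(probs, labels).item() > 0.999

    def test_uniform_prediction_matches_hand_evaluation(self):
        """Uniform probabilities on a one-pixel single-class image, by hand.

        With p_c = 1/4 everywhere and the true class occupying the whole
        (single-pixel) image: dice_true = 2*(1/4)/(1/4+1) = 2/5 and
        dice_other = 0 for the three absent classes, so the class-mean soft
        Dice is 0.1 and the loss 0.9 (up to the smoothing constant).
        """
        labels = np.zeros((1, 1, 1), dtype=np.int64)
        probs = Tensor(np.full((1, 4, 1, 1), 0.25, dtype=np.float32))
        expected = 1.0 - (2 * 0.25 / (0.25 + 1.0)) / 4
        assert dice_loss(probs, labels, smooth=0.0).item() == pytest.approx(expected, abs=1e-6)

    def test_bounded_by_one(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 4, (2, 6, 6))
        probs = softmax(Tensor(rng.standard_normal((2, 4, 6, 6)).astype(np.float32)), axis=1)
        val = dice_loss(probs, labels).item()
        assert 0.0 <= val <= 1.0 + 1e-4


class TestCrossEntropy:
    def test_uniform_logits_give_log4(self):
        logits = Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32))
        labels = np.zeros((1, 8, 8), dtype=np.int64)
        assert cross_entropy(logits, labels).item() == pytest.approx(np.log(4), abs=1e-6)

    def test_confident_correct_prediction_near_zero(self):
        labels = np.random.default_rng(0).integers(0, 4, (1, 8, 8))
        assert cross_entropy(Tensor(_one_hot_logits(labels)), labels).item() < 1e-4

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        logits = rng.standard_normal((1, 4, 5, 5)).astype(np.float32)
        labels = rng.integers(0, 4, (1, 5, 5))
        a = cross_entropy(Tensor(logits), labels).item()
        b = cross_entropy(Tensor(logits + 3.7), labels).item()
        assert a == pytest.approx(b, abs=1e-5)


class TestSegLoss:
    def test_default_weights_match_stated_mixture(self):
        w = LossWeights()
        assert (w.alpha, w.beta) == (1.0, 0.5)

    def test_perfect_prediction_near_zero(self):
        labels = np.random.default_rng(3).integers(0, 4, (2, 8, 8))
        val = seg_loss(Tensor(_one_hot_logits(labels)), labels).item()
        assert val < 1e-3

    def test_batch_mean_normalization(self):
        """Duplicating a sample leaves the batch-mean loss unchanged."""
        rng = np.random.default_rng(4)
        logits = rng.standard_normal((1, 4, 6, 6)).astype(np.float32)
        labels = rng.integers(0, 4, (1, 6, 6))
        single = seg_loss(Tensor(logits), labels).item()
        double = seg_loss(
            Tensor(np.concatenate([logits, logits])), np.concatenate([labels, labels])
        ).item()
        assert single == pytest.approx(double, rel=1e-5)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            seg_loss(Tensor(np.zeros((0, 4, 2, 2), dtype=np.float32)), np.zeros((0, 2, 2), int))


class TestTotalLoss:
    def test_linear_in_similarity_term(self):
        w = LossWeights(lambda_sim=0.5)
        assert total_loss(2.0, 0.0, w) == 2.0
        assert total_loss(2.0, 1.0, w) == 2.5
        assert total_loss(2.0, 2.0, w) == 3.0

    def test_zero_lambda_drops_the_pretext_term(self):
        w = LossWeights(lambda_sim=0.0)
        assert total_loss(1.25, 0.9, w) == 1.25


class TestRegions:
    def test_one_pixel_per_class_counts(self):
        labels = np.zeros((2, 2), dtype=np.int64)
        labels[0, 0], labels[0, 1], labels[1, 0] = 1, 2, 3
        masks = region_masks(labels)
        assert int(masks["WT"].sum()) == 3
        assert int(masks["TC"].sum()) == 2
        assert int(masks["ET"].sum()) == 1

    def test_all_background_gives_empty_regions(self):
        masks = region_masks(np.zeros((4, 4), dtype=np.int64))
        assert not any(m.any() for m in masks.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_containment_holds_for_any_label_map(self, seed):
        labels = np.random.default_rng(seed).integers(0, 4, (16, 16))
        masks = region_masks(labels)
        assert (masks["ET"] <= masks["TC"]).all()
        assert (masks["TC"] <= masks["WT"]).all()

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            region_masks(np.array([[0, 5]]))


class TestHD95:
    def test_two_by_two_toy_case(self):
        """T={(0,0)}, P={(0,1)}: all nearest-boundary distances are exactly 1."""
        pred = np.zeros((2, 2), dtype=bool)
        truth = np.zeros((2, 2), dtype=bool)
        pred[0, 1] = True
        truth[0, 0] = True
        assert hd95(pred, truth) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = rng.random((16, 16)) > 0.6
        b = rng.random((16, 16)) > 0.6
        assert hd95(a, b) == pytest.approx(hd95(b, a))

    def test_identical_regions_score_zero(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:5, 3:6] = True
        assert hd95(mask, mask) == 0.0

    def test_empty_cases(self):
        empty = np.zeros((8, 8), dtype=bool)
        full = ~empty.copy()
        full[:] = False
        full[1, 1] = True
        assert hd95(empty, empty) == 0.0
        assert hd95(full, empty) == pytest.approx(np.hypot(8, 8))
        assert hd95(full, empty, empty_penalty=42.0) == 42.0


class TestEvaluate:
    def test_truth_against_itself_is_perfect(self, phantom_case):
        scores = evaluate(phantom_case.labels, phantom_case.labels)
        for region in ("WT", "TC", "ET"):
            s = scores[region]
            assert (s.dice, s.sensitivity, s.specificity, s.hd95) == (1.0, 1.0, 1.0, 0.0)

    def test_disjoint_prediction_scores_zero_dice(self):
        truth = np.zeros((8, 8), dtype=np.int64)
        truth[0:2, 0:2] = 2
        pred = np.zeros((8, 8), dtype=np.int64)
        pred[6:8, 6:8] = 2
        assert evaluate(pred, truth)["WT"].dice == 0.0

    def test_mean_region_scores(self):
        truth = np.zeros((4, 4), dtype=np.int64)
        truth[0, 0] = 3
        perfect = evaluate(truth, truth)
        miss = evaluate(np.zeros_like(truth), truth)
        mean = mean_region_scores([perfect, miss])
        assert mean["ET"].dice == pytest.approx(0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            evaluate(np.zeros((2, 2), int), np.zeros((3, 3), int))
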