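"""Training losses and segmentation metrics.

The segmentation loss is a weighted mixture of soft Dice loss and pixel
cross-entropy, averaged over the batch; the total objective adds the
self-supervised similarity term. Evaluation follows the BraTS convention
of three nested regions — whole tumor WT = {1, 2, 3}, tumor core
TC = {1, 3}, enhancing tumor ET = {3} (internal 3 is raw class 4) — each
scored by Dice, sensitivity, specificity, and the 95th-percentile
Hausdorff distance over boundary pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .nn import Tensor, softmax, softmax_cross_entropy

__all__ = [
    "LossWeights",
    "RegionScores",
    "REGION_LABELS",
    "dice_loss",
    "cross_entropy",
    "seg_loss",
    "total_loss",
    "region_masks",
    "hd95",
    "evaluate",
    "mean_region_scores",
]

REGION_LABELS = {"WT": (1, 2, 3), "TC": (1, 3), "ET": (3,)}

DICE_SMOOTH = 1e-5


@dataclass
class LossWeights:
    """Coefficients of the combined objective."""

    alpha: float = 1.0  # Dice term
    beta: float = 0.5  # cross-entropy term
    lambda_sim: float = 1.0  # similarity term in the total objective
    epsilon: float = 1e-5  # similarity-loss smoothing
    dice_smooth: float = DICE_SMOOTH

    def __post_init__(self):
        if min(self.alpha, self.beta, self.lambda_sim, self.epsilon) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class RegionScores:
    """Evaluation record for one tumor region."""

    dice: float
    sensitivity: float
    specificity: float
    hd95: float


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    flat = np.eye(n_classes, dtype=np.float32)[labels.reshape(-1)]
    return flat.reshape(*labels.shape, n_classes)


def dice_loss(
    probs: Tensor,
    labels: np.ndarray,
    smooth: float = DICE_SMOOTH,
    include_background: bool = True,
) -> Tensor:
    """Soft Dice loss: one minus the class-mean probability-weighted Dice.

    ``probs`` is an (N, K, H, W) per-pixel probability map (summing to one
    over classes); per class c the overlap term is
    ``(2 * sum(p_c * y_c) + s) / (sum(p_c) + sum(y_c) + s)``.
    """
    n, k, h, w = probs.shape
    labels = np.asarray(labels)
    if labels.shape != (n, h, w):
        raise ValueError(f"labels shape {labels.shape} != {(n, h, w)}")
    onehot = _one_hot(labels, k).transpose(0, 3, 1, 2)  # (N, K, H, W)
    classes = list(range(k)) if include_background else list(range(1, k))
    total = None
    for c in classes:
        y_c = onehot[:, c]
        p_c = probs.narrow(1, c, 1)
        inter = (p_c * Tensor(y_c[:, None])).sum()
        denom = p_c.sum() + float(y_c.sum())
        d = (2.0 * inter + smooth) / (denom + smooth)
        total = d if total is None else total + d
    return 1.0 - total * (1.0 / len(classes))


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-pixel negative log-likelihood under softmax."""
    return softmax_cross_entropy(logits, np.asarray(labels))


def seg_loss(logits: Tensor, labels: np.ndarray, weights: LossWeights | None = None) -> Tensor:
    """Batch-mean of alpha * Dice loss + beta * cross-entropy per sample."""
    if weights is None:
        weights = LossWeights()
    n = logits.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    labels = np.asarray(labels)
    probs = softmax(logits, axis=1)
    total = None
    for i in range(n):
        d = dice_loss(probs.narrow(0, i, 1), labels[i : i + 1], smooth=weights.dice_smooth)
        total = d if total is None else total + d
    dice_term = total * (1.0 / n)
    # batch CE is a pixel mean, identical to the mean of per-sample CEs
    ce_term = cross_entropy(logits, labels)
    return weights.alpha * dice_term + weights.beta * ce_term


def total_loss(seg: Tensor | float, sim: Tensor | float, weights: LossWeights | None = None):
    """Total objective: segmentation loss plus weighted similarity loss."""
    if weights is None:
        weights = LossWeights()
    return seg + weights.lambda_sim * sim


def region_masks(labels: np.ndarray) -> dict[str, np.ndarray]:
    """WT/TC/ET binary maps from an internal-encoding label array."""
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - {0, 1, 2, 3}
    if bad:
        raise ValueError(f"labels contain invalid value(s) {sorted(bad)}")
    return {
        name: np.isin(labels, members) for name, members in REGION_LABELS.items()
    }


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a binary region (pixels losing a 4-neighbour)."""
    eroded = ndimage.binary_erosion(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return mask & ~eroded


def hd95(pred: np.ndarray, truth: np.ndarray, empty_penalty: float | None = None) -> float:
    """95th percentile of the pooled symmetric boundary-distance distribution.

    Distances are Euclidean in pixels between region boundaries; both
    directed distance sets are pooled before taking the percentile, which
    makes the statistic symmetric. Empty-vs-empty scores 0; empty-vs-
    nonempty scores ``empty_penalty`` (default: the image diagonal).
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    p_any, t_any = pred.any(), truth.any()
    if not p_any and not t_any:
        return 0.0
    if p_any != t_any:
        if empty_penalty is None:
            empty_penalty = float(np.hypot(*pred.shape))
        return float(empty_penalty)
    pb = np.argwhere(_boundary(pred))
    tb = np.argwhere(_boundary(truth))
    d_pt = cKDTree(tb).query(pb)[0]
    d_tp = cKDTree(pb).query(tb)[0]
    return float(np.percentile(np.concatenate([d_pt, d_tp]), 95))


def evaluate(
    pred_labels: np.ndarray,
    true_labels: np.ndarray,
    hd_penalty: float | None = None,
) -> dict[str, RegionScores]:
    """Score a predicted label map against the truth on WT, TC and ET."""
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    if pred_labels.shape != true_labels.shape:
        raise ValueError("prediction and truth shapes differ")
    pred_regions = region_masks(pred_labels)
    true_regions = region_masks(true_labels)
    out = {}
    for name in REGION_LABELS:
        p, t = pred_regions[name], true_regions[name]
        tp = float((p & t).sum())
        p_sum, t_sum = float(p.sum()), float(t.sum())
        tn = float((~p & ~t).sum())
        neg = float((~t).sum())
        if p_sum == 0 and t_sum == 0:
            dice = 1.0
        else:
            dice = 2.0 * tp / (p_sum + t_sum)
        sens = tp / t_sum if t_sum else 1.0
        spec = tn / neg if neg else 1.0
        out[name] = RegionScores(
            dice=dice,
            sensitivity=sens,
            specificity=spec,
            hd95=hd95(p, t, empty_penalty=hd_penalty),
        )
    return out


def mean_region_scores(per_case: list[dict[str, RegionScores]]) -> dict[str, RegionScores]:
    """Average RegionScores over cases, per region."""
    if not per_case:
        raise ValueError("no cases to average")
    out = {}
    for name in REGION_LABELS:
        out[name] = RegionScores(
            dice=float(np.mean([c[name].dice for c in per_case])),
            sensitivity=float(np.mean([c[name].sensitivity for c in per_case])),
            specificity=float(np.mean([c[name].specificity for c in per_case])),
            hd95=float(np.mean([c[name].hd95 for c in per_case])),
        )
    return out
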