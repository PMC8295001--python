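"""Segmentation accuracy metrics: misclassification rate and Kappa index.

Clustering assigns arbitrary class ids, so predictions are first matched to
the ground truth by the label permutation maximizing total pixel agreement.
After matching:

    MCR = (misclassified pixels) / (total pixels)
    KI_k = 2 TP_k / (2 TP_k + FP_k + FN_k)          (the Dice coefficient)

KI is reported per class and as the unweighted mean over classes; a class
absent from both maps scores KI = 1 (empty-empty convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass(frozen=True)
class EvaluationReport:
    mcr: float
    ki_per_class: tuple
    ki_mean: float
    matching: tuple  # permutation applied to predicted class ids

    def to_dict(self) -> dict:
        return {"mcr": self.mcr, "ki_per_class": list(self.ki_per_class),
                "ki_mean": self.ki_mean, "matching": list(self.matching)}


def _check_pair(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    if pred.min() < 0 or truth.min() < 0:
        raise ValueError("labels must be non-negative integers")
    return pred.astype(np.int64), truth.astype(np.int64)


def _n_classes(pred: np.ndarray, truth: np.ndarray) -> int:
    return int(max(pred.max(), truth.max())) + 1


def confusion_matrix(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> np.ndarray:
    """C[p, t] = number of pixels predicted p with truth t."""
    idx = pred.ravel() * n_classes + truth.ravel()
    return np.bincount(idx, minlength=n_classes * n_classes).reshape(
        n_classes, n_classes)


def match_labels(pred, truth) -> tuple:
    """Permutation of predicted ids maximizing agreement with the truth.

    Solved as a linear assignment on the confusion matrix; for small class
    counts this equals exhaustive search over all permutations (checked in the
    test suite).  Returns ``perm`` with ``perm[old_id] = new_id``.
    """
    pred, truth = _check_pair(pred, truth)
    k = _n_classes(pred, truth)
    if k > 10:
        raise ValueError("more than 10 classes are not supported")
    conf = confusion_matrix(pred, truth, k)
    rows, cols = linear_sum_assignment(-conf)
    perm = np.empty(k, dtype=np.int64)
    perm[rows] = cols
    return tuple(int(p) for p in perm)


def apply_matching(pred, perm) -> np.ndarray:
    return np.asarray(perm, dtype=np.int64)[np.asarray(pred, dtype=np.int64)]


def misclassification_rate(pred, truth) -> float:
    """Fraction of pixels whose (matched) predicted label differs from truth."""
    pred, truth = _check_pair(pred, truth)
    return float((pred != truth).mean())


def kappa_index(pred, truth, class_id: int) -> float:
    """Per-class KI = 2TP/(2TP+FP+FN); empty-empty classes score 1."""
    pred, truth = _check_pair(pred, truth)
    p = pred == class_id
    t = truth == class_id
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    if tp + fp + fn == 0:
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def evaluate(pred, truth) -> EvaluationReport:
    """Match labels once, then compute MCR and per-class/mean KI."""
    pred, truth = _check_pair(pred, truth)
    perm = match_labels(pred, truth)
    matched = apply_matching(pred, perm)
    k = _n_classes(matched, truth)
    ki = tuple(kappa_index(matched, truth, c) for c in range(k))
    return EvaluationReport(
        mcr=misclassification_rate(matched, truth),
        ki_per_class=ki,
        ki_mean=float(np.mean(ki)),
        matching=perm,
    )


def match_labels_bruteforce(pred, truth) -> tuple:
    """Exhaustive-permutation reference matcher (test oracle; K! cost)."""
    pred, truth = _check_pair(pred, truth)
    k = _n_classes(pred, truth)
    conf = confusion_matrix(pred, truth, k)
    best, best_score = None, -1
    for perm in permutations(range(k)):
        score = sum(conf[i, perm[i]] for i in range(k))
        if score > best_score:
            best, best_score = perm, score
    return tuple(best)
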