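"""Evaluation metrics and weight-distribution statistics.

F1 and balanced accuracy are the two headline metrics (both classes are
imbalanced in the simulated study, so plain accuracy would be misleading).
The positive class for F1 is label 1 — the minority class in the simulated
data — configurable via ``positive_label``. Zero-division conventions:
precision/recall/F1 are 0, never NaN, when their denominator is empty.

``weight_separation`` compares the meta-learned aggregate weights of
correctly-labeled vs mislabeled training samples with a two-sided Wilcoxon
rank-sum (Mann-Whitney) test: exact enumeration of the U distribution
(midranks, so ties are handled) when both groups have at most
``exact_threshold`` members, and a tie-corrected normal approximation
(scipy) otherwise. The "weight = 0" fraction counts exact zeros — a sample
weight is exactly 0 whenever its raw meta-gradient was non-positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .datasets import LabeledDataset

__all__ = [
    "EvalReport",
    "WeightStats",
    "f1_score",
    "balanced_accuracy",
    "rank_sum_test",
    "weight_separation",
    "evaluate_model",
]


@dataclass
class WeightStats:
    """Summary of the correct-vs-mislabeled weight comparison."""

    mean_weight_correct: float
    mean_weight_mislabeled: float
    median_weight_correct: float
    median_weight_mislabeled: float
    zero_weight_fraction_mislabeled: float
    statistic: float
    p_value: float


@dataclass
class EvalReport:
    """Per-method, per-condition evaluation row."""

    method: str
    condition: str
    f1: float
    balanced_accuracy: float
    n_test: int
    weight_stats: WeightStats | None = None

    def __post_init__(self) -> None:
        for v in (self.f1, self.balanced_accuracy):
            if not 0.0 <= v <= 1.0:
                raise ValueError("metrics must lie in [0, 1]")


def _check_binary(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary {0, 1}")
    return y_true, y_pred


def f1_score(y_true, y_pred, positive_label: int = 1) -> float:
    """Harmonic mean of precision and recall for the positive class."""
    y_true, y_pred = _check_binary(y_true, y_pred)
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    tp = int((pos_t & pos_p).sum())
    fp = int((~pos_t & pos_p).sum())
    fn = int((pos_t & ~pos_p).sum())
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2.0 * precision * recall / (precision + recall)


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of the per-class recalls; requires both classes in y_true."""
    y_true, y_pred = _check_binary(y_true, y_pred)
    recalls = []
    for cls in (0, 1):
        mask = y_true == cls
        if not mask.any():
            raise ValueError(
                "balanced accuracy is undefined when y_true has one class"
            )
        recalls.append(float((y_pred[mask] == cls).mean()))
    return float(np.mean(recalls))


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values)


def rank_sum_test(
    x, y, exact_threshold: int = 10
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of the first group against the second.

    Returns (U, p) where U is the Mann-Whitney statistic of the first group
    (number of (x, y) pairs with x > y, counting ties as half). For small
    groups (both sizes <= ``exact_threshold``) the p-value is computed by
    exact enumeration over all C(n1+n2, n1) rank assignments using midranks;
    otherwise scipy's tie-corrected normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    ranks = _midranks(np.concatenate([x, y]))
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if n1 <= exact_threshold and n2 <= exact_threshold:
        total = comb(n1 + n2, n1)
        lower = higher = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            if u <= u_obs + 1e-9:
                lower += 1
            if u >= u_obs - 1e-9:
                higher += 1
        p = min(1.0, 2.0 * min(lower, higher) / total)
        return u_obs, p

    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def weight_separation(
    aggregate_weights: np.ndarray, mislabel_mask: np.ndarray
) -> WeightStats:
    """Compare meta-learned weights of correctly-labeled vs mislabeled samples."""
    w = np.asarray(aggregate_weights, dtype=float)
    mask = np.asarray(mislabel_mask, dtype=bool)
    if w.shape != mask.shape:
        raise ValueError("weights and mask must align")
    correct, mislabeled = w[~mask], w[mask]
    if len(correct) == 0 or len(mislabeled) == 0:
        raise ValueError("both groups must be non-empty")
    stat, p = rank_sum_test(correct, mislabeled)
    return WeightStats(
        mean_weight_correct=float(correct.mean()),
        mean_weight_mislabeled=float(mislabeled.mean()),
        median_weight_correct=float(np.median(correct)),
        median_weight_mislabeled=float(np.median(mislabeled)),
        zero_weight_fraction_mislabeled=float((mislabeled == 0.0).mean()),
        statistic=stat,
        p_value=p,
    )


def evaluate_model(
    model,
    test: LabeledDataset,
    method: str = "",
    condition: str = "",
    weight_stats: WeightStats | None = None,
) -> EvalReport:
    """Predict on a clean test set and fill the metric report."""
    y_pred = model.predict(test.features) if hasattr(model, "predict") else None
    if y_pred is None:
        from .trainer import forward_predict

        _, y_pred = forward_predict(model, test.features)
    return EvalReport(
        method=method or getattr(model, "method", "model"),
        condition=condition,
        f1=f1_score(test.labels, y_pred),
        balanced_accuracy=balanced_accuracy(test.labels, y_pred),
        n_test=test.n_samples,
        weight_stats=weight_stats,
    )
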