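"""Classifier evaluation: splits, ranking metrics, threshold selection,
confusion summaries and permutation feature importance.

AUC-ROC follows the Mann-Whitney formulation (ties count one half);
AUC-PRC is average precision (step rule, no trapezoid interpolation).
The operating threshold maximises Youden's J = sensitivity + specificity
minus 1 over the observed scores.  Feature importance is the mean held-out
AUC drop when one feature column is permuted, normalised to percentages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score, average_precision_score

__all__ = ["EvalReport", "split_train_test", "auc_roc", "auc_prc",
           "youden_threshold", "confusion_metrics", "permutation_importance",
           "evaluate_scores"]


@dataclass
class EvalReport:
    auc_roc: float
    auc_prc: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    feature_importance: dict[str, float] | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _check_two_classes(labels):
    labels = np.asarray(labels)
    if not ((labels == 0).any() and (labels == 1).any()):
        raise ValueError("both classes must be present")
    return labels


def split_train_test(table, ratio: float = 0.8, seed: int = 0):
    """Stratified split; per class, floor(ratio * n) rows go to training.

    Returns ``(train_table, test_table)``; the union is the input and the
    parts are disjoint.  The standardiser is fitted on the training rows
    and shared with the test table.
    """
    labels = _check_two_classes(table.labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 rows")
        idx = rng.permutation(idx)
        k = int(np.floor(ratio * idx.size))
        train_idx.extend(idx[:k])
        test_idx.extend(idx[k:])
    train_idx = np.sort(np.asarray(train_idx))
    test_idx = np.sort(np.asarray(test_idx))

    table.fit_standardiser(train_idx)
    train = table.subset(train_idx)
    test = table.subset(test_idx)
    return train, test


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve, equal to P(score_pos > score_neg) + P(tie)/2."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def auc_prc(scores, labels) -> float:
    """Average precision: sum of precision x recall increments over thresholds."""
    labels = np.asarray(labels)
    if not (labels == 1).any():
        raise ValueError("no positive labels")
    return float(average_precision_score(labels, np.asarray(scores, float)))


def youden_threshold(scores, labels):
    """Threshold among observed scores maximising J = sens + spec - 1.

    Ties are broken in favour of higher specificity, then lower threshold.
    Returns ``(threshold, sensitivity, specificity)``.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, float)
    best = None
    for t in np.unique(scores):
        pred = scores >= t
        sens = float((pred & (labels == 1)).sum() / (labels == 1).sum())
        spec = float((~pred & (labels == 0)).sum() / (labels == 0).sum())
        key = (sens + spec - 1, spec, -t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return float(best[1]), best[2], best[3]


def confusion_metrics(scores, labels, threshold):
    """Accuracy / sensitivity / specificity and counts at ``score >= threshold``."""
    labels = _check_two_classes(labels)
    pred = np.asarray(scores, float) >= threshold
    pos, neg = labels == 1, labels == 0
    tp = int((pred & pos).sum())
    fp = int((pred & neg).sum())
    tn = int((~pred & neg).sum())
    fn = int((~pred & pos).sum())
    return {
        "accuracy": (tp + tn) / labels.size,
        "sensitivity": tp / pos.sum(),
        "specificity": tn / neg.sum(),
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }


def permutation_importance(model, table, n_repeats: int = 20, seed: int = 0):
    """Per-feature percentage of the total held-out AUC drop under permutation.

    Each feature column is shuffled ``n_repeats`` times; the drop is the
    mean decrease in AUC-ROC relative to the intact table, clipped at 0,
    and the drops are normalised to sum to 100.  If nothing drops, the
    percentages are uniform (with a warning).
    """
    from .model import predict  # local import to avoid a cycle

    labels = _check_two_classes(table.labels)
    rng = np.random.default_rng(seed)
    base = auc_roc(predict(model, table), labels)
    drops = np.zeros(table.X.shape[1])
    for j in range(table.X.shape[1]):
        deltas = []
        for _ in range(n_repeats):
            perm = table.subset(np.arange(len(table)))
            perm.X[:, j] = perm.X[rng.permutation(len(perm)), j]
            deltas.append(base - auc_roc(predict(model, perm), labels))
        drops[j] = max(0.0, float(np.mean(deltas)))
    total = drops.sum()
    if total == 0:
        warnings.warn("no feature permutation reduced AUC; reporting uniform importance")
        pct = np.full(drops.size, 100.0 / drops.size)
    else:
        pct = 100.0 * drops / total
    return dict(zip(table.feature_names, pct.tolist()))


def evaluate_scores(scores, labels, feature_importance=None) -> EvalReport:
    """Full report at the Youden threshold."""
    thr, sens, spec = youden_threshold(scores, labels)
    cm = confusion_metrics(scores, labels, thr)
    return EvalReport(
        auc_roc=auc_roc(scores, labels),
        auc_prc=auc_prc(scores, labels),
        accuracy=cm["accuracy"],
        sensitivity=cm["sensitivity"],
        specificity=cm["specificity"],
        threshold=thr,
        tp=cm["tp"], fp=cm["fp"], tn=cm["tn"], fn=cm["fn"],
        feature_importance=feature_importance,
    )
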