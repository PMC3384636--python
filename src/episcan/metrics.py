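"""Evaluation measures for binary epitope calls and real-valued propensities.

Binary metrics are the usual confusion-table ratios; MCC uses the standard
numerator TP*TN - FP*FN and the convention MCC = 0 when any factor of the
denominator vanishes. AUC is computed both as the tie-corrected Mann-Whitney
rank statistic and by trapezoidal integration of the ROC curve (the two are
equal; both are exposed so either can cross-check the other). The chain-level
success rate counts chains whose native-epitope residues score, on average,
strictly above the chain-wide average propensity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_calls(cls, predicted, truth) -> "ConfusionCounts":
        predicted = np.asarray(predicted, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        if predicted.shape != truth.shape:
            raise ValueError("prediction/truth length mismatch")
        return cls(tp=int((predicted & truth).sum()),
                   tn=int((~predicted & ~truth).sum()),
                   fp=int((predicted & ~truth).sum()),
                   fn=int((~predicted & truth).sum()))


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return float("nan")
    return num / den


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision, F-measure and MCC."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    out = {
        "accuracy": _ratio(c.tp + c.tn, c.total, "accuracy"),
        "sensitivity": _ratio(c.tp, c.tp + c.fn, "sensitivity"),
        "specificity": _ratio(c.tn, c.tn + c.fp, "specificity"),
        "precision": _ratio(c.tp, c.tp + c.fp, "precision"),
        "f_measure": _ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp, "f_measure"),
    }
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        out["mcc"] = 0.0
    else:
        out["mcc"] = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return out


def auc(scores, labels) -> float:
    """Tie-corrected Mann-Whitney (rank) AUC; ties contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def roc_curve_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points from a threshold sweep over the unique scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    # keep only the last index of each tied-score block
    last = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tp[last] / max(tp[-1], 1)]
    fpr = np.r_[0.0, fp[last] / max(fp[-1], 1)]
    return fpr, tpr


def auc_trapezoidal(scores, labels) -> float:
    """AUC by trapezoidal integration of the ROC curve."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUC requires both classes")
    fpr, tpr = roc_curve_points(scores, labels)
    return float(np.trapezoid(tpr, fpr))


def success_rate(profiles: list[np.ndarray],
                 truths: list[np.ndarray]) -> float:
    """Fraction of chains where the mean propensity over native epitope
    residues strictly exceeds the chain-wide mean propensity.

    Chains without any epitope residue are excluded (with a warning).
    """
    if len(profiles) != len(truths):
        raise ValueError("profiles/truths length mismatch")
    n_eval = n_success = 0
    for i, (prof, truth) in enumerate(zip(profiles, truths)):
        prof = np.asarray(prof, dtype=float)
        truth = np.asarray(truth, dtype=bool)
        if prof.shape != truth.shape:
            raise ValueError(f"chain {i}: profile/truth length mismatch")
        if not truth.any():
            warnings.warn(f"chain {i} has no epitope residues; excluded",
                          stacklevel=2)
            continue
        n_eval += 1
        if prof[truth].mean() > prof.mean():
            n_success += 1
    if n_eval == 0:
        raise ValueError("no evaluable chains (none had epitope residues)")
    return n_success / n_eval
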