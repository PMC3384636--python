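"""Wrapper feature selection: biserial-correlation ranking followed by
backward elimination under cross-validated MCC.

Features are first sorted by their absolute biserial correlation coefficient

    BCC = (M_e - M_ne) * sqrt(n_e * n_ne / n) / stdev

(M_e, M_ne: class-conditional means; n_e, n_ne, n: class and total counts;
stdev: population standard deviation of the feature over all samples),
averaged over the training sides of a stratified k-fold partition. Starting
from the least correlated feature, elimination repeatedly sweeps the current
ascending-|BCC| order and drops any feature whose removal does not lower the
cross-validated MCC; it stops when a full sweep removes nothing. One fixed,
seeded fold partition is used throughout.

Note the printed normalizer sqrt(n_e*n_ne/n) is kept verbatim although it can
exceed 1 in magnitude (the textbook point-biserial divides by n); with n
fixed the two orderings are identical, and only the ordering is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .svm_core import SvmConfig, cross_validated_mcc, make_fold_assignment


def biserial_cc(values, labels) -> float:
    """Biserial correlation of one feature against the binary labels.

    Returns 0 for a zero-variance feature (convention). ``labels`` True marks
    the epitope class.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_e = int(labels.sum())
    n_ne = labels.size - n_e
    if n_e == 0 or n_ne == 0:
        raise ValueError("BCC requires both classes")
    stdev = values.std()  # population form
    if stdev == 0:
        return 0.0
    n = values.size
    return float((values[labels].mean() - values[~labels].mean())
                 * np.sqrt(n_e * n_ne / n) / stdev)


def rank_features(X: np.ndarray, y: np.ndarray, names: list[str],
                  folds: int = 10, seed: int = 0) -> list[str]:
    """Feature names sorted by mean |BCC| over fold-training subsets,
    ascending (least correlated first); ties broken by input (canonical)
    order."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if X.shape[1] != len(names):
        raise ValueError("names must match feature columns")
    assignment = make_fold_assignment(y, folds, seed)
    mean_abs = np.zeros(X.shape[1])
    fold_ids = np.unique(assignment)
    for f in fold_ids:
        train_mask = assignment != f
        for j in range(X.shape[1]):
            mean_abs[j] += abs(biserial_cc(X[train_mask, j], y[train_mask]))
    mean_abs /= len(fold_ids)
    order = np.argsort(mean_abs, kind="stable")  # stable = canonical ties
    return [names[j] for j in order]


@dataclass
class EliminationStep:
    feature: str
    mcc_before: float
    mcc_after: float
    dropped: bool


@dataclass
class SelectionResult:
    manifest: list[str]          # surviving features, canonical order
    initial_mcc: float
    final_mcc: float
    log: list[EliminationStep] = field(default_factory=list)


def backward_eliminate(X: np.ndarray, y: np.ndarray, names: list[str],
                       svm_config: SvmConfig | None = None,
                       folds: int = 10, seed: int = 0,
                       ranked: list[str] | None = None,
                       max_candidates: int | None = None,
                       ) -> SelectionResult:
    """Greedy backward elimination in ascending-|BCC| order.

    A feature is dropped iff the cross-validated MCC without it is >= the
    current MCC; full sweeps repeat until none can be dropped, so the final
    MCC is never below the initial one. ``max_candidates`` optionally caps
    the search to the top-m ranked features (the rest are dropped up front by
    rank alone), a cost knob for large feature sets.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    config = svm_config or SvmConfig()
    if ranked is None:
        ranked = rank_features(X, y, names, folds=folds, seed=seed)
    index = {n: i for i, n in enumerate(names)}
    assignment = make_fold_assignment(y, folds, seed)
    current = list(ranked)  # ascending |BCC|
    if max_candidates is not None and len(current) > max_candidates:
        current = current[-max_candidates:]

    def cv_mcc(feats: list[str]) -> float:
        cols = [index[n] for n in feats]
        return cross_validated_mcc(X[:, cols], y, config,
                                   fold_assignment=assignment)

    log: list[EliminationStep] = []
    current_mcc = initial_mcc = cv_mcc(current)
    removed_any = True
    while removed_any:
        removed_any = False
        for feat in list(current):
            if len(current) == 1:
                break
            candidate = [f for f in current if f != feat]
            mcc = cv_mcc(candidate)
            dropped = mcc >= current_mcc
            log.append(EliminationStep(feat, current_mcc, mcc, dropped))
            if dropped:
                current = candidate
                current_mcc = mcc
                removed_any = True
    manifest = [n for n in names if n in set(current)]
    return SelectionResult(manifest=manifest, initial_mcc=initial_mcc,
                           final_mcc=current_mcc, log=log)


def write_manifest(manifest: list[str], path) -> None:
    with open(path, "w") as fh:
        for name in manifest:
            fh.write(name + "\n")


def read_manifest(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_elimination_log(log: list[EliminationStep], path) -> None:
    with open(path, "w") as fh:
        fh.write("feature\tmcc_before\tmcc_after\tdecision\n")
        for step in log:
            fh.write(f"{step.feature}\t{step.mcc_before:.6f}\t"
                     f"{step.mcc_after:.6f}\t"
                     f"{'dropped' if step.dropped else 'kept'}\n")
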