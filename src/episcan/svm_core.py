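"""RBF-kernel SVM classification of featurized 20-mer fragments.

The classifier is an RBF support-vector machine over standardized features
(zero mean, unit variance, learned on the training data only) with
sigmoid-calibrated probability outputs; a fragment is called an epitope when
its score exceeds 0.5 (a score of exactly 0.5 calls negative). Defaults:
C = 2^0, gamma = 2^-9 for a selected-feature model and C = 2^3, gamma = 2^-10
for the full 198-feature model; both grid-search winners over
C = 2^-2..2^4, gamma = 2^-11..2^0 under 10-fold cross-validated MCC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .metrics import ConfusionCounts, confusion_metrics

#: Parameter grids of the reference grid search.
DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-2, 5))        # 2^-2 .. 2^4
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-11, 1))   # 2^-11 .. 2^0


@dataclass(frozen=True)
class SvmConfig:
    """RBF-SVM hyper-parameters and training conventions."""

    C: float = 2.0 ** 0
    gamma: float = 2.0 ** -9
    probability_scores: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")

    @classmethod
    def selected_features_default(cls, seed: int = 0) -> "SvmConfig":
        return cls(C=2.0 ** 0, gamma=2.0 ** -9, seed=seed)

    @classmethod
    def full_features_default(cls, seed: int = 0) -> "SvmConfig":
        return cls(C=2.0 ** 3, gamma=2.0 ** -10, seed=seed)


@dataclass
class TrainedModel:
    """A fitted scorer plus everything needed to featurize new fragments.

    ``manifest`` is the ordered feature-name list the pipeline expects;
    ``wop_fallback_table`` and the similarity ``library`` travel with the
    model because new chains must be annotated and featurized exactly as the
    training data were.
    """

    pipeline: Pipeline
    config: SvmConfig
    manifest: list[str]
    wop_fallback_table: dict[str, np.ndarray] | None = None
    library: "object | None" = None  # FragmentLibrary
    library_fingerprint: str = ""
    extras: dict = field(default_factory=dict)

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.manifest):
            raise ValueError(
                f"feature matrix has {X.shape[1]} columns but the model "
                f"manifest lists {len(self.manifest)} features")
        return self.pipeline.predict_proba(X)[:, 1]


def _validate_training_input(X: np.ndarray, y: np.ndarray) -> None:
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains NaN or infinite values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")


def train(X: np.ndarray, y: np.ndarray, config: SvmConfig | None = None,
          manifest: list[str] | None = None) -> TrainedModel:
    """Fit scaler + RBF-SVM with probability calibration."""
    config = config or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    _validate_training_input(X, y)
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(kernel="rbf", C=config.C, gamma=config.gamma,
                    probability=config.probability_scores,
                    random_state=config.seed)),
    ])
    with warnings.catch_warnings():
        # libsvm's internal sigmoid calibration is exactly what we want;
        # newer sklearn nags to migrate to CalibratedClassifierCV
        warnings.simplefilter("ignore", FutureWarning)
        pipe.fit(X, y.astype(int))
    if manifest is None:
        manifest = [f"f{i}" for i in range(X.shape[1])]
    return TrainedModel(pipeline=pipe, config=config, manifest=list(manifest))


def predict_fragments(model: TrainedModel, X: np.ndarray,
                      cutoff: float = 0.5,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(scores in [0,1], binary calls). A call is positive iff score > cutoff."""
    scores = model.scores(X)
    return scores, scores > cutoff


def cross_validated_mcc(X: np.ndarray, y: np.ndarray, config: SvmConfig,
                        folds: int = 10, seed: int = 0,
                        fold_assignment: np.ndarray | None = None) -> float:
    """MCC of out-of-fold calls under stratified k-fold cross-validation.

    Predictions are pooled over folds and a single MCC is computed from the
    pooled confusion table. A precomputed ``fold_assignment`` (one integer
    fold id per sample) makes repeated evaluations — e.g. during feature
    selection — use the identical partition.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if fold_assignment is None:
        fold_assignment = make_fold_assignment(y, folds, seed)
    pred = np.zeros_like(y)
    for f in np.unique(fold_assignment):
        test = fold_assignment == f
        train_idx = ~test
        model = train(X[train_idx], y[train_idx], config)
        pred[test] = model.scores(X[test]) > 0.5
    return confusion_metrics(ConfusionCounts.from_calls(pred, y))["mcc"]


def make_fold_assignment(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Seeded stratified fold ids, serializable for reproducibility."""
    y = np.asarray(y, dtype=bool)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = f
    return assignment


def grid_search(X: np.ndarray, y: np.ndarray,
                C_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                folds: int = 10, seed: int = 0,
                ) -> tuple[float, float, dict[tuple[float, float], float]]:
    """Pick (C, gamma) maximizing cross-validated MCC.

    Ties are broken toward the smallest C, then the smallest gamma. Returns
    the winner plus the full criterion surface.
    """
    if not len(C_grid) or not len(gamma_grid):
        raise ValueError("parameter grids must be non-empty")
    fold_assignment = make_fold_assignment(np.asarray(y, bool), folds, seed)
    surface: dict[tuple[float, float], float] = {}
    best: tuple[float, float] | None = None
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            mcc = cross_validated_mcc(
                X, y, SvmConfig(C=C, gamma=gamma, seed=seed),
                fold_assignment=fold_assignment)
            surface[(C, gamma)] = mcc
            if best is None or mcc > surface[best]:
                best = (C, gamma)
    return best[0], best[1], surface
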