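"""Cross-validated SVM decoding of phrase classes from band-power features.

The decoder is a support vector machine with a 2nd-order polynomial kernel
(C = 1), evaluated with stratified 5-fold cross-validation: with 60 trials
per phrase each fold holds 12 trials per phrase, four folds (48 per phrase)
train and one validates, and the mean across folds is the reported accuracy.
Feature columns are z-scored with statistics fit on the training folds only
— polynomial kernels are scale-sensitive and RMS magnitudes differ by band.
Multiclass handling is one-vs-one; the kernel is (gamma x.x' + 1)^2 with
gamma = 1 / (n_features * var(X)) (sklearn "scale"). The inhomogeneous form
(coef0 = 1) is required: with zero coefficient an even-degree kernel is
blind to sign, and z-scored class clusters that mirror each other through
the origin become inseparable.

Fold assignments are created once per dataset and reused across sensor
subsets so that step-wise selection comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix, subset_features
from .synth import SensorLayout

__all__ = [
    "DecoderConfig",
    "CVResult",
    "TTestResult",
    "make_folds",
    "crossval_svm",
    "hemisphere_eval",
    "paired_ttest",
]


@dataclass
class DecoderConfig:
    """SVM + cross-validation hyperparameters (defaults fixed, not tuned)."""

    degree: int = 2
    C: float = 1.0
    folds: int = 5
    seed: int = 0
    scaling: str = "zscore_trainfit"  # or "none"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.scaling not in ("zscore_trainfit", "none"):
            raise ValueError("scaling must be 'zscore_trainfit' or 'none'")


@dataclass
class CVResult:
    """Per-fold accuracies (%) with the pooled confusion matrix."""

    fold_accuracies: np.ndarray
    confusion: np.ndarray
    fold_assignment: np.ndarray
    classes: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "sd": self.sd,
            "confusion": self.confusion.tolist(),
            "classes": self.classes.tolist(),
        }


@dataclass
class TTestResult:
    t: float
    p: float  # two-tailed unless tails=1 requested
    tails: int
    degenerate: bool = False


def make_folds(labels: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Stratified fold assignment: exactly n/folds trials of each class per fold.

    Class counts must divide evenly by ``folds`` (guaranteed after trial
    balancing). Deterministic for a given seed.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) % folds:
            raise ValueError(
                f"class {cls} count {len(idx)} not divisible by {folds} folds"
            )
        perm = rng.permutation(idx)
        per = len(idx) // folds
        for f in range(folds):
            assignment[perm[f * per : (f + 1) * per]] = f
    return assignment


def _fit_predict_fold(
    X: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    config: DecoderConfig,
) -> np.ndarray:
    if len(np.unique(y[train])) < 2:
        raise RuntimeError("degenerate training fold: fewer than 2 classes")
    Xtr, Xte = X[train], X[test]
    if config.scaling == "zscore_trainfit":
        scaler = StandardScaler().fit(Xtr)
        Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
    clf = SVC(
        kernel="poly",
        degree=config.degree,
        gamma="scale",
        coef0=1.0,
        C=config.C,
        decision_function_shape="ovo",
    )
    clf.fit(Xtr, y[train])
    return clf.predict(Xte)


def crossval_svm(
    features: FeatureMatrix,
    config: DecoderConfig,
    fold_assignment: np.ndarray | None = None,
) -> CVResult:
    """Stratified k-fold CV of the polynomial SVM on a feature matrix."""
    X = np.asarray(features.values, dtype=np.float64)
    y = np.asarray(features.labels)
    if np.isnan(X).any():
        raise ValueError("features contain NaN")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if fold_assignment is None:
        fold_assignment = make_folds(y, config.folds, config.seed)
    fold_assignment = np.asarray(fold_assignment)
    n_folds = int(fold_assignment.max()) + 1
    accs = np.empty(n_folds)
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for f in range(n_folds):
        test = np.flatnonzero(fold_assignment == f)
        train = np.flatnonzero(fold_assignment != f)
        pred = _fit_predict_fold(X, y, train, test, config)
        accs[f] = 100.0 * np.mean(pred == y[test])
        confusion += confusion_matrix(y[test], pred, labels=classes)
    return CVResult(accs, confusion, fold_assignment, classes)


def hemisphere_eval(
    features: FeatureMatrix,
    layout: SensorLayout,
    side: str,
    config: DecoderConfig | None = None,
    fold_assignment: np.ndarray | None = None,
) -> CVResult:
    """CV decoding restricted to one hemisphere's sensors ("left"/"right"/"all")."""
    if config is None:
        config = DecoderConfig()
    if side == "all":
        sensors = [s for s in features.sensor_ids]
    elif side in ("left", "right"):
        wanted = set(layout.side(side))
        sensors = [s for s in features.sensor_ids if s in wanted]
    else:
        raise ValueError("side must be 'left', 'right' or 'all'")
    if not sensors:
        raise RuntimeError(f"no sensors on side {side!r}")
    return crossval_svm(subset_features(features, sensors), config, fold_assignment)


def paired_ttest(acc_a, acc_b, tails: int = 2) -> TTestResult:
    """Paired t-test between matched per-subject accuracy vectors.

    With zero variance of the pairwise differences the statistic is
    undefined; the result is flagged degenerate (t = 0, p = 1 when the
    vectors are identical). For ``tails=1`` the reported p is one-sided in
    the direction of the observed mean difference.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return TTestResult(t=0.0, p=1.0, tails=tails, degenerate=True)
        t = np.inf if d.mean() > 0 else -np.inf
        return TTestResult(t=float(t), p=0.0, tails=tails, degenerate=True)
    t, p2 = stats.ttest_rel(a, b)
    p = p2 / 2 if tails == 1 else p2
    return TTestResult(t=float(t), p=float(p), tails=tails)
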