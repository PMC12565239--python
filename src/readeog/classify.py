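"""Classifier estimator, confusion-matrix metrics and k-fold evaluation.

Metrics follow the standard binary definitions computed from a 2×2
confusion matrix and reported as percentages:

    accuracy    = (tp + tn) / (tp + tn + fp + fn)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    F1          = 2·tp / (2·tp + fp + fn)

Cross-validation is stratified k-fold (default k = 5).  The split unit is
configurable: ``frame`` (each scalogram image independent — mirrors the
common protocol but lets frames of one recording appear in both train and
test), ``recording`` or ``subject`` (group-disjoint folds, recommended
when leakage matters).  Fold metrics are aggregated as arithmetic mean ±
sample standard deviation, and the per-fold confusion matrices sum to an
"overlapped" matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .cnn import ModelSpec, build_model, dyslexianet, softmax, train_model

__all__ = [
    "ConfusionMatrix",
    "CvConfig",
    "CvReport",
    "DyslexiaNetClassifier",
    "metrics",
    "confusion_matrix",
    "run_cv",
    "aggregate_folds",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 outcome counts, positive class = dyslexia."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """The four percentage metrics; zero-denominator cases come back NaN
    with the metric name recorded under the ``"undefined"`` key."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return 100.0 * num / den

    out = {
        "accuracy": ratio(cm.tp + cm.tn, cm.total, "accuracy"),
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn, "sensitivity"),
        "specificity": ratio(cm.tn, cm.tn + cm.fp, "specificity"),
        "f1": ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1"),
    }
    out["undefined"] = undefined
    return out


def confusion_matrix(y_true, y_pred, positive) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def aggregate_folds(fold_values) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation of fold metrics.

    A singleton list gets std 0 by convention (there is no spread to
    estimate); callers should treat that value as flagged.
    """
    vals = np.asarray(list(fold_values), dtype=float)
    if vals.size == 0:
        raise ValueError("no fold values to aggregate")
    if vals.size == 1:
        return float(vals[0]), 0.0
    return float(vals.mean()), float(vals.std(ddof=1))


class DyslexiaNetClassifier(ClassifierMixin, BaseEstimator):
    """The lightweight scalogram CNN as a scikit-learn classifier.

    Parameters
    ----------
    model_spec : ModelSpec, optional
        Architecture to build; defaults to :func:`readeog.cnn.dyslexianet`.
    epochs, batch_size, learning_rate
        Adam training schedule (defaults 20 / 64 / 1e-3).
    random_state : int, optional
        Seeds weight initialisation, dropout and minibatch shuffling.

    Input images are NHWC uint8 or float arrays matching the spec's
    input shape; pixel values are zero-centred with the training-set
    mean image (stored as ``mean_image_``).
    """

    def __init__(
        self,
        model_spec: ModelSpec | None = None,
        epochs: int = 20,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.model_spec = model_spec
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.verbose = verbose

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        shape = (self.model_spec or dyslexianet()).input_shape
        if X.ndim == 3:
            X = X[None]
        if X.ndim != 4 or X.shape[1:] != shape:
            raise ValueError(f"expected images of shape (n, {shape[0]}, {shape[1]}, "
                             f"{shape[2]}), got {X.shape}")
        return X

    def fit(self, X, y):
        spec = self.model_spec or dyslexianet()
        X = self._check_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != spec.n_classes:
            raise ValueError(f"expected {spec.n_classes} classes, got {len(self.classes_)}")
        y_idx = np.searchsorted(self.classes_, y)
        self.mean_image_ = X.mean(axis=0)
        Xc = (X - self.mean_image_) / 255.0
        self.model_ = build_model(spec, seed=self.random_state)
        self.loss_history_ = train_model(
            self.model_, Xc, y_idx,
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, seed=self.random_state,
            verbose=self.verbose,
        )
        self.n_features_in_ = int(np.prod(spec.input_shape))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = self._check_X(X)
        Xc = (X - self.mean_image_) / 255.0
        # Batched evaluation keeps peak memory flat on large image sets.
        probs = [softmax(self.model_.forward(Xc[i:i + 256], train=False))
                 for i in range(0, len(Xc), 256)]
        return np.concatenate(probs)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


@dataclass(frozen=True)
class CvConfig:
    """Cross-validation and training schedule configuration."""

    k: int = 5
    split_unit: str = "frame"  # frame | recording | subject
    seed: int | None = None
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.split_unit not in ("frame", "recording", "subject"):
            raise ValueError(f"unknown split_unit {self.split_unit!r}")


@dataclass
class CvReport:
    """Per-fold and aggregated k-fold evaluation results."""

    fold_metrics: list[dict[str, float]]
    fold_cms: list[ConfusionMatrix]
    mean: dict[str, float]
    std: dict[str, float]
    overlapped_cm: ConfusionMatrix
    positive_class: str
    training_time: float = 0.0
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "positive_class": self.positive_class,
            "folds": [
                {**{k: m[k] for k in METRIC_NAMES},
                 "cm": vars(cm)}
                for m, cm in zip(self.fold_metrics, self.fold_cms)
            ],
            "mean": self.mean,
            "std": self.std,
            "overlapped_cm": vars(self.overlapped_cm),
            "training_time_s": self.training_time,
            "flags": self.flags,
        }


def run_cv(
    images,
    labels,
    cfg: CvConfig | None = None,
    model_spec: ModelSpec | None = None,
    groups=None,
) -> CvReport:
    """Stratified k-fold evaluation of the CNN on labelled images.

    ``groups`` supplies the recording/subject id per image and is
    required for group-disjoint split units.  The positive class is
    ``"dyslexia"`` when present, else the second sorted label.
    """
    import time

    if cfg is None:
        cfg = CvConfig()
    images = np.asarray(images)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < cfg.k:
        raise ValueError(f"need at least k={cfg.k} samples per class")
    positive = "dyslexia" if "dyslexia" in classes else str(classes[-1])

    if cfg.split_unit == "frame":
        splitter = StratifiedKFold(n_splits=cfg.k, shuffle=True, random_state=cfg.seed)
        split_iter = splitter.split(images, labels)
    else:
        if groups is None:
            raise ValueError(f"split_unit={cfg.split_unit!r} requires groups")
        splitter = StratifiedGroupKFold(n_splits=cfg.k, shuffle=True,
                                        random_state=cfg.seed)
        split_iter = splitter.split(images, labels, groups=np.asarray(groups))

    fold_metrics, fold_cms, flags = [], [], []
    t0 = time.perf_counter()
    for fold, (train_idx, test_idx) in enumerate(split_iter):
        if len(np.unique(labels[test_idx])) < len(classes):
            raise ValueError(f"fold {fold}: a class is absent from the test split; "
                             "re-stratify or adjust k")
        clf = DyslexiaNetClassifier(
            model_spec=model_spec,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate,
            random_state=None if cfg.seed is None else cfg.seed + fold,
        )
        clf.fit(images[train_idx], labels[train_idx])
        pred = clf.predict(images[test_idx])
        cm = confusion_matrix(labels[test_idx], pred, positive)
        m = metrics(cm)
        if m["undefined"]:
            flags.append(f"fold {fold}: undefined metrics {m['undefined']}")
        fold_cms.append(cm)
        fold_metrics.append(m)
    elapsed = time.perf_counter() - t0

    mean, std = {}, {}
    for name in METRIC_NAMES:
        mean[name], std[name] = aggregate_folds([m[name] for m in fold_metrics])
    overlapped = fold_cms[0]
    for cm in fold_cms[1:]:
        overlapped = overlapped + cm
    return CvReport(
        fold_metrics=fold_metrics,
        fold_cms=fold_cms,
        mean=mean,
        std=std,
        overlapped_cm=overlapped,
        positive_class=positive,
        training_time=elapsed,
        flags=flags,
    )
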