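"""Stratified splitting, classifiers, and evaluation for mineral-content
classification.

The split design mirrors the study: 70 training and 21 test spectra with
fixed per-class counts over the six mineral-content classes. Four model
families are supported — multinomial logistic regression, a nu-SVM
(one-vs-one RBF NuSVC), a single-hidden-layer neural network and a random
forest — all seeded so a run is reproducible from one master seed.
Hyperparameter defaults are widely used library defaults (nu = 0.5, RBF
scale gamma; 100 hidden units; 100 trees) and are overridable per spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import NuSVC

from .exceptions import InvalidArgumentError

__all__ = [
    "SplitSpec",
    "ClassifierSpec",
    "EvaluationReport",
    "split",
    "make_classifier",
    "train",
    "predict",
    "evaluate",
    "CLASSIFIER_KINDS",
    "DEFAULT_TRAIN_PER_CLASS",
    "DEFAULT_TEST_PER_CLASS",
]

CLASSIFIER_KINDS = ("logistic", "v_svm", "neural_network", "random_forest")

#: Per-class training counts for labels (0, 20, 40, 60, 80, 100) wt%; sum 70.
DEFAULT_TRAIN_PER_CLASS = (12, 12, 12, 12, 9, 13)
#: Per-class test counts; sum 21.
DEFAULT_TEST_PER_CLASS = (4, 4, 4, 3, 3, 3)


@dataclass(frozen=True)
class SplitSpec:
    """Per-class train/test counts plus the split seed."""

    class_labels: tuple = (0, 20, 40, 60, 80, 100)
    train_per_class: tuple = DEFAULT_TRAIN_PER_CLASS
    test_per_class: tuple = DEFAULT_TEST_PER_CLASS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            len(self.class_labels)
            == len(self.train_per_class)
            == len(self.test_per_class)
        ):
            raise InvalidArgumentError("per-class count lengths differ")
        if any(t < 0 for t in self.train_per_class + self.test_per_class):
            raise InvalidArgumentError("counts must be >= 0")


def split(labels, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified split; returns (train_indices, test_indices).

    Samples are drawn uniformly without replacement within each class;
    train and test are disjoint and honor the exact per-class counts.
    """
    labels = np.asarray(labels, dtype=float)
    rng = np.random.default_rng(spec.seed)
    train_idx, test_idx = [], []
    for lab, n_tr, n_te in zip(
        spec.class_labels, spec.train_per_class, spec.test_per_class
    ):
        idx = np.flatnonzero(labels == float(lab))
        if idx.size < n_tr + n_te:
            raise InvalidArgumentError(
                f"class {lab}: need {n_tr + n_te} samples, have {idx.size}"
            )
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_tr])
        test_idx.extend(perm[n_tr : n_tr + n_te])
    return np.array(train_idx, dtype=int), np.array(test_idx, dtype=int)


@dataclass(frozen=True)
class ClassifierSpec:
    """Model family plus hyperparameter overrides and seed."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise InvalidArgumentError(
                f"kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}"
            )


def make_classifier(spec: ClassifierSpec):
    """Instantiate the (unfitted) scikit-learn estimator for a spec."""
    hp = dict(spec.hyperparameters)
    if spec.kind == "logistic":
        defaults = dict(C=1.0, max_iter=5000)
        defaults.update(hp)
        return LogisticRegression(**defaults)
    if spec.kind == "v_svm":
        defaults = dict(nu=0.5, kernel="rbf", gamma="scale")
        defaults.update(hp)
        return NuSVC(**defaults)
    if spec.kind == "neural_network":
        defaults = dict(
            hidden_layer_sizes=(100,),
            activation="relu",
            max_iter=1000,
            random_state=spec.seed,
        )
        defaults.update(hp)
        return MLPClassifier(**defaults)
    defaults = dict(n_estimators=100, random_state=spec.seed)
    defaults.update(hp)
    return RandomForestClassifier(**defaults)


def train(spec: ClassifierSpec, features: np.ndarray, labels):
    """Fit the classifier; deterministic given (spec, data, seed)."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(features)):
        raise InvalidArgumentError("features must be finite")
    if np.unique(labels).size < 2:
        raise InvalidArgumentError("training labels must contain >= 2 classes")
    return make_classifier(spec).fit(features, labels)


def predict(model, features: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(features, dtype=float))


@dataclass(frozen=True)
class EvaluationReport:
    """Accuracy, weighted precision and the class-by-class confusion matrix
    (rows = actual, columns = predicted)."""

    accuracy: float
    precision: float
    confusion: np.ndarray
    per_class: dict
    class_order: tuple

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "class_order": list(self.class_order),
            "confusion": self.confusion.tolist(),
            "per_class": {
                str(k): dict(v) for k, v in self.per_class.items()
            },
        }


def evaluate(predicted, actual, class_order) -> EvaluationReport:
    """Confusion-matrix bookkeeping.

    Per-class precision is column-correct/column-total (0 for an empty
    column); the report-level precision averages per-class precisions
    weighted by actual class sizes; recall is row-correct/row-total.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise InvalidArgumentError("predicted and actual lengths differ")
    order = [float(c) for c in class_order]
    for arr, name in ((predicted, "predicted"), (actual, "actual")):
        if not np.all(np.isin(arr, order)):
            raise InvalidArgumentError(f"{name} labels outside class order")
    k = len(order)
    pos = {c: i for i, c in enumerate(order)}
    confusion = np.zeros((k, k), dtype=int)
    for a, p in zip(actual, predicted):
        confusion[pos[a], pos[p]] += 1
    total = confusion.sum()
    accuracy = float(np.trace(confusion)) / total
    col_tot = confusion.sum(axis=0)
    row_tot = confusion.sum(axis=1)
    diag = np.diag(confusion)
    per_class = {}
    weighted_prec = 0.0
    for i, c in enumerate(order):
        prec = float(diag[i] / col_tot[i]) if col_tot[i] > 0 else 0.0
        rec = float(diag[i] / row_tot[i]) if row_tot[i] > 0 else 0.0
        per_class[c] = {"precision": prec, "recall": rec, "support": int(row_tot[i])}
        weighted_prec += row_tot[i] * prec
    return EvaluationReport(
        accuracy=accuracy,
        precision=float(weighted_prec / total),
        confusion=confusion,
        per_class=per_class,
        class_order=tuple(order),
    )
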