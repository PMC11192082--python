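"""Classifier-based projection of reference cell-state labels.

A random forest (500 trees) is trained on integrated low-dimensional
coordinates and applied to new cells by taking the highest-scoring class;
reliability is quantified by stratified 10-fold cross-validation with
per-class sensitivity, specificity and balanced accuracy.

The backend is pluggable: any estimator with ``fit(X, y)`` and
``predict_proba(X)`` (a cells x classes score matrix with classes in
sorted order, as scikit-learn provides) satisfies the contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .datatypes import CVReport, LabelSet

logger = logging.getLogger(__name__)

__all__ = ["StateClassifier", "train_state_classifier", "predict_states", "crossvalidate"]


@dataclass
class StateClassifier:
    """Trained state classifier with its class vocabulary and seed."""

    model: object
    classes: np.ndarray
    n_features: int
    seed: int

    def score_matrix(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimensionality {features.shape} does not match training ({self.n_features})"
            )
        return np.asarray(self.model.predict_proba(features))


def _check_training_labels(y: np.ndarray) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    small = classes[counts < 2]
    if len(small):
        raise ValueError(f"classes with fewer than 2 cells: {list(map(str, small))}")


def train_state_classifier(
    features: np.ndarray,
    labels: LabelSet | np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    backend=None,
) -> StateClassifier:
    """Train the state classifier (default random forest, 500 trees).

    ``backend`` may supply any fitted-interface estimator; by default a
    ``RandomForestClassifier(n_estimators=n_trees, random_state=seed)``.
    Training is deterministic given the seed.
    """
    features = np.asarray(features, dtype=float)
    y = labels.labels.astype(str) if isinstance(labels, LabelSet) else np.asarray(labels).astype(str)
    if len(y) != features.shape[0]:
        raise ValueError("features and labels length differ")
    _check_training_labels(y)
    model = backend if backend is not None else RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    model.fit(features, y)
    return StateClassifier(
        model=model, classes=np.asarray(model.classes_), n_features=features.shape[1], seed=seed
    )


def predict_states(model: StateClassifier, features: np.ndarray, cell_ids=None) -> LabelSet:
    """Assign each cell the highest-scoring class; confidence = that score.

    Score ties are broken toward the lexicographically smallest class
    (classes are stored sorted, and argmax takes the first maximum); ties
    are logged.
    """
    scores = model.score_matrix(features)
    best = scores.argmax(axis=1)
    n_ties = int((scores == scores.max(axis=1, keepdims=True)).sum(axis=1).max() > 1)
    if n_ties:
        logger.info("score ties present; broken toward lexicographically smallest class")
    labels = model.classes[best].astype(object)
    confidence = scores[np.arange(len(best)), best]
    if cell_ids is None:
        cell_ids = np.array([f"q{i:05d}" for i in range(len(best))], dtype=object)
    return LabelSet(
        cell_ids=np.asarray(cell_ids, dtype=object),
        labels=labels,
        vocabulary=tuple(model.classes),
        confidence=confidence,
    )


def _per_class_metrics(confusion: pd.DataFrame) -> pd.DataFrame:
    total = confusion.to_numpy().sum()
    rows = {}
    for c in confusion.index:
        tp = confusion.loc[c, c]
        fn = confusion.loc[c].sum() - tp
        fp = confusion[c].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        rows[c] = {"sensitivity": sens, "specificity": spec, "balanced_accuracy": (sens + spec) / 2}
    return pd.DataFrame.from_dict(rows, orient="index")


def crossvalidate(
    features: np.ndarray,
    labels: LabelSet | np.ndarray,
    n_folds: int = 10,
    n_trees: int = 500,
    seed: int = 0,
    backend_factory=None,
) -> CVReport:
    """Stratified k-fold cross-validation of the state classifier.

    Out-of-fold predictions are pooled into one confusion matrix
    (rows = truth, columns = prediction); sensitivity, specificity and
    balanced accuracy = (sensitivity + specificity)/2 are reported per
    class together with their macro average.
    """
    features = np.asarray(features, dtype=float)
    y = labels.labels.astype(str) if isinstance(labels, LabelSet) else np.asarray(labels).astype(str)
    classes, counts = np.unique(y, return_counts=True)
    too_small = classes[counts < n_folds]
    if len(too_small):
        raise ValueError(
            f"classes smaller than n_folds={n_folds}: {list(map(str, too_small))}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    for fold, (tr, te) in enumerate(skf.split(features, y)):
        clf = train_state_classifier(
            features[tr], y[tr], n_trees=n_trees, seed=seed + fold,
            backend=backend_factory(seed + fold) if backend_factory else None,
        )
        pred[te] = predict_states(clf, features[te]).labels

    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y, pred):
        confusion.loc[t, p] += 1
    per_class = _per_class_metrics(confusion)
    return CVReport(
        per_class=per_class,
        confusion=confusion,
        macro_balanced_accuracy=float(per_class["balanced_accuracy"].mean()),
        n_folds=n_folds,
        seed=seed,
    )
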