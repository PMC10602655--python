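"""Classifier construction and training.

The main classifier is the shallow CNN (see :mod:`eegfc.cnn`), fed either
19 x 19 connectivity matrices (z-score normalized) or 224 x 224
spectrogram images.  Conventional baselines — LDA, RBF-kernel SVM (C=1,
gamma=1/n_features) and kNN (k=5) — operate on the flattened
conventional feature vectors, standardized within training folds, and
report 10-fold cross-validated accuracy alongside the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cnn import CnnConfig, ShallowCNN, train_cnn as _train_cnn_impl

BASELINE_KINDS = ("lda", "svm", "knn")
CLASS_LABELS = ("AD", "FTD", "HC")


@dataclass
class TrainedModel:
    """A fitted classifier plus its provenance."""

    kind: str
    model: Any
    seed: int
    config: dict = field(default_factory=dict)
    training_log: dict = field(default_factory=dict)
    cv_scores: np.ndarray | None = None

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        p = self.model.predict_proba(x)
        if p.shape[1] != len(CLASS_LABELS):
            raise ValueError("expected probabilities over exactly 3 classes")
        return p

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


def build_cnn(cfg: CnnConfig | None = None) -> ShallowCNN:
    """Construct the (untrained) shallow CNN."""
    return ShallowCNN(cfg or CnnConfig())


def train_cnn(model: ShallowCNN, x_train, y_train, x_val, y_val) -> TrainedModel:
    """Train the shallow CNN with early stopping; see :func:`eegfc.cnn.train_cnn`."""
    log = _train_cnn_impl(model, x_train, y_train, x_val, y_val)
    return TrainedModel(
        kind="cnn", model=model, seed=model.cfg.seed,
        config=model.cfg.__dict__.copy(), training_log=log,
    )


def _make_baseline(kind: str, seed: int) -> Pipeline:
    if kind == "lda":
        clf = LinearDiscriminantAnalysis()
    elif kind == "svm":
        clf = SVC(kernel="rbf", C=1.0, gamma="auto", probability=True,
                  random_state=seed)
    elif kind == "knn":
        clf = KNeighborsClassifier(n_neighbors=5)
    else:
        raise ValueError(f"unknown baseline {kind!r}; known: {BASELINE_KINDS}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train_baseline(kind: str, features: np.ndarray, labels: np.ndarray,
                   seed: int = 0, n_folds: int = 10) -> TrainedModel:
    """Fit a conventional baseline and report stratified 10-fold CV accuracy.

    Features are standardized inside each fold's training portion (the
    scaler lives in the pipeline), so CV estimates are leakage-free.
    """
    features = np.asarray(features)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    if counts.min() < n_folds:
        raise ValueError(
            f"{n_folds}-fold CV needs >= {n_folds} samples per class "
            f"(smallest class has {counts.min()})"
        )
    pipe = _make_baseline(kind, seed)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(pipe, features, labels, cv=cv)
    pipe.fit(features, labels)
    return TrainedModel(
        kind=kind, model=pipe, seed=seed,
        config={"n_folds": n_folds}, cv_scores=scores,
    )
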