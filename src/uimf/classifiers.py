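"""The three interchangeable classifier heads: random forest, SVM, FCNN.

Random forest and SVM delegate to scikit-learn behind this module's surface
(one-vs-rest soft-margin SVM; bagged trees with per-tree feature
subsampling). The FCNN is the in-repo feed-forward network trained with the
focal-flooding loss by AdamW with early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .nn import (
    FFLossParams,
    MLPNet,
    TrainingResult,
    cross_entropy_from_logits,
    ff_loss_from_logits,
    softmax_probabilities,
    train_network,
)

__all__ = [
    "RFConfig",
    "SVMConfig",
    "FCNNConfig",
    "PredictionBatch",
    "RandomForestSatisfaction",
    "SVMSatisfaction",
    "FCNNSatisfaction",
    "train_rf",
    "train_svm",
    "train_fcnn",
    "predict",
]


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters (tuned grid optimum: depth 100, 100 trees)."""

    n_trees: int = 100
    max_depth: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_depth < 1:
            raise ValueError("n_trees and max_depth must be >= 1")


@dataclass(frozen=True)
class SVMConfig:
    """Soft-margin SVM hyperparameters; kernel is linear or gaussian (RBF)."""

    kernel: str = "linear"
    C: float = 1.0
    gamma: float | str = "scale"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "gaussian"):
            raise ValueError(f"kernel must be linear or gaussian, got {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass(frozen=True)
class FCNNConfig:
    """FCNN head: 2 hidden layers by default, trained by AdamW on FF loss."""

    n_hidden_layers: int = 2
    hidden_width: int = 64
    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden_layers < 1:
            raise ValueError("n_hidden_layers must be >= 1")
        if self.hidden_width < 3:
            raise ValueError("hidden_width must be >= 3")


@dataclass
class PredictionBatch:
    """Class probabilities (rows on the simplex) and argmax labels."""

    probabilities: np.ndarray
    labels: np.ndarray
    true_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        row_sums = self.probabilities.sum(axis=1)
        if self.probabilities.size and not np.allclose(row_sums, 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")


def _validate_training_input(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per label")
    if not np.all(np.isfinite(X)):
        raise ValueError("training vectors contain non-finite entries")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    return X, y


class RandomForestSatisfaction(BaseEstimator, ClassifierMixin):
    """Bootstrap-aggregated decision trees; probabilities are tree-vote means."""

    def __init__(self, n_trees: int = 100, max_depth: int = 100, seed: int = 0):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.seed = seed

    def fit(self, X, y) -> "RandomForestSatisfaction":
        X, y = _validate_training_input(X, y)
        RFConfig(n_trees=self.n_trees, max_depth=self.max_depth, seed=self.seed)
        self.model_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            max_features="sqrt",
            bootstrap=True,
            random_state=self.seed,
            n_jobs=1,
        ).fit(X, y)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        return _expand_proba(self.model_.predict_proba(X), self.classes_)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


class SVMSatisfaction(BaseEstimator, ClassifierMixin):
    """One-vs-rest soft-margin SVM.

    Decision scores are turned into pseudo-probabilities by a softmax over
    class scores — used only for loss reporting, never for calibration.
    """

    def __init__(self, kernel: str = "linear", C: float = 1.0,
                 gamma: float | str = "scale", seed: int = 0):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.seed = seed

    def fit(self, X, y) -> "SVMSatisfaction":
        X, y = _validate_training_input(X, y)
        SVMConfig(kernel=self.kernel, C=self.C, gamma=self.gamma, seed=self.seed)
        sk_kernel = "rbf" if self.kernel == "gaussian" else "linear"
        base = SVC(kernel=sk_kernel, C=self.C, gamma=self.gamma,
                   random_state=self.seed)
        self.model_ = OneVsRestClassifier(base).fit(X, y)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def decision_scores(self, X) -> np.ndarray:
        scores = self.model_.decision_function(X)
        if scores.ndim == 1:  # binary corner case
            scores = np.column_stack([-scores, scores])
        return scores

    def predict_proba(self, X) -> np.ndarray:
        return _expand_proba(
            softmax_probabilities(self.decision_scores(X)), self.classes_
        )

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


def _expand_proba(proba: np.ndarray, classes: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Map probabilities over the observed classes onto the 3-class layout."""
    if proba.shape[1] == n_classes and np.array_equal(classes, np.arange(n_classes)):
        return proba
    out = np.zeros((proba.shape[0], n_classes))
    for j, c in enumerate(classes):
        out[:, int(c)] = proba[:, j]
    row = out.sum(axis=1, keepdims=True)
    row[row == 0] = 1.0
    return out / row


class FCNNSatisfaction(BaseEstimator, ClassifierMixin):
    """Feed-forward softmax classifier trained with the focal-flooding loss.

    Training runs minibatch AdamW (decoupled weight decay) on the FF batch
    loss and stops early when the validation loss has not improved for
    ``patience`` epochs, restoring the best-validation-epoch parameters.
    Setting ``loss="cross_entropy"`` trains the same architecture with plain
    cross-entropy (the benchmark configuration).
    """

    def __init__(
        self,
        n_hidden_layers: int = 2,
        hidden_width: int = 64,
        learning_rate: float = 1e-3,
        weight_decay: float = 0.01,
        batch_size: int = 32,
        max_epochs: int = 100,
        patience: int = 10,
        seed: int = 0,
        loss_params: FFLossParams | None = None,
        loss: str = "ff",
    ):
        self.n_hidden_layers = n_hidden_layers
        self.hidden_width = hidden_width
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.loss_params = loss_params
        self.loss = loss

    def _loss(self, logits, labels, validation: bool = False):
        if self.loss == "cross_entropy":
            return cross_entropy_from_logits(logits, labels)
        params = self.loss_params_
        if validation:
            # flooding regularizes the *training* objective only; model
            # selection uses the unflooded mean focal loss
            params = FFLossParams(alpha=params.alpha, gamma=params.gamma, flood_b=0.0)
        return ff_loss_from_logits(logits, labels, params)

    def fit(self, X, y, X_val=None, y_val=None) -> "FCNNSatisfaction":
        X, y = _validate_training_input(X, y)
        FCNNConfig(
            n_hidden_layers=self.n_hidden_layers, hidden_width=self.hidden_width,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs, patience=self.patience, seed=self.seed,
        )
        self.loss_params_ = self.loss_params or FFLossParams()
        self.network_ = MLPNet(
            n_features=X.shape[1],
            hidden_width=self.hidden_width,
            n_hidden_layers=self.n_hidden_layers,
            seed=self.seed,
        )
        have_val = X_val is not None and y_val is not None and len(X_val) > 0

        def forward_loss(idx):
            return self._loss(self.network_(X[idx]), y[idx])

        def val_loss():
            return self._loss(self.network_(np.asarray(X_val, float)),
                              np.asarray(y_val, int), validation=True).item()

        self.training_result_: TrainingResult = train_network(
            self.network_.params,
            forward_loss,
            n_train=len(X),
            val_loss=val_loss if have_val else None,
            lr=self.learning_rate,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=self.seed,
        )
        self.classes_ = np.arange(3)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        logits = self.network_(np.asarray(X, dtype=float)).data
        return softmax_probabilities(logits)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


# --- functional wrappers -----------------------------------------------------


def train_rf(vectors, labels, config: RFConfig = RFConfig()) -> RandomForestSatisfaction:
    X = vectors.matrix if hasattr(vectors, "matrix") else vectors
    return RandomForestSatisfaction(
        n_trees=config.n_trees, max_depth=config.max_depth, seed=config.seed
    ).fit(X, labels)


def train_svm(vectors, labels, config: SVMConfig = SVMConfig()) -> SVMSatisfaction:
    X = vectors.matrix if hasattr(vectors, "matrix") else vectors
    return SVMSatisfaction(
        kernel=config.kernel, C=config.C, gamma=config.gamma, seed=config.seed
    ).fit(X, labels)


def train_fcnn(
    vectors,
    labels,
    config: FCNNConfig = FCNNConfig(),
    loss_params: FFLossParams | None = None,
    validation: tuple | None = None,
) -> FCNNSatisfaction:
    X = vectors.matrix if hasattr(vectors, "matrix") else vectors
    X_val = y_val = None
    if validation is not None:
        X_val, y_val = validation
        X_val = X_val.matrix if hasattr(X_val, "matrix") else X_val
    clf = FCNNSatisfaction(
        n_hidden_layers=config.n_hidden_layers,
        hidden_width=config.hidden_width,
        learning_rate=config.learning_rate,
        weight_decay=config.weight_decay,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        seed=config.seed,
        loss_params=loss_params,
    )
    return clf.fit(X, labels, X_val=X_val, y_val=y_val)


def predict(classifier, vectors, true_labels=None) -> PredictionBatch:
    """Run a trained classifier; argmax ties break toward the lower class."""
    X = vectors.matrix if hasattr(vectors, "matrix") else np.asarray(vectors, float)
    expected = getattr(classifier, "n_features_in_", X.shape[1])
    if X.shape[1] != expected:
        raise ValueError(
            f"vector dim {X.shape[1]} does not match classifier input dim {expected}"
        )
    proba = classifier.predict_proba(X)
    return PredictionBatch(
        probabilities=proba,
        labels=np.argmax(proba, axis=1),
        true_labels=None if true_labels is None else np.asarray(true_labels, int),
    )
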