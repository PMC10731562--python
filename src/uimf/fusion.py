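"""Encoder x classifier fusion: registries, composition, training protocols.

Any of the two encoders (word_embedding, transformer) composes with any of
the three classifiers (rf, svm, fcnn) into one of six fused models
f = g o h. Training depends on the pair:

* word_embedding + {rf, svm}   — fit encoder on train, encode, fit classifier;
* word_embedding + fcnn        — fit encoder, train the FCNN head with the
                                 focal-flooding loss (AdamW, early stopping);
* transformer + fcnn           — joint end-to-end training of encoder + head
                                 with the focal-flooding loss;
* transformer + {rf, svm}      — stage 1 trains transformer + fcnn jointly,
                                 stage 2 freezes the encoder and fits the
                                 rf/svm head on the pooled train vectors.

Cross-validation holds the stratified 30% test set out once and rotates the
10 folds over the remaining 70% as validation surfaces; metrics are computed
on the untouched test set per fold-trained model.
"""

from __future__ import annotations

import pickle
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .classifiers import (
    FCNNConfig,
    FCNNSatisfaction,
    PredictionBatch,
    RandomForestSatisfaction,
    RFConfig,
    SVMConfig,
    SVMSatisfaction,
    predict as _predict_batch,
)
from .encoders import (
    TfidfBowEncoder,
    TransformerDocumentEncoder,
    TransformerEncoderConfig,
    WeightedEmbeddingEncoder,
)
from .metrics import EvalReport, aggregate_reports, cohen_kappa, confusion_matrix, evaluate_predictions
from .nn import FFLossParams, MLPNet, ff_loss_from_logits, focal_loss_per_sample, train_network
from .preprocess import DatasetSplit, LabeledDocument, SplitSpec, stratified_split

__all__ = [
    "ENCODER_IDS",
    "CLASSIFIER_IDS",
    "FusedModelSpec",
    "FusedModel",
    "TrainingReport",
    "RandomProjectionAdapter",
    "compose_fused_model",
    "enumerate_specs",
    "train_fused_model",
    "extract_module",
    "recompose",
    "cross_validate",
    "grid_search_ff",
    "grid_search_rf",
    "GridSearchResult",
    "FF_ALPHA1_GRID",
    "FF_GAMMA_GRID",
    "RF_DEPTH_GRID",
    "RF_TREES_GRID",
]

ENCODER_IDS = ("word_embedding", "transformer")
CLASSIFIER_IDS = ("rf", "svm", "fcnn")

FF_ALPHA1_GRID = (0.5, 1.0, 2.0, 4.0)
FF_GAMMA_GRID = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5)
RF_DEPTH_GRID = (10, 50, 100, 300)
RF_TREES_GRID = (10, 20, 50, 100, 200, 1000)


@dataclass(frozen=True)
class FusedModelSpec:
    """One cell of the 2 x 3 encoder-classifier grid, plus its training knobs."""

    encoder_id: str = "word_embedding"
    classifier_id: str = "rf"
    encoder_mode: str = "tfidf_bow"  # word_embedding only: tfidf_bow | weighted_embedding
    max_features: int = 6000
    transformer_config: TransformerEncoderConfig | None = None
    rf_config: RFConfig = field(default_factory=RFConfig)
    svm_config: SVMConfig = field(default_factory=SVMConfig)
    fcnn_config: FCNNConfig = field(default_factory=FCNNConfig)
    loss_params: FFLossParams = field(default_factory=FFLossParams)
    split_spec: SplitSpec = field(default_factory=SplitSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.encoder_id not in ENCODER_IDS:
            raise ValueError(
                f"unknown encoder_id {self.encoder_id!r}; registered: {ENCODER_IDS}"
            )
        if self.classifier_id not in CLASSIFIER_IDS:
            raise ValueError(
                f"unknown classifier_id {self.classifier_id!r}; registered: {CLASSIFIER_IDS}"
            )
        if self.encoder_mode not in ("tfidf_bow", "weighted_embedding"):
            raise ValueError(f"unknown encoder mode {self.encoder_mode!r}")

    @property
    def is_neural_path(self) -> bool:
        return self.classifier_id == "fcnn" or self.encoder_id == "transformer"


def enumerate_specs(**kwargs) -> list[FusedModelSpec]:
    """All six valid encoder x classifier compositions."""
    return [
        FusedModelSpec(encoder_id=e, classifier_id=c, **kwargs)
        for e in ENCODER_IDS
        for c in CLASSIFIER_IDS
    ]


@dataclass
class TrainingReport:
    """Loss curves, empirical risk and wall-clock accounting of one fit."""

    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    empirical_risk_train: float | None = None
    empirical_risk_val: float | None = None
    wall_seconds: float = 0.0
    seed: int = 0
    best_epoch: int = -1


class RandomProjectionAdapter:
    """Seeded Gaussian random projection reconciling encoder/head dimensions.

    Used when an extracted classifier head expects a different input width
    than the encoder it is recomposed with (e.g. a d_model-width FCNN head
    atop the 6000-dimensional selected TF-IDF encoder).
    """

    def __init__(self, in_dim: int, out_dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.matrix = rng.normal(0.0, 1.0 / np.sqrt(in_dim), size=(in_dim, out_dim))
        self.in_dim, self.out_dim = in_dim, out_dim

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.matrix


def _labels(docs: Sequence[LabeledDocument]) -> np.ndarray:
    return np.asarray([d.label for d in docs], dtype=int)


def _per_sample_risk(probs: np.ndarray, labels: np.ndarray, params: FFLossParams) -> float:
    """Mean per-sample flooded focal loss (>= flood level by construction)."""
    focal = focal_loss_per_sample(probs, labels, params)
    return float(np.mean(np.abs(focal - params.flood_b) + params.flood_b))


class FusedModel:
    """A fused prediction function f = g o h over one spec cell."""

    def __init__(self, spec: FusedModelSpec):
        self.spec = spec
        self.encoder_ = None
        self.classifier_ = None
        self.adapter_ = None
        self.report_: TrainingReport | None = None

    @property
    def is_fitted(self) -> bool:
        return self.encoder_ is not None and self.classifier_ is not None

    # -- construction of the two modules --------------------------------------

    def _make_encoder(self):
        spec = self.spec
        if spec.encoder_id == "word_embedding":
            if spec.encoder_mode == "weighted_embedding":
                return WeightedEmbeddingEncoder(
                    max_features=spec.max_features, seed=spec.seed
                )
            return TfidfBowEncoder(max_features=spec.max_features)
        cfg = spec.transformer_config or TransformerEncoderConfig(seed=spec.seed)
        return TransformerDocumentEncoder(config=cfg)

    def _make_classifier(self, n_features: int):
        spec = self.spec
        if spec.classifier_id == "rf":
            c = spec.rf_config
            return RandomForestSatisfaction(n_trees=c.n_trees, max_depth=c.max_depth,
                                            seed=spec.seed)
        if spec.classifier_id == "svm":
            c = spec.svm_config
            return SVMSatisfaction(kernel=c.kernel, C=c.C, gamma=c.gamma, seed=spec.seed)
        c = spec.fcnn_config
        return FCNNSatisfaction(
            n_hidden_layers=c.n_hidden_layers, hidden_width=c.hidden_width,
            learning_rate=c.learning_rate, weight_decay=c.weight_decay,
            batch_size=c.batch_size, max_epochs=c.max_epochs, patience=c.patience,
            seed=spec.seed, loss_params=spec.loss_params,
        )

    # -- training --------------------------------------------------------------

    def fit(
        self,
        docs: Sequence[LabeledDocument],
        split: DatasetSplit | None = None,
    ) -> "FusedModel":
        docs = list(docs)
        if split is None:
            split = stratified_split(docs, replace(self.spec.split_spec, seed=self.spec.seed))
        by_uid = {d.uid: d for d in docs}
        train_docs = [by_uid[u] for u in sorted(split.train)]
        val_docs = [by_uid[u] for u in sorted(split.validation)]
        y_train, y_val = _labels(train_docs), _labels(val_docs)
        if len(np.unique(y_train)) < 3:
            raise ValueError("degenerate split: a class is missing from the train set")

        t0 = time.perf_counter()
        report = TrainingReport(seed=self.spec.seed)
        if self.spec.encoder_id == "word_embedding":
            self.encoder_ = self._make_encoder().fit(train_docs)
            X_train = self.encoder_.transform(train_docs)
            X_val = self.encoder_.transform(val_docs) if val_docs else None
            self.classifier_ = self._make_classifier(X_train.shape[1])
            if self.spec.classifier_id == "fcnn":
                self.classifier_.fit(X_train, y_train, X_val=X_val, y_val=y_val)
                tr = self.classifier_.training_result_
                report.train_losses = tr.train_losses
                report.val_losses = tr.val_losses
                report.best_epoch = tr.best_epoch
            else:
                self.classifier_.fit(X_train, y_train)
        else:
            self._fit_transformer_paths(train_docs, y_train, val_docs, y_val, report)

        report.wall_seconds = time.perf_counter() - t0
        if self.spec.is_neural_path:
            probs = self.predict(train_docs).probabilities
            report.empirical_risk_train = _per_sample_risk(
                probs, y_train, self.spec.loss_params
            )
            if val_docs:
                report.empirical_risk_val = _per_sample_risk(
                    self.predict(val_docs).probabilities, y_val, self.spec.loss_params
                )
        self.report_ = report
        return self

    def _fit_transformer_paths(self, train_docs, y_train, val_docs, y_val, report):
        """Stage 1: joint transformer+FCNN training with FF loss. Stage 2 (rf/svm
        heads): freeze the encoder and fit the head on pooled train vectors."""
        spec = self.spec
        encoder: TransformerDocumentEncoder = self._make_encoder().fit(train_docs)
        head_cfg = spec.fcnn_config
        head_net = MLPNet(
            n_features=encoder.config_.d_model,
            hidden_width=head_cfg.hidden_width,
            n_hidden_layers=head_cfg.n_hidden_layers,
            seed=spec.seed + 1,
        )
        params = encoder.network_.params + head_net.params
        ids_tr, mask_tr = encoder.encode_ids(train_docs)
        val_ids = encoder.encode_ids(val_docs) if val_docs else None

        def forward_loss(idx):
            pooled = encoder.network_(ids_tr[idx], mask_tr[idx])
            return ff_loss_from_logits(head_net(pooled), y_train[idx], spec.loss_params)

        val_params = replace(spec.loss_params, flood_b=0.0)  # selection unflooded

        def val_loss():
            pooled = encoder.network_(val_ids[0], val_ids[1])
            return ff_loss_from_logits(head_net(pooled), y_val, val_params).item()

        tr = train_network(
            params, forward_loss, n_train=len(train_docs),
            val_loss=val_loss if val_docs else None,
            lr=head_cfg.learning_rate, weight_decay=head_cfg.weight_decay,
            batch_size=head_cfg.batch_size, max_epochs=head_cfg.max_epochs,
            patience=head_cfg.patience, seed=spec.seed,
        )
        report.train_losses = tr.train_losses
        report.val_losses = tr.val_losses
        report.best_epoch = tr.best_epoch
        self.encoder_ = encoder

        if spec.classifier_id == "fcnn":
            head = FCNNSatisfaction(
                n_hidden_layers=head_cfg.n_hidden_layers,
                hidden_width=head_cfg.hidden_width, seed=spec.seed,
                loss_params=spec.loss_params,
            )
            head.network_ = head_net
            head.loss_params_ = spec.loss_params
            head.classes_ = np.arange(3)
            head.n_features_in_ = encoder.config_.d_model
            head.training_result_ = tr
            self.classifier_ = head
        else:
            X_train = encoder.transform(train_docs)  # frozen stage-1 encoder
            self.classifier_ = self._make_classifier(X_train.shape[1])
            self.classifier_.fit(X_train, y_train)

    # -- inference --------------------------------------------------------------

    def predict(self, docs: Sequence[LabeledDocument]) -> PredictionBatch:
        if not self.is_fitted:
            raise RuntimeError("model is not trained; call fit first")
        X = self.encoder_.transform(list(docs))
        if self.adapter_ is not None:
            X = self.adapter_(X)
        return _predict_batch(self.classifier_, X, true_labels=_labels(list(docs)))

    def evaluate(self, docs: Sequence[LabeledDocument]) -> EvalReport:
        docs = list(docs)
        batch = self.predict(docs)
        risk = None
        if self.spec.is_neural_path:
            risk = _per_sample_risk(batch.probabilities, _labels(docs), self.spec.loss_params)
        return evaluate_predictions(
            _labels(docs), batch.labels, empirical_risk=risk,
            train_seconds=self.report_.wall_seconds if self.report_ else None,
        )

    # -- module extraction / serialization --------------------------------------

    def extract_module(self, which: str):
        """Pull out the fitted encoder or classifier for reuse."""
        if not self.is_fitted:
            raise RuntimeError("cannot extract modules from an untrained model")
        if which == "encoder":
            return self.encoder_
        if which == "classifier":
            return self.classifier_
        raise ValueError(f"which must be 'encoder' or 'classifier', got {which!r}")

    def save(self, path: str | Path) -> None:
        manifest = {
            "version": 1,
            "encoder_id": self.spec.encoder_id,
            "classifier_id": self.spec.classifier_id,
            "seed": self.spec.seed,
        }
        with open(path, "wb") as fh:
            pickle.dump({"manifest": manifest, "model": self}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "FusedModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        return payload["model"]


def compose_fused_model(spec: FusedModelSpec) -> FusedModel:
    return FusedModel(spec)


def train_fused_model(
    model: FusedModel, docs: Sequence[LabeledDocument], split: DatasetSplit | None = None
) -> FusedModel:
    return model.fit(docs, split=split)


def extract_module(model: FusedModel, which: str):
    return model.extract_module(which)


def recompose(
    encoder, classifier, spec: FusedModelSpec | None = None,
    adapter: RandomProjectionAdapter | None = None,
) -> FusedModel:
    """Re-assemble fitted modules into a working fused model.

    Recomposing a model's own extracted encoder and classifier reproduces its
    predictions exactly. Crossing modules with mismatched dimensions requires
    an explicit adapter.
    """
    out = FusedModel(spec or FusedModelSpec())
    enc_dim = getattr(encoder, "n_features_", None)
    clf_dim = getattr(classifier, "n_features_in_", None)
    if adapter is None and enc_dim is not None and clf_dim is not None and enc_dim != clf_dim:
        raise ValueError(
            f"encoder output dim {enc_dim} != classifier input dim {clf_dim}; "
            "supply a RandomProjectionAdapter"
        )
    out.encoder_ = encoder
    out.classifier_ = classifier
    out.adapter_ = adapter
    return out


# --- cross-validation ---------------------------------------------------------


def cross_validate(
    spec: FusedModelSpec,
    docs: Sequence[LabeledDocument],
    n_folds: int | None = None,
) -> tuple[list[EvalReport], dict]:
    """Per-fold training with the held-out test set as the metric surface.

    The stratified 30% test set is held out once. Each of the ``n_folds``
    folds over the remaining 70% serves once as the validation set (early
    stopping surface for neural paths); the model trained on the remaining
    folds is evaluated on the untouched test set.
    """
    docs = list(docs)
    split_spec = spec.split_spec if n_folds is None else replace(spec.split_spec, n_folds=n_folds)
    if split_spec.n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    split = stratified_split(docs, replace(split_spec, seed=spec.seed))
    by_uid = {d.uid: d for d in docs}
    dev_uids = split.train | split.validation
    test_uids = sorted(split.test)
    reports: list[EvalReport] = []
    for fold_idx, fold in enumerate(split.folds):
        fold_split = DatasetSplit(
            train=dev_uids - fold, validation=set(fold), test=set(test_uids), folds=[]
        )
        model = FusedModel(replace(spec, seed=spec.seed + fold_idx))
        model.fit(docs, split=fold_split)
        reports.append(model.evaluate([by_uid[u] for u in test_uids]))
    return reports, aggregate_reports(reports)


# --- hyperparameter grids -----------------------------------------------------


@dataclass
class GridSearchResult:
    """A kappa surface over a 2-D hyperparameter grid."""

    row_values: tuple
    col_values: tuple
    surface: np.ndarray  # kappa, shape (len(rows), len(cols))
    best: tuple  # (row_value, col_value)

    @property
    def n_cells(self) -> int:
        return self.surface.size


def _validation_kappa(model: FusedModel, docs, split) -> float:
    by_uid = {d.uid: d for d in docs}
    val_docs = [by_uid[u] for u in sorted(split.validation)]
    batch = model.predict(val_docs)
    return cohen_kappa(confusion_matrix(_labels(val_docs), batch.labels))


def grid_search_ff(
    base_spec: FusedModelSpec,
    docs: Sequence[LabeledDocument],
    alpha1_values: tuple = FF_ALPHA1_GRID,
    gamma_values: tuple = FF_GAMMA_GRID,
) -> GridSearchResult:
    """Validation-kappa surface over the (alpha_1, gamma) focal-loss grid.

    alpha of class 1 ranges over {0.5, 1, 2, 4} with classes 0 and 2 fixed at
    1; gamma over {0.25 .. 1.5}. Ties prefer larger alpha_1, then larger
    gamma. All 24 cells share one stratified split; the per-cell seed is the
    base seed plus the cell index.
    """
    if not base_spec.is_neural_path:
        raise ValueError("grid_search_ff requires an FF-trained (neural) path")
    docs = list(docs)
    split = stratified_split(docs, replace(base_spec.split_spec, seed=base_spec.seed))
    surface = np.zeros((len(alpha1_values), len(gamma_values)))
    for i, a1 in enumerate(alpha1_values):
        for j, g in enumerate(gamma_values):
            cell = i * len(gamma_values) + j
            spec = replace(
                base_spec,
                loss_params=replace(base_spec.loss_params, alpha=(1.0, a1, 1.0), gamma=g),
                seed=base_spec.seed + cell,
            )
            model = FusedModel(spec).fit(docs, split=split)
            surface[i, j] = _validation_kappa(model, docs, split)
    best_flat = max(
        ((i, j) for i in range(len(alpha1_values)) for j in range(len(gamma_values))),
        key=lambda ij: (surface[ij], alpha1_values[ij[0]], gamma_values[ij[1]]),
    )
    return GridSearchResult(
        row_values=tuple(alpha1_values), col_values=tuple(gamma_values),
        surface=surface,
        best=(alpha1_values[best_flat[0]], gamma_values[best_flat[1]]),
    )


def grid_search_rf(
    base_spec: FusedModelSpec,
    docs: Sequence[LabeledDocument],
    depth_values: tuple = RF_DEPTH_GRID,
    tree_values: tuple = RF_TREES_GRID,
) -> GridSearchResult:
    """Validation-kappa surface over the random-forest depth x trees grid.

    Ties prefer fewer trees, then smaller depth (the cheaper model). The
    encoder is fitted once and shared across cells, since only the forest
    changes.
    """
    if base_spec.classifier_id != "rf":
        raise ValueError("grid_search_rf requires an rf classifier spec")
    docs = list(docs)
    split = stratified_split(docs, replace(base_spec.split_spec, seed=base_spec.seed))
    by_uid = {d.uid: d for d in docs}
    train_docs = [by_uid[u] for u in sorted(split.train)]
    val_docs = [by_uid[u] for u in sorted(split.validation)]
    y_train, y_val = _labels(train_docs), _labels(val_docs)

    base_model = FusedModel(base_spec)
    if base_spec.encoder_id == "transformer":
        # stage-1 joint training once; every grid cell reuses the frozen encoder
        base_model.fit(docs, split=split)
        encoder = base_model.encoder_
    else:
        encoder = base_model._make_encoder().fit(train_docs)
    X_train = encoder.transform(train_docs)
    X_val = encoder.transform(val_docs)

    surface = np.zeros((len(depth_values), len(tree_values)))
    for i, depth in enumerate(depth_values):
        for j, trees in enumerate(tree_values):
            cell = i * len(tree_values) + j
            clf = RandomForestSatisfaction(
                n_trees=trees, max_depth=depth, seed=base_spec.seed + cell
            ).fit(X_train, y_train)
            pred = np.argmax(clf.predict_proba(X_val), axis=1)
            surface[i, j] = cohen_kappa(confusion_matrix(y_val, pred))
    best = max(
        ((i, j) for i in range(len(depth_values)) for j in range(len(tree_values))),
        key=lambda ij: (surface[ij], -tree_values[ij[1]], -depth_values[ij[0]]),
    )
    return GridSearchResult(
        row_values=tuple(depth_values), col_values=tuple(tree_values),
        surface=surface, best=(depth_values[best[0]], tree_values[best[1]]),
    )
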