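"""Two-layer stacking: four primary learners feed a cost-sensitive naive
Bayes metalearner.

Meta-features are the primary learners' *out-of-fold* outputs: the training
rows are split into stratified inner folds, each learner is fit on the
complement of a fold and its predictions recorded for the held-out rows, so
no sample's meta-row comes from a learner that saw that sample.  The CSNB
metalearner is trained on the meta-feature matrix; primary learners are then
refit on the full training partition for deployment.

``mode="probability"`` (default) uses one positive-class probability column
per learner; ``mode="label"`` thresholds at 0.5 into {0, 1} columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .csnb import CostMatrix, CSNBModel, fit_csnb, posterior, predict_cs
from .data import LabeledDataset
from .learners import LearnerSpec, make_primary_learners

__all__ = [
    "MetaFeatures",
    "StackingModel",
    "build_meta_features",
    "fit_stacking",
    "predict_stacking",
]


@dataclass
class MetaFeatures:
    """samples x learners matrix of out-of-fold primary outputs."""

    matrix: np.ndarray
    fold_assignment: np.ndarray
    mode: str = "probability"


@dataclass
class StackingModel:
    primary: list
    meta: CSNBModel
    mode: str
    inner_folds: int
    n_features: int
    positive_class: object = None


def _meta_columns(learners, X_fit, y_fit, X_out, mode) -> np.ndarray:
    cols = []
    for lr in learners:
        proba = np.asarray(lr.fit(X_fit, y_fit).predict_proba(X_out), dtype=float)
        if mode == "label":
            proba = (proba >= 0.5).astype(float)
        cols.append(proba)
    return np.stack(cols, axis=1)


def build_meta_features(
    data: LabeledDataset,
    learners: list,
    inner_folds: int = 10,
    mode: str = "probability",
    seed: int = 0,
) -> MetaFeatures:
    """Out-of-fold meta-feature construction over stratified inner folds.

    y is encoded with 1 = positive (minority) class so that every meta column
    is a positive-class score.
    """
    if mode not in {"probability", "label"}:
        raise ValueError(f"unknown meta-feature mode {mode!r}")
    y_pos = (data.labels == data.positive_class).astype(int)
    min_class = int(min(np.sum(y_pos == 0), np.sum(y_pos == 1)))
    if inner_folds < 2:
        raise ValueError("inner_folds must be >= 2")
    if min_class < inner_folds:
        raise ValueError(
            f"smallest class has {min_class} samples < {inner_folds} inner folds; "
            "reduce inner_folds"
        )
    X = data.matrix
    meta = np.empty((data.n_samples, len(learners)))
    assignment = np.empty(data.n_samples, dtype=int)
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    for f, (train_idx, test_idx) in enumerate(skf.split(X, y_pos)):
        meta[test_idx] = _meta_columns(
            learners, X[train_idx], y_pos[train_idx], X[test_idx], mode
        )
        assignment[test_idx] = f
    return MetaFeatures(matrix=meta, fold_assignment=assignment, mode=mode)


def fit_stacking(
    data: LabeledDataset,
    specs="defaults",
    inner_folds: int = 10,
    mode: str = "probability",
    cost: CostMatrix | str = "auto",
    seed: int = 0,
) -> StackingModel:
    """Fit the two-layer ensemble on a training partition.

    Builds out-of-fold meta-features, fits CSNB on them, then refits the four
    primary learners on all training rows for deployment.
    """
    learners = make_primary_learners(specs, seed=seed)
    mf = build_meta_features(data, learners, inner_folds, mode, seed)
    meta_data = LabeledDataset(
        mf.matrix,
        data.labels,
        [f"meta_{i}" for i in range(mf.matrix.shape[1])],
        data.positive_class,
    )
    meta_model = fit_csnb(meta_data, cost=cost)
    y_pos = (data.labels == data.positive_class).astype(int)
    for lr in learners:
        lr.fit(data.matrix, y_pos)
    return StackingModel(
        primary=learners,
        meta=meta_model,
        mode=mode,
        inner_folds=inner_folds,
        n_features=data.n_features,
        positive_class=data.positive_class,
    )


def predict_stacking(model: StackingModel, matrix) -> tuple[np.ndarray, np.ndarray]:
    """Labels and positive-class scores for new samples.

    Scores are the metalearner's posterior of the positive class; the cost
    matrix moves the labeling threshold but never reorders scores, so ROC
    analysis is cost-free.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    cols = []
    for lr in model.primary:
        proba = np.asarray(lr.predict_proba(X), dtype=float)
        if model.mode == "label":
            proba = (proba >= 0.5).astype(float)
        cols.append(proba)
    meta = np.stack(cols, axis=1)
    labels = predict_cs(model.meta, meta)
    post = np.atleast_2d(posterior(model.meta, meta))
    pos_idx = list(model.meta.class_labels).index(model.positive_class)
    return labels, post[:, pos_idx]
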