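"""Nested cross-validation and the metric suite for imbalanced two-class data.

The outer 5-fold split measures generalization; inside each outer training
partition the stacking ensemble runs its own 10-fold split to build
meta-features, giving the 5 x 10 nested design.  Standardization, FCBF
selection and the full stacking fit are all computed on the outer training
partition only and then applied to the held-out fold, so feature selection
cannot peek at test samples.  A ``paper_mode`` switch instead performs one
global FCBF pass before the outer split (the workflow used by some published
microarray studies); it logs a selection-bias warning.

Metrics treat the minority class as positive.  Pooled (micro-averaged)
counts across outer folds are the headline numbers; per-fold metrics are
retained.  AUC is the Mann-Whitney statistic (ties counted 1/2) of the
pooled positive-class scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .csnb import CostMatrix
from .data import LabeledDataset, apply_standardizer, fit_standardizer
from .fcbf import fcbf_select
from .stacking import fit_stacking, predict_stacking

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_metrics",
    "roc_auc",
    "nested_cv_evaluate",
    "stratified_folds",
]

logger = logging.getLogger("csnbstack")


@dataclass
class ConfusionCounts:
    """2x2 counts with the minority class as positive."""

    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fn + other.fn,
            self.tn + other.tn, self.fp + other.fp,
        )

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def _ratio(num: float, den: float) -> float:
    """0/0 is defined as 0 for every metric ratio."""
    return num / den if den > 0 else 0.0


def confusion_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, recall, specificity, precision and F-score from counts."""
    if counts.n < 1:
        raise ValueError("empty confusion table")
    recall = _ratio(counts.tp, counts.tp + counts.fn)
    specificity = _ratio(counts.tn, counts.tn + counts.fp)
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    return {
        "accuracy": _ratio(counts.tp + counts.tn, counts.n),
        "recall": recall,
        "specificity": specificity,
        "precision": precision,
        "f_score": _ratio(2 * precision * recall, precision + recall),
    }


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points (fpr, tpr) from a threshold sweep plus the AUC.

    AUC equals the Mann-Whitney probability that a random positive outscores
    a random negative, ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to sweep a ROC curve")
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(roc_auc_score(labels, scores))


def stratified_folds(labels, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified test-fold index sets (shuffled once by seed)."""
    y = np.asarray(labels)
    _, y_enc = np.unique(y, return_inverse=True)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros_like(y_enc), y_enc)]


@dataclass
class MetricReport:
    pooled: dict
    auc: float
    roc_points: list
    counts: ConfusionCounts
    per_fold: list = field(default_factory=list)
    n_selected: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pooled": self.pooled,
            "auc": self.auc,
            "counts": vars(self.counts),
            "per_fold": self.per_fold,
            "n_selected_per_fold": self.n_selected,
            "roc_points": self.roc_points,
        }


def _count_fold(y_true_pos: np.ndarray, y_pred_pos: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int(np.sum((y_true_pos == 1) & (y_pred_pos == 1))),
        fn=int(np.sum((y_true_pos == 1) & (y_pred_pos == 0))),
        tn=int(np.sum((y_true_pos == 0) & (y_pred_pos == 0))),
        fp=int(np.sum((y_true_pos == 0) & (y_pred_pos == 1))),
    )


def nested_cv_evaluate(
    data: LabeledDataset,
    outer_folds: int = 5,
    inner_folds: int = 10,
    seed: int = 0,
    delta: float = 0.0,
    cost: CostMatrix | str = "auto",
    mode: str = "probability",
    specs="defaults",
    paper_mode: bool = False,
) -> MetricReport:
    """5-fold-outer / 10-fold-inner nested cross-validation of the pipeline.

    Per outer fold: standardizer and FCBF fit on the training partition,
    stacking fit on the reduced training matrix, held-out fold scored;
    confusion counts pooled across folds, ROC from pooled scores.
    """
    y_pos = (data.labels == data.positive_class).astype(int)
    counts_per_class = np.bincount(y_pos, minlength=2)
    if counts_per_class.min() < outer_folds:
        raise ValueError(
            f"smallest class has {counts_per_class.min()} samples; cannot "
            f"stratify {outer_folds} outer folds"
        )
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=outer_folds + 1)

    global_selected = None
    if paper_mode:
        logger.warning(
            "paper_mode: FCBF runs once on the full dataset before the outer "
            "split; selection sees the test folds (selection bias)"
        )
        mean, sd = fit_standardizer(data.matrix)
        full_std = LabeledDataset(
            apply_standardizer(data.matrix, mean, sd),
            data.labels, data.feature_names, data.positive_class,
        )
        global_selected = fcbf_select(full_std, delta=delta).selected

    folds = stratified_folds(data.labels, outer_folds, int(fold_seeds[-1]))
    all_idx = np.arange(data.n_samples)
    pooled = ConfusionCounts()
    scores = np.empty(data.n_samples)
    preds_pos = np.empty(data.n_samples, dtype=int)
    per_fold = []
    n_selected = []

    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train = data.subset_rows(train_idx)
        mean, sd = fit_standardizer(train.matrix)
        Xtr = apply_standardizer(train.matrix, mean, sd)
        Xte = apply_standardizer(data.matrix[test_idx], mean, sd)
        train_std = LabeledDataset(
            Xtr, train.labels, train.feature_names, train.positive_class
        )
        if paper_mode:
            selected = global_selected
        else:
            selected = fcbf_select(train_std, delta=delta).selected
        n_selected.append(len(selected))
        if selected:
            Xtr_sel, Xte_sel = Xtr[:, selected], Xte[:, selected]
        else:
            # nothing survived the filter: a constant column makes every
            # learner fall back to the class prior
            Xtr_sel = np.zeros((Xtr.shape[0], 1))
            Xte_sel = np.zeros((Xte.shape[0], 1))
        fold_train = LabeledDataset(
            Xtr_sel, train.labels, None, train.positive_class
        )
        model = fit_stacking(
            fold_train, specs=specs, inner_folds=inner_folds, mode=mode,
            cost=cost, seed=int(fold_seeds[f]),
        )
        labels_hat, score = predict_stacking(model, Xte_sel)
        yhat_pos = (labels_hat == data.positive_class).astype(int)
        scores[test_idx] = score
        preds_pos[test_idx] = yhat_pos
        fold_counts = _count_fold(y_pos[test_idx], yhat_pos)
        pooled = pooled + fold_counts
        per_fold.append(
            {
                "fold": f,
                "test_indices": [int(i) for i in test_idx],
                "counts": vars(fold_counts),
                "metrics": confusion_metrics(fold_counts),
            }
        )

    assert pooled.n == data.n_samples
    fpr, tpr, auc = roc_auc(scores, y_pos)
    return MetricReport(
        pooled=confusion_metrics(pooled),
        auc=auc,
        roc_points=[[float(a), float(b)] for a, b in zip(fpr, tpr)],
        counts=pooled,
        per_fold=per_fold,
        n_selected=n_selected,
    )
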