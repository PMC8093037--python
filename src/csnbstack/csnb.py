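"""Cost-sensitive naive Bayes (CSNB) for two classes.

Class 0 is the minority class, class 1 the majority.  A 2x2 cost matrix C
assigns C[i][j] = cost of predicting class j when the truth is class i; with
zero diagonal and c01 > c10 the rare class is the expensive one to miss.
Posteriors come from a naive Bayes with Gaussian per-feature conditionals
(features are assumed standardized and continuous); likelihoods accumulate in
log space so that thousands of features cannot underflow.  Prediction
minimizes the expected misclassification cost

    R(c_j | x) = sum_i P(c_i | x) * C[i][j]

and ties go to the minority class, consistent with the cost-sensitive intent.
With c01 = c10 the rule reduces exactly to the MAP naive Bayes baseline.

A categorical event model over discretized codes is available behind
``event_model="categorical"`` for sensitivity checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .data import LabeledDataset

__all__ = [
    "CostMatrix",
    "CSNBModel",
    "RiskVector",
    "fit_csnb",
    "posterior",
    "expected_risk",
    "predict_cs",
    "decide_from_posteriors",
    "model_to_json",
    "model_from_json",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class CostMatrix:
    """Misclassification costs; row = true class, column = predicted class."""

    c01: float
    c10: float = 1.0
    c00: float = 0.0
    c11: float = 0.0

    def __post_init__(self) -> None:
        if self.c00 != 0.0 or self.c11 != 0.0:
            raise ValueError("correct classification must cost 0 (c00 = c11 = 0)")
        if not (self.c10 > 0 and self.c01 > 0):
            raise ValueError("misclassification costs must be positive")
        if self.c01 < self.c10:
            raise ValueError(
                "c01 (minority misclassified) must be >= c10; "
                "use c01 == c10 for the cost-blind naive Bayes mode"
            )

    @property
    def ratio(self) -> float:
        return self.c01 / self.c10

    @classmethod
    def uniform(cls) -> "CostMatrix":
        return cls(c01=1.0, c10=1.0)

    @classmethod
    def auto(cls, n_minority: int, n_majority: int) -> "CostMatrix":
        """Inverse class-frequency costs: c01 = N_maj / N_min, c10 = 1."""
        return cls(c01=n_majority / n_minority, c10=1.0)


@dataclass
class RiskVector:
    """Expected cost of predicting class 0 (r0) and class 1 (r1)."""

    r0: float
    r1: float


@dataclass
class CSNBModel:
    """Fitted priors, per-class per-feature Gaussian moments and cost matrix.

    ``class_labels`` maps (class 0, class 1) = (minority, majority) back to
    the original label values.
    """

    log_priors: np.ndarray          # shape (2,)
    means: np.ndarray               # shape (2, p)
    variances: np.ndarray           # shape (2, p), floored at eps
    cost: CostMatrix
    eps: float
    class_labels: tuple = ("0", "1")
    event_model: str = "gaussian"
    log_cond: np.ndarray | None = None   # categorical model: (2, p, n_codes)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def fit_csnb(
    data: LabeledDataset,
    cost: CostMatrix | str = "auto",
    event_model: str = "gaussian",
) -> CSNBModel:
    """Fit CSNB: priors = class frequencies, conditionals per class/feature.

    ``cost="auto"`` uses the inverse class-frequency matrix.  Gaussian moments
    use the n-1 variance denominator with a floor eps = max(1e-9 * largest
    feature variance, 1e-9) guarding against zero-variance collapse.
    """
    y = data.binary_labels()
    n0 = int((y == 0).sum())
    n1 = int((y == 1).sum())
    if min(n0, n1) < 2:
        raise ValueError("each class needs at least 2 samples to fit conditionals")
    if cost == "auto":
        cost = CostMatrix.auto(n_minority=n0, n_majority=n1)
    elif not isinstance(cost, CostMatrix):
        raise ValueError(f"invalid cost specification: {cost!r}")

    X = data.matrix
    means = np.stack([X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)])
    variances = np.stack(
        [X[y == 0].var(axis=0, ddof=1), X[y == 1].var(axis=0, ddof=1)]
    )
    overall = X.var(axis=0, ddof=1)
    eps = max(1e-9 * float(overall.max(initial=0.0)), 1e-9)
    variances = np.maximum(variances, eps)
    model = CSNBModel(
        log_priors=np.log(np.array([n0, n1]) / (n0 + n1)),
        means=means,
        variances=variances,
        cost=cost,
        eps=eps,
        class_labels=(data.minority_class, data.majority_class),
        event_model=event_model,
    )
    if event_model == "categorical":
        codes = X.astype(int)
        n_codes = int(codes.max()) + 1 if codes.size else 1
        cond = np.ones((2, X.shape[1], n_codes))  # Laplace smoothing
        for c in (0, 1):
            for j in range(X.shape[1]):
                cnt = np.bincount(codes[y == c, j], minlength=n_codes)
                cond[c, j] += cnt
        cond /= cond.sum(axis=2, keepdims=True)
        model.log_cond = np.log(cond)
    elif event_model != "gaussian":
        raise ValueError(f"unknown event model {event_model!r}")
    return model


def _log_joint(model: CSNBModel, X: np.ndarray) -> np.ndarray:
    """log P(x, c) for each sample and class, shape (n, 2); log space throughout."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    if model.event_model == "categorical":
        codes = np.clip(X.astype(int), 0, model.log_cond.shape[2] - 1)
        feat = np.arange(model.n_features)[None, :]
        ll = np.empty((X.shape[0], 2))
        for c in (0, 1):
            ll[:, c] = model.log_cond[c][feat, codes].sum(axis=1)
    else:
        diff = X[:, None, :] - model.means[None, :, :]
        ll = -0.5 * (
            diff**2 / model.variances[None, :, :]
            + np.log(model.variances[None, :, :])
            + _LOG_2PI
        ).sum(axis=2)
    return ll + model.log_priors[None, :]


def posterior(model: CSNBModel, x) -> np.ndarray:
    """Normalized class posteriors (P(c0|x), P(c1|x)); rows sum to 1.

    Accepts a single feature vector or a samples x features matrix; returns
    shape (2,) or (n, 2) accordingly.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    lj = _log_joint(model, x)
    post = np.exp(lj - logsumexp(lj, axis=1, keepdims=True))
    return post[0] if single else post


def decide_from_posteriors(p0, p1, cost: CostMatrix) -> np.ndarray:
    """Risk-minimizing class index from posteriors; tie -> minority (0).

    r0 = p0*c00 + p1*c10, r1 = p0*c01 + p1*c11; returns argmin, vectorized.
    Risks within 1e-9 relative of each other count as tied, so that exact
    mathematical ties (e.g. posteriors equal to the priors under the
    inverse-frequency cost matrix) are not broken by rounding noise.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    r0 = p0 * cost.c00 + p1 * cost.c10
    r1 = p0 * cost.c01 + p1 * cost.c11
    tol = 1e-9 * np.maximum(np.maximum(r0, r1), 1e-300)
    return np.where(r0 <= r1 + tol, 0, 1)


def expected_risk(model: CSNBModel, x) -> RiskVector:
    """Expected misclassification cost of each possible prediction."""
    p = posterior(model, np.asarray(x, dtype=float))
    if p.ndim != 1:
        raise ValueError("expected_risk takes a single feature vector")
    c = model.cost
    return RiskVector(
        r0=float(p[0] * c.c00 + p[1] * c.c10),
        r1=float(p[0] * c.c01 + p[1] * c.c11),
    )


def predict_cs(model: CSNBModel, x) -> object:
    """Predict by minimizing expected cost; returns original label value(s).

    Equivalently: predict the minority class iff P(c0|x)/P(c1|x) > c10/c01,
    with the boundary itself going to the minority class.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    p = np.atleast_2d(posterior(model, x))
    idx = decide_from_posteriors(p[:, 0], p[:, 1], model.cost)
    labels = np.asarray(model.class_labels, dtype=object)[idx]
    return labels[0] if single else labels


def model_to_json(model: CSNBModel, path: str | Path | None = None) -> str:
    """Serialize a fitted model to a documented JSON layout."""
    payload = {
        "format": "csnb-model-v1",
        "event_model": model.event_model,
        "class_labels": [str(c) for c in model.class_labels],
        "log_priors": model.log_priors.tolist(),
        "means": model.means.tolist(),
        "variances": model.variances.tolist(),
        "eps": model.eps,
        "cost": {"c01": model.cost.c01, "c10": model.cost.c10},
        "log_cond": None if model.log_cond is None else model.log_cond.tolist(),
    }
    text = json.dumps(payload, indent=1, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(source: str | Path) -> CSNBModel:
    text = str(source)
    if not text.lstrip().startswith("{"):
        text = Path(text).read_text()
    d = json.loads(text)
    if d.get("format") != "csnb-model-v1":
        raise ValueError("not a csnb model JSON")
    return CSNBModel(
        log_priors=np.asarray(d["log_priors"]),
        means=np.asarray(d["means"]),
        variances=np.asarray(d["variances"]),
        cost=CostMatrix(c01=d["cost"]["c01"], c10=d["cost"]["c10"]),
        eps=float(d["eps"]),
        class_labels=tuple(d["class_labels"]),
        event_model=d["event_model"],
        log_cond=None if d["log_cond"] is None else np.asarray(d["log_cond"]),
    )
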