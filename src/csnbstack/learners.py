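"""The four primary learners behind a uniform fit / predict-probability contract.

Order is fixed as (rbf-SVM, KNN, gain-ratio tree, random forest) so that
meta-feature columns are reproducible.  Each wrapper exposes

    fit(X, y)            with y in {0, 1}, 1 = positive class
    predict_proba(X)     -> per-sample positive-class probability in [0, 1]

SVM, KNN and random forest adapt scikit-learn estimators; the ensemble and
metalearner are the interesting part of this package, not these textbook
classifiers.  The tree is bespoke because the backing library offers no
gain-ratio split criterion: binary threshold splits chosen by information
gain ratio (among splits with at least average information gain, the usual
guard against the ratio favoring tiny splits), with optional pessimistic
pruning from a Clopper-Pearson upper confidence bound on the leaf error.

The RBF kernel here is K(x, xi) = exp(-||x - xi||^2 / sigma^2); note the
sigma^2 denominator, which maps onto the common "gamma" convention as
gamma = 1 / sigma^2 (no factor of 2).  sigma defaults to the median pairwise
distance of the training rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from scipy.special import expit
from scipy.stats import beta
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "LearnerSpec",
    "rbf_kernel",
    "make_primary_learners",
    "RbfSvmLearner",
    "KnnLearner",
    "GainRatioTreeLearner",
    "RandomForestLearner",
]

LEARNER_ORDER = ("rbf_svm", "knn", "c45_tree", "random_forest")


def rbf_kernel(x, xi, sigma: float) -> float:
    """exp(-||x - xi||^2 / sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = np.asarray(x, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if x.shape != xi.shape:
        raise ValueError("x and xi must have equal length")
    return float(np.exp(-np.sum((x - xi) ** 2) / sigma**2))


@dataclass(frozen=True)
class LearnerSpec:
    """Declarative description of one primary learner."""

    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in LEARNER_ORDER:
            raise ValueError(f"unknown learner kind {self.kind!r}")
        p = self.parameters
        if self.kind == "knn" and p.get("k", 5) < 1:
            raise ValueError("knn needs k >= 1")
        if self.kind == "rbf_svm" and p.get("sigma") is not None and p["sigma"] <= 0:
            raise ValueError("rbf_svm needs sigma > 0")
        if self.kind == "random_forest" and p.get("n_trees", 100) < 1:
            raise ValueError("random_forest needs n_trees >= 1")


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) with one label per row")
    return X, y


class RbfSvmLearner:
    """RBF-kernel SVM; probabilities are a logistic link on decision values,
    hence a monotone (rank-preserving) transform of them."""

    def __init__(self, sigma: float | None = None, C: float = 1.0):
        if sigma is not None and sigma <= 0:
            raise ValueError("sigma must be > 0")
        self.sigma = sigma
        self.C = C
        self._est = None

    def fit(self, X, y):
        X, y = _check_xy(X, y)
        sigma = self.sigma
        if sigma is None:
            d = pdist(X) if X.shape[0] > 1 else np.array([0.0])
            med = float(np.median(d))
            sigma = med if med > 0 else 1.0
        self._gamma = 1.0 / sigma**2
        self._est = SVC(kernel="rbf", gamma=self._gamma, C=self.C)
        self._est.fit(X, y)
        return self

    def decision_values(self, X) -> np.ndarray:
        df = self._est.decision_function(np.asarray(X, dtype=float))
        # sklearn orients the decision function toward classes_[1]
        return df if self._est.classes_[1] == 1 else -df

    def predict_proba(self, X) -> np.ndarray:
        return expit(self.decision_values(X))


class KnnLearner:
    """K-nearest-neighbor vote; probability = fraction of positive neighbors."""

    def __init__(self, k: int = 5, metric: str = "euclidean"):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.metric = metric
        self._est = None

    def fit(self, X, y):
        X, y = _check_xy(X, y)
        k = min(self.k, X.shape[0])
        self._est = KNeighborsClassifier(n_neighbors=k, metric=self.metric)
        self._est.fit(X, y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        proba = self._est.predict_proba(np.asarray(X, dtype=float))
        if 1 not in self._est.classes_:
            return np.zeros(proba.shape[0])
        return proba[:, list(self._est.classes_).index(1)]


def _entropy2(counts: np.ndarray, axis=None) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum(axis=axis, keepdims=True)
    total = np.where(total == 0, 1.0, total)
    p = counts / total
    with np.errstate(invalid="ignore", divide="ignore"):
        term = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -term.sum(axis=axis)


@dataclass
class _Node:
    n_pos: int
    n_neg: int
    feature: int = -1
    threshold: float = 0.0
    left: "._Node | None" = None
    right: "._Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


class GainRatioTreeLearner:
    """Binary-threshold decision tree split on the information gain ratio.

    Candidate splits are midpoints between distinct adjacent feature values;
    only splits whose information gain reaches the node's average candidate
    gain compete on gain ratio.  With ``prune=True`` (default) subtrees are
    replaced by leaves when the pessimistic error estimate (upper 75%
    Clopper-Pearson bound on the error rate) does not improve.
    """

    def __init__(
        self,
        prune: bool = True,
        confidence: float = 0.25,
        min_samples_split: int = 2,
        max_depth: int | None = None,
    ):
        self.prune = prune
        self.confidence = confidence
        self.min_samples_split = min_samples_split
        self.max_depth = max_depth
        self._root: _Node | None = None

    # -- growing ---------------------------------------------------------
    def _best_split(self, X, y):
        best = None  # (ratio, feature, threshold)
        for j in range(X.shape[1]):
            vals = X[:, j]
            order = np.argsort(vals, kind="mergesort")
            v = vals[order]
            t = y[order]
            distinct = np.flatnonzero(np.diff(v) > 0)  # boundary after index i
            if distinct.size == 0:
                continue
            cum_pos = np.cumsum(t)
            n = len(t)
            n_pos = cum_pos[-1]
            nl = distinct + 1
            lp = cum_pos[distinct]
            left = np.stack([lp, nl - lp], axis=1)
            right = np.stack([n_pos - lp, (n - nl) - (n_pos - lp)], axis=1)
            ent_s = float(_entropy2(np.array([n_pos, n - n_pos])))
            gain = ent_s - (
                nl * _entropy2(left, axis=1) + (n - nl) * _entropy2(right, axis=1)
            ) / n
            useful = gain > 1e-12
            if not useful.any():
                continue
            avg_gain = gain[useful].mean()
            split_info = _entropy2(np.stack([nl, n - nl], axis=1), axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(split_info > 0, gain / split_info, 0.0)
            ok = useful & (gain >= avg_gain - 1e-12) & (split_info > 0)
            if not ok.any():
                continue
            cand = np.flatnonzero(ok)
            best_i = cand[np.argmax(ratio[cand])]
            thr = float((v[distinct[best_i]] + v[distinct[best_i] + 1]) / 2.0)
            if best is None or ratio[best_i] > best[0] + 1e-12:
                best = (float(ratio[best_i]), j, thr)
        return best

    def _grow(self, X, y, depth) -> _Node:
        node = _Node(n_pos=int(y.sum()), n_neg=int(len(y) - y.sum()))
        if (
            node.n_pos == 0
            or node.n_neg == 0
            or len(y) < self.min_samples_split
            or (self.max_depth is not None and depth >= self.max_depth)
        ):
            return node
        best = self._best_split(X, y)
        if best is None:
            return node
        _, j, thr = best
        mask = X[:, j] <= thr
        node.feature = j
        node.threshold = thr
        node.left = self._grow(X[mask], y[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], depth + 1)
        return node

    # -- pruning ---------------------------------------------------------
    def _pessimistic(self, errors: int, n: int) -> float:
        if n == 0:
            return 0.0
        if errors >= n:
            return float(n)
        return n * float(beta.ppf(1.0 - self.confidence, errors + 1, n - errors))

    def _prune(self, node: _Node) -> float:
        n = node.n_pos + node.n_neg
        leaf_err = self._pessimistic(min(node.n_pos, node.n_neg), n)
        if node.is_leaf:
            return leaf_err
        subtree_err = self._prune(node.left) + self._prune(node.right)
        if leaf_err <= subtree_err:
            node.left = node.right = None
            node.feature = -1
            return leaf_err
        return subtree_err

    def fit(self, X, y):
        X, y = _check_xy(X, y)
        self._root = self._grow(X, y, 0)
        if self.prune:
            self._prune(self._root)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            node = self._root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.n_pos / max(node.n_pos + node.n_neg, 1)
        return out


class RandomForestLearner:
    """Bagged decision-tree ensemble (vote-fraction probability)."""

    def __init__(self, n_trees: int = 100, seed: int = 0):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.n_trees = n_trees
        self.seed = seed
        self._est = None

    def fit(self, X, y):
        X, y = _check_xy(X, y)
        self._est = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.seed
        )
        self._est.fit(X, y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        proba = self._est.predict_proba(np.asarray(X, dtype=float))
        if 1 not in self._est.classes_:
            return np.zeros(proba.shape[0])
        return proba[:, list(self._est.classes_).index(1)]


def _build(spec: LearnerSpec):
    p = spec.parameters
    if spec.kind == "rbf_svm":
        return RbfSvmLearner(sigma=p.get("sigma"), C=p.get("C", 1.0))
    if spec.kind == "knn":
        return KnnLearner(k=p.get("k", 5), metric=p.get("metric", "euclidean"))
    if spec.kind == "c45_tree":
        return GainRatioTreeLearner(
            prune=p.get("prune", True),
            max_depth=p.get("max_depth"),
        )
    return RandomForestLearner(n_trees=p.get("n_trees", 100), seed=spec.seed)


def default_specs(seed: int = 0) -> list[LearnerSpec]:
    return [LearnerSpec(kind=k, seed=seed) for k in LEARNER_ORDER]


def make_primary_learners(specs="defaults", seed: int = 0) -> list:
    """Instantiate the four primary learners in the fixed (svm, knn, tree,
    forest) order.  ``specs`` is "defaults" or a list of four LearnerSpec in
    that order."""
    if isinstance(specs, str):
        if specs != "defaults":
            raise ValueError(f"unknown specs preset {specs!r}")
        specs = default_specs(seed)
    specs = list(specs)
    if [s.kind for s in specs] != list(LEARNER_ORDER):
        raise ValueError(f"specs must be the four kinds in order {LEARNER_ORDER}")
    return [_build(s) for s in specs]
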