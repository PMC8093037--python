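"""Fast correlation-based filter (FCBF) feature selection.

Relevance of a feature to the class (C-correlation) and redundancy between
features (F-correlation) are both measured with symmetric uncertainty,

    SU(X, Y) = 2 * IG(X|Y) / (H(X) + H(Y)),

a normalized information gain in [0, 1] (entropies in bits).  Continuous
expression values are first made discrete with supervised entropy
minimization: recursive binary splitting where each split must pass the
Fayyad-Irani minimum-description-length acceptance test.  Features whose
discretization collapses to a single bin carry no class information and
receive SU = 0.

Selection follows the predominant-feature algorithm: rank features by
C-correlation, drop those at or below the relevance threshold delta, then walk
the ranking and remove any later feature Fj dominated by a retained earlier
feature Fi, i.e. SU(Fi, Fj) >= SU(Fj, class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .data import LabeledDataset

__all__ = [
    "DiscretizedFeature",
    "FCBFResult",
    "symmetric_uncertainty",
    "su_from_table",
    "mdl_discretize",
    "fcbf_select",
]

#: two candidate cut gains closer than this are treated as tied (smaller cut wins)
GAIN_TIE_TOL = 1e-12


def _entropy_bits(counts: np.ndarray, axis=None) -> np.ndarray:
    """Shannon entropy in bits of empirical counts along ``axis``."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum(axis=axis, keepdims=True)
    total = np.where(total == 0, 1.0, total)
    p = counts / total
    return -(xlogy(p, p).sum(axis=axis)) / np.log(2.0)


def su_from_table(table: np.ndarray) -> np.ndarray:
    """Symmetric uncertainty from a joint contingency table.

    ``table`` has shape (..., r, c); the last two axes index the joint counts
    of X and Y.  Returns 0 where both variables are constant (H(X)+H(Y)=0).
    """
    table = np.asarray(table, dtype=float)
    hx = _entropy_bits(table.sum(axis=-1), axis=-1)
    hy = _entropy_bits(table.sum(axis=-2), axis=-1)
    flat = table.reshape(*table.shape[:-2], -1)
    hxy = _entropy_bits(flat, axis=-1)
    denom = hx + hy
    ig = hx + hy - hxy
    with np.errstate(invalid="ignore", divide="ignore"):
        su = np.where(denom > 0, 2.0 * ig / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(su, 0.0, 1.0)


def symmetric_uncertainty(x, y) -> float:
    """SU between two discrete sequences, from empirical joint frequencies."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if x.size == 0:
        raise ValueError("empty sequences")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    table = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(table, (xi, yi), 1.0)
    return float(su_from_table(table))


@dataclass
class DiscretizedFeature:
    """Integer bin codes per sample plus the ascending cut points that made them."""

    codes: np.ndarray
    cut_points: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.cut_points) + 1


def _class_entropy(counts: np.ndarray) -> float:
    return float(_entropy_bits(counts))


def _best_cut(values: np.ndarray, onehot: np.ndarray) -> tuple[float, float, int] | None:
    """Best accepted binary split of (values, labels), or None.

    Returns (cut_point, gain, split_position) where split_position is the
    index into the distinct-value groups at which the left part ends.
    Vectorized over all boundaries between distinct adjacent values; gain ties
    within GAIN_TIE_TOL resolve to the smallest cut value.  A split is kept
    only when it passes the Fayyad-Irani MDL acceptance test.
    """
    distinct, inverse = np.unique(values, return_inverse=True)
    m = len(distinct)
    if m < 2:
        return None
    # per-distinct-value class counts, then cumulative from the left
    grp = np.zeros((m, onehot.shape[1]))
    np.add.at(grp, inverse, onehot)
    cum = np.cumsum(grp, axis=0)
    total = cum[-1]
    n = total.sum()
    left = cum[:-1]                      # boundary after distinct value i
    right = total - left
    nl = left.sum(axis=1)
    nr = right.sum(axis=1)
    ent_s = _class_entropy(total)
    ent_l = _entropy_bits(left, axis=1)
    ent_r = _entropy_bits(right, axis=1)
    gain = ent_s - (nl * ent_l + nr * ent_r) / n
    best = float(gain.max())
    pos = int(np.argmax(gain >= best - GAIN_TIE_TOL))  # smallest tied cut
    # Fayyad-Irani MDL acceptance
    k = int((total > 0).sum())
    k1 = int((left[pos] > 0).sum())
    k2 = int((right[pos] > 0).sum())
    delta = np.log2(3.0**k - 2.0) - (
        k * ent_s - k1 * float(ent_l[pos]) - k2 * float(ent_r[pos])
    )
    threshold = (np.log2(n - 1.0) + delta) / n
    g = float(gain[pos])
    if g <= threshold or g <= 0:
        return None
    cut = float((distinct[pos] + distinct[pos + 1]) / 2.0)
    return cut, g, pos


def mdl_discretize(values, labels) -> DiscretizedFeature:
    """Supervised entropy/MDL discretization of one continuous feature.

    Recursively picks the class-information-gain-maximizing boundary and keeps
    it only if the Fayyad-Irani MDL criterion holds; otherwise the segment
    stays one bin.  Returns bin codes plus ascending cut points (possibly
    empty, meaning a single bin).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be 1-d of equal length")
    classes, yi = np.unique(labels, return_inverse=True)
    onehot = np.eye(len(classes))[yi]

    cuts: list[float] = []

    def recurse(mask: np.ndarray) -> None:
        res = _best_cut(values[mask], onehot[mask])
        if res is None:
            return
        cut, _, _ = res
        cuts.append(cut)
        recurse(mask & (values <= cut))
        recurse(mask & (values > cut))

    recurse(np.ones(len(values), dtype=bool))
    cut_arr = np.sort(np.asarray(cuts, dtype=float))
    codes = np.searchsorted(cut_arr, values, side="left")
    return DiscretizedFeature(codes=codes, cut_points=cut_arr)


@dataclass
class FCBFResult:
    """Outcome of FCBF selection.

    ``selected`` is ordered by descending C-correlation (ties by ascending
    original index).  Every redundant removal records the predominant selected
    feature that caused it.
    """

    selected: list[int]
    c_correlation: list[float]
    removed_redundant: list[int]
    removed_irrelevant: list[int]
    delta: float
    predominant: dict[int, int] = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def fcbf_select(data: LabeledDataset, delta: float = 0.0) -> FCBFResult:
    """FCBF selection on a labeled dataset.

    Features are discretized internally (per call, i.e. per training fold when
    used inside cross-validation); features with SU(feature, class) <= delta
    are irrelevant, and of the survivors any feature dominated by a
    higher-ranked retained one is redundant.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    y = data.binary_labels()
    p = data.n_features
    codes = np.empty((data.n_samples, p), dtype=int)
    su_c = np.empty(p)
    for j in range(p):
        disc = mdl_discretize(data.matrix[:, j], y)
        codes[:, j] = disc.codes
        su_c[j] = 0.0 if disc.n_bins == 1 else symmetric_uncertainty(disc.codes, y)

    relevant = np.flatnonzero(su_c > delta)
    removed_irrelevant = sorted(set(range(p)) - set(relevant.tolist()))
    # descending SU, ties by ascending original index
    order = relevant[np.lexsort((relevant, -su_c[relevant]))]

    selected: list[int] = []
    removed_redundant: list[int] = []
    predominant: dict[int, int] = {}
    remaining = list(order)
    while remaining:
        fi = remaining.pop(0)
        selected.append(fi)
        kept = []
        for fj in remaining:
            if symmetric_uncertainty(codes[:, fi], codes[:, fj]) >= su_c[fj]:
                removed_redundant.append(fj)
                predominant[fj] = fi
            else:
                kept.append(fj)
        remaining = kept

    return FCBFResult(
        selected=[int(i) for i in selected],
        c_correlation=[float(su_c[i]) for i in selected],
        removed_redundant=sorted(int(i) for i in removed_redundant),
        removed_irrelevant=[int(i) for i in removed_irrelevant],
        delta=float(delta),
        predominant={int(k): int(v) for k, v in predominant.items()},
    )
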