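"""Synthetic microarray-like fixture generator with known ground truth.

Emulates the regime of classic two-class cancer expression benchmarks: tens
to a couple of hundred samples, thousands of features, class imbalance, a
handful of informative genes, noisy redundant copies of them, and Gaussian
noise everywhere else.  Defaults sit in the middle of that regime
(100 samples, 5000 features, 10 informative + 10 redundant, minority
fraction 0.2, mean shift 2 within-class standard deviations).

What it deliberately does not emulate: heavy-tailed intensity distributions,
gene-gene correlation beyond the planted redundant copies, and batch
effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LabeledDataset

__all__ = ["SyntheticSpec", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    effect_size is the between-class mean shift of informative features in
    within-class standard deviation units; redundant features are informative
    columns plus N(0, noise_sd^2) noise; imbalance is the minority fraction,
    realized exactly as round(imbalance * n) minority samples.
    """

    n_samples: int = 100
    n_features: int = 5000
    n_informative: int = 10
    n_redundant: int = 10
    imbalance: float = 0.2
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValueError("informative + redundant exceeds n_features")
        if not 0 < self.imbalance <= 0.5:
            raise ValueError("imbalance must be in (0, 0.5]")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant features need informative ones to copy")
        n_min = round(self.imbalance * self.n_samples)
        if n_min < 2:
            raise ValueError("minority class must have at least 2 samples")
        if self.noise_sd < 0 or self.n_samples < 4:
            raise ValueError("invalid noise_sd or too few samples")


def generate(spec: SyntheticSpec) -> tuple[LabeledDataset, dict]:
    """Draw one dataset; returns (dataset, truth).

    truth holds the informative and redundant column indices plus ``groups``:
    for each informative feature, the set {itself + its redundant copies}.
    FCBF keeps one representative per redundant group, so recovery should be
    judged at the group level.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    n_min = round(spec.imbalance * n)
    y01 = np.zeros(n, dtype=int)
    y01[:n_min] = 1  # 1 = minority ("case") before shuffling
    rng.shuffle(y01)

    X = rng.standard_normal((n, p))
    cols = rng.permutation(p)
    informative = np.sort(cols[: spec.n_informative])
    redundant = np.sort(cols[spec.n_informative : spec.n_informative + spec.n_redundant])

    X[np.ix_(y01 == 1, informative)] += spec.effect_size
    groups: list[list[int]] = [[int(i)] for i in informative]
    for k, j in enumerate(redundant):
        src = informative[k % spec.n_informative]
        X[:, j] = X[:, src] + spec.noise_sd * rng.standard_normal(n)
        groups[k % spec.n_informative].append(int(j))

    labels = np.where(y01 == 1, "case", "control")
    names = [f"g{i}" for i in range(p)]
    data = LabeledDataset(X, labels, names, positive_class="case")
    truth = {
        "informative": [int(i) for i in informative],
        "redundant": [int(i) for i in redundant],
        "groups": groups,
        "minority_label": "case",
    }
    return data, truth
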