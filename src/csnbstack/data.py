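"""Loading, validation and standardization of labeled expression matrices.

A dataset is a samples x features numeric matrix plus one binary class label
per sample.  Files are read from CSV/TSV (header row, samples as rows, one
label column) or from a minimal ARFF dialect (numeric attributes plus a single
nominal class attribute).  Rows or columns with missing entries are rejected
outright rather than imputed: with tens of samples and thousands of genes any
imputation choice would dominate downstream feature scores.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "load_dataset",
    "write_dataset",
    "standardize",
    "fit_standardizer",
    "apply_standardizer",
]


@dataclass
class LabeledDataset:
    """Samples x features matrix with a binary label per sample.

    ``positive_class`` defaults to the minority label (the label with strictly
    fewer samples; on an exact tie, the second label in first-appearance
    order).  The minority class is the one the cost-sensitive machinery
    protects, so it doubles as the positive class for recall/specificity.
    """

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str] | None = None
    positive_class: object = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional (samples x features)")
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"matrix has {self.matrix.shape[0]} rows but {self.labels.shape[0]} labels"
            )
        if not np.isfinite(self.matrix).all():
            raise ValueError("matrix contains missing or non-finite values")
        if len(self.classes) != 2:
            raise ValueError(
                f"labels are not binary: found {len(self.classes)} distinct values"
            )
        if self.feature_names is not None:
            if len(self.feature_names) != self.matrix.shape[1]:
                raise ValueError("feature_names length does not match matrix width")
        if self.positive_class is None:
            self.positive_class = self.minority_class
        elif self.positive_class not in self.classes:
            raise ValueError(f"positive_class {self.positive_class!r} not among labels")

    @property
    def classes(self) -> list:
        """The two label values in first-appearance order."""
        seen: dict = {}
        for v in self.labels.tolist():
            seen.setdefault(v, None)
        return list(seen)

    @property
    def minority_class(self):
        """Label with strictly fewer samples; tie goes to the second label."""
        a, b = self.classes
        na = int(np.sum(self.labels == a))
        nb = int(np.sum(self.labels == b))
        return a if na < nb else b

    @property
    def majority_class(self):
        a, b = self.classes
        return b if self.minority_class == a else a

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def binary_labels(self) -> np.ndarray:
        """Labels encoded as ints: 0 = minority class, 1 = majority class."""
        return np.where(self.labels == self.minority_class, 0, 1)

    def subset_rows(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(idx)
        sub_labels = self.labels[idx]
        if len(set(sub_labels.tolist())) < 2:
            raise ValueError("row subset does not contain both classes")
        return LabeledDataset(
            self.matrix[idx], sub_labels, self.feature_names, self.positive_class
        )

    def subset_features(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(idx, dtype=int)
        names = (
            [self.feature_names[i] for i in idx] if self.feature_names is not None else None
        )
        return LabeledDataset(
            self.matrix[:, idx], self.labels, names, self.positive_class
        )


def _check_missing(frame: pd.DataFrame) -> None:
    mask = frame.isna()
    if mask.to_numpy().any():
        rows = frame.index[mask.any(axis=1)].tolist()[:5]
        cols = frame.columns[mask.any(axis=0)].tolist()[:5]
        raise ValueError(
            f"missing values detected (rows {rows}, columns {cols}); "
            "rows/columns with missing entries must be removed before loading"
        )


def _frame_to_dataset(
    frame: pd.DataFrame, label_column: str | int, transpose: bool
) -> LabeledDataset:
    if transpose:
        frame = frame.T
    if isinstance(label_column, int):
        if not -frame.shape[1] <= label_column < frame.shape[1]:
            raise ValueError(f"label column index {label_column} out of range")
        label_name = frame.columns[label_column]
    else:
        if label_column not in frame.columns:
            raise ValueError(f"label column {label_column!r} not found in header")
        label_name = label_column
    labels = frame[label_name].astype(str).to_numpy()
    features = frame.drop(columns=[label_name])
    _check_missing(features)
    try:
        matrix = features.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric feature cell: {exc}") from exc
    n_classes = len(set(labels.tolist()))
    if n_classes != 2:
        raise ValueError(f"not binary: {n_classes} distinct label values")
    return LabeledDataset(matrix, labels, [str(c) for c in features.columns])


def _load_arff(path: Path, label_column: str | int | None) -> LabeledDataset:
    """Minimal ARFF reader: numeric attributes + one nominal class attribute."""
    attrs: list[tuple[str, str | list[str]]] = []
    data_lines: list[str] = []
    in_data = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if in_data:
            data_lines.append(line)
        elif low.startswith("@attribute"):
            m = re.match(r"@attribute\s+('[^']+'|\"[^\"]+\"|\S+)\s+(.+)", line, re.I)
            if not m:
                raise ValueError(f"unparseable ARFF attribute line: {line!r}")
            name = m.group(1).strip("'\"")
            spec = m.group(2).strip()
            if spec.startswith("{"):
                values = [v.strip().strip("'\"") for v in spec.strip("{}").split(",")]
                attrs.append((name, values))
            elif spec.lower() in {"numeric", "real", "integer"}:
                attrs.append((name, "numeric"))
            else:
                raise ValueError(f"unsupported ARFF attribute type: {spec!r}")
        elif low.startswith("@data"):
            in_data = True
    if not attrs or not data_lines:
        raise ValueError("ARFF file has no attributes or no data section")
    names = [a[0] for a in attrs]
    rows = [[c.strip().strip("'\"") for c in ln.split(",")] for ln in data_lines]
    if any(len(r) != len(attrs) for r in rows):
        raise ValueError("ARFF data row length does not match attribute count")
    frame = pd.DataFrame(rows, columns=names)
    frame = frame.replace("?", np.nan)
    if label_column is None:
        nominal = [n for n, t in attrs if isinstance(t, list)]
        if len(nominal) != 1:
            raise ValueError(
                "ARFF file must have exactly one nominal (class) attribute, "
                f"found {len(nominal)}; pass label_column explicitly"
            )
        label_column = nominal[0]
    return _frame_to_dataset(frame, label_column, transpose=False)


def load_dataset(
    path: str | Path,
    format: str | None = None,
    label_column: str | int | None = None,
    transpose: bool = False,
) -> LabeledDataset:
    """Read a labeled expression matrix from CSV, TSV or ARFF.

    Parameters
    ----------
    path : file path.
    format : one of ``csv``, ``tsv``, ``arff``; inferred from the suffix when
        omitted.
    label_column : header name or positional index of the class column.
        Defaults to the last column for CSV/TSV and to the single nominal
        attribute for ARFF.
    transpose : set when the file stores genes as rows (some public exports
        do); the loader normalizes to samples-as-rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".arff": "arff"}.get(
            path.suffix.lower(), "csv"
        )
    format = format.lower()
    if format == "arff":
        if transpose:
            raise ValueError("transpose is not supported for ARFF input")
        return _load_arff(path, label_column)
    if format not in {"csv", "tsv"}:
        raise ValueError(f"unknown format {format!r}")
    sep = "," if format == "csv" else "\t"
    frame = pd.read_csv(path, sep=sep, header=0, index_col=None)
    if label_column is None:
        label_column = -1
    return _frame_to_dataset(frame, label_column, transpose)


def write_dataset(
    data: LabeledDataset, path: str | Path, label_column: str = "class"
) -> None:
    """Write a dataset as CSV (header row, samples as rows, label column last)."""
    names = data.feature_names or [f"f{i}" for i in range(data.n_features)]
    frame = pd.DataFrame(data.matrix, columns=names)
    frame[label_column] = data.labels
    frame.to_csv(path, index=False)


def fit_standardizer(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and sample (n-1) standard deviation.

    Constant features get sd 1 so that applying the standardizer maps them to
    all zeros instead of raising; FCBF discards them later anyway.
    """
    matrix = np.asarray(matrix, dtype=float)
    mean = matrix.mean(axis=0)
    if matrix.shape[0] > 1:
        sd = matrix.std(axis=0, ddof=1)
    else:
        sd = np.zeros(matrix.shape[1])
    sd = np.where(sd == 0.0, 1.0, sd)
    return mean, sd


def apply_standardizer(
    matrix: np.ndarray, mean: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    return (np.asarray(matrix, dtype=float) - mean) / sd


def standardize(data: LabeledDataset) -> LabeledDataset:
    """Center each feature to mean 0 and scale to sample sd 1; labels unchanged."""
    mean, sd = fit_standardizer(data.matrix)
    return replace(data, matrix=apply_standardizer(data.matrix, mean, sd))
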