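"""Tabular datasets, synthetic data generation, and diagnosis metrics.

The benchmark tables this package targets (hand-drawing and speech feature
tables for Parkinson's disease screening) are delimited text: one row per
subject, numeric feature columns, and a binary class label.  The synthetic
generator emulates that layout — ``m_informative`` columns whose
class-conditional means differ by ``effect`` noise standard deviations,
the rest pure standard-normal noise — so every pipeline stage is testable
without external downloads.

Evaluation uses the screening-literature triple: accuracy, detection rate
(DR, sensitivity = TP/(TP+FN)) and false alarm rate (FAR = FP/(FP+TN)),
with "positive" meaning the disease class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TabularDataset",
    "SyntheticSpec",
    "EvalReport",
    "generate_synthetic",
    "load_tabular",
    "save_tabular",
    "evaluate",
]


@dataclass
class TabularDataset:
    """A numeric feature matrix with binary labels.

    ``positive_label`` designates the disease ("positive") class used when
    computing detection and false-alarm rates.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    positive_label: object = 1

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be (n, D) with one label per row")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match the column count")
        if np.isnan(self.X).any():
            raise ValueError("dataset contains missing values")
        labels = np.unique(self.y)
        if labels.size != 2:
            raise ValueError(f"expected exactly two classes, found {labels.size}")
        if self.positive_label not in labels:
            raise ValueError(f"positive label {self.positive_label!r} absent from labels {labels!r}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def masked(self, mask) -> "TabularDataset":
        """Restriction to the columns where ``mask`` is set."""
        mask = np.asarray(mask).astype(bool)
        names = [n for n, m in zip(self.feature_names, mask) if m]
        return TabularDataset(self.X[:, mask], self.y, names, self.positive_label)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic diagnosis table.

    Defaults mirror the dimensionality of a 13-feature hand-drawing table
    with 4 class-informative columns: n = 300 subjects, a 2-SD
    class-conditional mean shift on the informative columns, balanced
    classes.  Informative columns are the first ``m_informative`` by
    construction.
    """

    n: int = 300
    D: int = 13
    m_informative: int = 4
    effect: float = 2.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_informative > self.D:
            raise ValueError("m_informative cannot exceed D")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must lie in (0, 1)")
        if self.n < 4:
            raise ValueError("need at least 4 samples")
        if self.effect < 0:
            raise ValueError("effect must be non-negative")


def generate_synthetic(spec: SyntheticSpec) -> TabularDataset:
    """Deterministic synthetic dataset per the spec's recipe.

    Informative columns are N(0, 1) for class 0 and N(effect, 1) for class 1;
    noise columns are N(0, 1) regardless of class.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = min(max(int(round(spec.n * spec.class_balance)), 1), spec.n - 1)
    y = np.zeros(spec.n, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)
    X = rng.standard_normal((spec.n, spec.D))
    X[:, : spec.m_informative] += spec.effect * y[:, None]
    names = [f"inf_{j}" for j in range(spec.m_informative)] + [
        f"noise_{j}" for j in range(spec.m_informative, spec.D)
    ]
    return TabularDataset(X, y, names, positive_label=1)


def load_tabular(path, label_column: str, positive_label=1) -> TabularDataset:
    """Load a delimited-text table with a header row into a :class:`TabularDataset`.

    Feature cells must be numeric; rows containing unparseable values are
    rejected with their (1-based, header-inclusive) line numbers.
    """
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    y = df[label_column].to_numpy()
    feats = df.drop(columns=[label_column])
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        raise ValueError(f"non-numeric or missing feature values on line(s) {lines} of {path}")
    # labels may be strings; try to make them numeric so `1` matches "1"
    y_num = pd.to_numeric(pd.Series(y), errors="coerce")
    if not y_num.isna().any():
        y = y_num.to_numpy()
    return TabularDataset(
        numeric.to_numpy(dtype=float), y, list(feats.columns), positive_label
    )


def save_tabular(dataset: TabularDataset, path, label_column: str = "label") -> None:
    """Write the dataset as comma-delimited text with a header row."""
    df = pd.DataFrame(dataset.X, columns=dataset.feature_names)
    df[label_column] = dataset.y
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and the accuracy / DR / FAR triple."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def accuracy(self) -> float:
        return (self.TP + self.TN) / (self.TP + self.FP + self.TN + self.FN)

    @property
    def DR(self) -> float:
        """Detection rate (sensitivity): fraction of diseased subjects flagged."""
        pos = self.TP + self.FN
        return self.TP / pos if pos else 0.0

    @property
    def FAR(self) -> float:
        """False alarm rate: fraction of healthy subjects incorrectly flagged."""
        neg = self.FP + self.TN
        return self.FP / neg if neg else 0.0

    def to_dict(self) -> dict:
        return {
            "TP": self.TP,
            "FP": self.FP,
            "TN": self.TN,
            "FN": self.FN,
            "accuracy": self.accuracy,
            "DR": self.DR,
            "FAR": self.FAR,
        }

    def __add__(self, other: "EvalReport") -> "EvalReport":
        return EvalReport(
            self.TP + other.TP, self.FP + other.FP, self.TN + other.TN, self.FN + other.FN
        )


def evaluate(predictions, truth, positive_label=1) -> EvalReport:
    """Confusion counts of ``predictions`` against ``truth``.

    "Positive" is the disease class; a perfect classifier yields
    accuracy 1.000, DR 1.000, FAR 0.000.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    p = predictions == positive_label
    t = truth == positive_label
    return EvalReport(
        TP=int(np.sum(p & t)),
        FP=int(np.sum(p & ~t)),
        TN=int(np.sum(~p & ~t)),
        FN=int(np.sum(~p & t)),
    )
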