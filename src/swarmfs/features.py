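"""Binary wrapper feature selection driven by the sailfish optimizer.

The continuous optimizer searches a D-dimensional box (default [-4, 4] per
coordinate); each candidate position is squashed through the logistic
transfer function T(x) = 1/(1 + e^-x) and stochastically binarized —
bit d is set when a fresh uniform draw falls below T(x_d) — giving a
feature inclusion mask.  A mask's fitness is

    fitness = omega * error(S) + (1 - omega) * |S| / D        (minimized)

where error(S) is the stratified k-fold cross-validated misclassification
rate of a wrapper classifier restricted to the selected columns (default:
1-nearest-neighbour with per-fold z-scoring) and |S|/D penalizes subset
size.  Error estimates are memoized per distinct mask, so the number of
classifier evaluations is bounded by the number of distinct masks visited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import expit
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .chaos import Bounds
from .data import TabularDataset
from .sailfish import SFOConfig, optimize

__all__ = [
    "FSResult",
    "sigmoid_transfer",
    "binarize",
    "subset_fitness",
    "estimate_error",
    "select_features",
]


def sigmoid_transfer(x):
    """Logistic transfer function ``1 / (1 + exp(-x))``; maps reals into (0, 1)."""
    return expit(x)


def binarize(position: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stochastic binarization of a continuous position into a feature mask.

    Bit d is 1 when a fresh uniform draw is below the transfer value of
    coordinate d.  An all-zero outcome is repaired by setting one
    uniformly random bit, since an empty subset has no defined error.
    """
    position = np.asarray(position, dtype=float)
    mask = (rng.random(position.size) < sigmoid_transfer(position)).astype(np.int8)
    if not mask.any():
        mask[rng.integers(position.size)] = 1
    return mask


def subset_fitness(mask, error_rate: float, omega: float, D: int) -> float:
    """Weighted error/size objective ``omega * error + (1 - omega) * |S| / D``."""
    mask = np.asarray(mask)
    n_sel = int(np.count_nonzero(mask))
    if n_sel == 0:
        raise ValueError("fitness is undefined for an empty feature subset")
    if not (0.0 <= omega <= 1.0):
        raise ValueError("omega must lie in [0, 1]")
    if not (0.0 <= error_rate <= 1.0):
        raise ValueError("error_rate must lie in [0, 1]")
    return omega * error_rate + (1.0 - omega) * n_sel / D


def _fold_indices(dataset: TabularDataset, folds: int, seed: int):
    _, counts = np.unique(dataset.y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"cannot stratify {folds} folds: the smaller class has only "
            f"{counts.min()} samples, so some folds would hold a single class"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(dataset.X, dataset.y))


def _knn1_cv_error(dataset: TabularDataset, mask: np.ndarray, splits) -> float:
    """5-fold-style 1-NN misclassification rate on the masked columns.

    Vectorized nearest-neighbour with per-fold z-scoring fitted on the
    training part; ties in distance go to the earlier training row.
    """
    X = dataset.X[:, mask.astype(bool)]
    y = dataset.y
    wrong = 0
    for tr, te in splits:
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        nn = np.argmin(cdist(Xte, Xtr), axis=1)
        wrong += int(np.sum(y[tr][nn] != y[te]))
    return wrong / y.size


def _estimator_cv_error(dataset: TabularDataset, mask: np.ndarray, splits, estimator) -> float:
    """CV error with an arbitrary fit/predict estimator, per-fold z-scored."""
    X = dataset.X[:, mask.astype(bool)]
    y = dataset.y
    wrong = 0
    for tr, te in splits:
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        est = clone(estimator)
        est.fit((X[tr] - mu) / sd, y[tr])
        wrong += int(np.sum(est.predict((X[te] - mu) / sd) != y[te]))
    return wrong / y.size


def estimate_error(
    mask,
    dataset: TabularDataset,
    *,
    folds: int = 5,
    seed: int = 0,
    evaluator="knn1",
) -> float:
    """Cross-validated misclassification rate of the wrapper classifier.

    ``evaluator`` is either the string ``"knn1"`` (the fast built-in
    1-nearest-neighbour) or any scikit-learn-style estimator, cloned and
    refitted per fold.  Deterministic given (dataset, mask, folds, seed,
    evaluator).
    """
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("mask selects no features")
    splits = _fold_indices(dataset, folds, seed)
    if isinstance(evaluator, str):
        if evaluator != "knn1":
            raise ValueError(f"unknown evaluator {evaluator!r}")
        return _knn1_cv_error(dataset, mask, splits)
    return _estimator_cv_error(dataset, mask, splits, evaluator)


@dataclass
class FSResult:
    """Outcome of a feature-selection run."""

    mask: np.ndarray
    fitness: float
    error_rate: float
    n_selected: int
    history: np.ndarray
    n_estimator_calls: int

    def to_dict(self) -> dict:
        return {
            "mask": "".join(str(int(b)) for b in self.mask),
            "fitness": self.fitness,
            "error_rate": self.error_rate,
            "n_selected": self.n_selected,
            "n_estimator_calls": self.n_estimator_calls,
        }


def select_features(
    dataset: TabularDataset,
    *,
    num_sardines: int = 60,
    percent: float = 0.3,
    max_iter: int = 500,
    seed: int = 0,
    omega: float = 0.99,
    box: float = 4.0,
    folds: int = 5,
    cv_seed: int = 0,
    evaluator="knn1",
    A: float = 4.0,
    epsilon: float = 0.001,
    chaos_init: bool = True,
    t0: float = 0.9,
) -> FSResult:
    """Wrapper feature selection with the tent-chaos sailfish optimizer.

    The continuous search runs over ``[-box, box]^D``; every objective call
    binarizes the candidate with a counter-based random stream derived from
    ``seed`` (reproducible yet fresh per evaluation), looks up or computes
    the memoized CV error of the resulting mask, and scores it with
    :func:`subset_fitness`.  The best mask ever evaluated is returned.

    The error estimator is frozen by ``cv_seed`` independently of the
    search seed, so repeated searches over the same dataset compete on one
    fixed objective landscape.
    """
    D = dataset.n_features
    if D < 2:
        raise ValueError("need at least two features to select from")
    bounds = Bounds.cube(-box, box, D)
    cfg = SFOConfig(
        num_sardines=num_sardines,
        percent=percent,
        A=A,
        epsilon=epsilon,
        max_iter=max_iter,
        seed=seed,
        bounds=bounds,
        chaos_init=chaos_init,
        t0=t0,
    )

    memo: dict[tuple, float] = {}
    best = {"fitness": np.inf, "mask": None, "error": None}
    counter = [0]

    def objective(x: np.ndarray) -> float:
        rng = np.random.default_rng([seed % (2**31), counter[0]])
        counter[0] += 1
        mask = binarize(x, rng)
        key = tuple(mask.tolist())
        if key not in memo:
            memo[key] = estimate_error(mask, dataset, folds=folds, seed=cv_seed, evaluator=evaluator)
        err = memo[key]
        fit = subset_fitness(mask, err, omega, D)
        if fit < best["fitness"]:
            best["fitness"] = fit
            best["mask"] = mask.copy()
            best["error"] = err
        return fit

    result = optimize(objective, cfg)
    return FSResult(
        mask=best["mask"],
        fitness=float(best["fitness"]),
        error_rate=float(best["error"]),
        n_selected=int(np.count_nonzero(best["mask"])),
        history=result.history,
        n_estimator_calls=len(memo),
    )
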