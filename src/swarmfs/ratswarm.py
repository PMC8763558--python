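"""Rat swarm optimizer (RSO): a compact continuous minimizer.

Agents "chase and fight" around the best solution found so far.  With
``x`` the iteration index, ``R ~ U[1, 5]`` drawn once per iteration and
``C ~ U[0, 2]`` fresh per agent:

    A = R - x * (R / max_iter)                 (anneals linearly R -> 0)
    P = A * P_i + C * (P_best - P_i)
    P_i <- P_best - P

Note the first term scales the agent's own position by A rather than its
distance to the best, so early iterations push agents through the origin
region; the update is implemented exactly in this printed form.  Used here
to tune the bidirectional GRU's hyperparameters over a small continuous
box, but exposed as a general minimizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chaos import Bounds
from .sailfish import OptResult, _evaluate

__all__ = ["RSOConfig", "rso_A", "rso_step", "rso_optimize", "HyperSpace", "tune_bigru"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RSOConfig:
    pop_size: int
    max_iter: int
    R_range: tuple[float, float] = (1.0, 5.0)
    C_range: tuple[float, float] = (0.0, 2.0)
    seed: int = 0
    bounds: Bounds = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pop_size < 1:
            raise ValueError("pop_size must be positive")
        if self.max_iter < 0:
            raise ValueError("max_iter must be non-negative")
        if self.bounds is None:
            raise ValueError("bounds are required")


def rso_A(x: int, R: float, max_iter: int) -> float:
    """Annealed coefficient ``R - x * (R / max_iter)``: R at x=0, 0 at x=max_iter."""
    return R - x * (R / max_iter)


def rso_step(p_i: np.ndarray, p_r: np.ndarray, A: float, C: float) -> np.ndarray:
    """One agent update ``P_r - (A * P_i + C * (P_r - P_i))`` (caller clips)."""
    return p_r - (A * p_i + C * (p_r - p_i))


def rso_optimize(objective, config: RSOConfig) -> OptResult:
    """Minimize ``objective`` over ``config.bounds``; returns the best-ever solution.

    Uniform-random initialization; with ``max_iter == 0`` the best of the
    initial population is returned.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    bounds = config.bounds
    pos = rng.uniform(bounds.lower, bounds.upper, (config.pop_size, bounds.dim))
    fit = _evaluate(objective, pos)
    evaluations = fit.size

    best = int(np.argmin(fit))
    best_pos, best_fit = pos[best].copy(), float(fit[best])
    history = []

    for x in range(config.max_iter):
        R = rng.uniform(*config.R_range)
        A = rso_A(x, R, config.max_iter)
        C = rng.uniform(*config.C_range, size=config.pop_size)
        for i in range(config.pop_size):
            pos[i] = bounds.clip(rso_step(pos[i], best_pos, A, C[i]))
        fit = _evaluate(objective, pos)
        evaluations += fit.size
        i_best = int(np.argmin(fit))
        if fit[i_best] < best_fit:
            best_fit = float(fit[i_best])
            best_pos = pos[i_best].copy()
        history.append(best_fit)
        logger.debug("rso iter=%d best_fit=%.6g", x, best_fit)

    return OptResult(best_pos=best_pos, best_fit=best_fit, history=np.asarray(history), evaluations=evaluations)


@dataclass(frozen=True)
class HyperSpace:
    """Continuous box over BiGRU hyperparameters, decoded at evaluation time.

    Coordinates: log2 of the hidden size, log10 of the learning rate, and
    the epoch count; integers are obtained by rounding at decode time.
    """

    hidden_log2: tuple[float, float] = (2.0, 6.0)
    lr_log10: tuple[float, float] = (-4.0, -1.0)
    epochs: tuple[float, float] = (10.0, 100.0)

    def bounds(self) -> Bounds:
        lo, hi = zip(self.hidden_log2, self.lr_log10, self.epochs)
        return Bounds(np.array(lo, dtype=float), np.array(hi, dtype=float))

    def decode(self, x: np.ndarray) -> dict:
        return {
            "hidden_size": int(round(2.0 ** x[0])),
            "learning_rate": float(10.0 ** x[1]),
            "epochs": int(round(x[2])),
        }

    def midpoint(self) -> dict:
        mid = 0.5 * (self.bounds().lower + self.bounds().upper)
        return self.decode(mid)


def tune_bigru(dataset, mask, space: HyperSpace, config: RSOConfig, *, folds: int = 3):
    """Tune BiGRU hyperparameters by RSO on the masked dataset's CV error.

    Returns ``(hyperparameters, cv_error, trace)`` where ``trace`` is the
    optimizer's :class:`OptResult`.  The objective is the stratified
    ``folds``-fold cross-validated misclassification rate of a BiGRU
    trained with the decoded hyperparameters on the selected columns.
    """
    from .gru import bigru_cv_error

    mask = np.asarray(mask)
    cfg = RSOConfig(
        pop_size=config.pop_size,
        max_iter=config.max_iter,
        R_range=config.R_range,
        C_range=config.C_range,
        seed=config.seed,
        bounds=space.bounds(),
    )
    cache: dict[tuple, float] = {}

    def objective(x: np.ndarray) -> float:
        hp = space.decode(x)
        key = (hp["hidden_size"], round(hp["learning_rate"], 12), hp["epochs"])
        if key not in cache:
            cache[key] = bigru_cv_error(
                dataset, mask, hp, folds=folds, seed=config.seed
            )
        return cache[key]

    trace = rso_optimize(objective, cfg)
    best_hp = space.decode(trace.best_pos)
    return best_hp, trace.best_fit, trace
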