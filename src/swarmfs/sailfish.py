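"""Improved sailfish optimizer (SFO) for continuous minimization.

Two interacting populations search a box: *sailfish* exploit around the best
solutions while *sardines* (the prey) explore and are progressively captured.
The best-fitness sailfish ever seen is the *elite*, the best current sardine
the *injured*; both act as attractors.

Per iteration k (0-based):

  Pd    = 1 - NumSF / (NumSF + NumSD)            (prey density)
  mu_k  = 2 * r * Pd - Pd,  r ~ U(0,1)           (one draw per iteration)
  SF_i <- elite - mu_k * r_i * ((elite + injured)/2 - SF_i)
  ATK   = A * (1 - 2 * k * eps)                  (attack power, decaying)

When ATK >= 0.5 every sardine updates every coordinate by
``r * (elite - SD_j + ATK)``; once ATK drops below 0.5 only
``alpha = floor(NumSD * ATK)`` sardines update ``beta = floor(d * ATK)``
coordinates each.  A sardine whose fitness strictly beats a sailfish is
captured: the sailfish adopts its position and the sardine is removed, so
the prey population shrinks over the run.  Populations are initialized from
a single tent-chaos stream (uniform random initialization is available as a
drop-in alternative), and all positions are clipped to the box after every
update.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chaos import Bounds, TentStream, init_population

__all__ = [
    "SFOConfig",
    "SwarmState",
    "OptResult",
    "compute_pd",
    "compute_mu",
    "compute_atk",
    "update_sailfish",
    "update_sardines",
    "capture_and_replace",
    "optimize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SFOConfig:
    """Configuration of one SFO run.

    Parameters
    ----------
    num_sardines : initial prey population size.
    percent : sailfish count as a fraction of the sardine count; the
        sailfish population is ``max(1, round(num_sardines * percent))``.
    A, epsilon : attack-power schedule constants (defaults 4 and 0.001,
        under which ATK crosses 0.5 at iteration 437 and hits 0 at 500).
    max_iter : iteration budget.
    seed : master seed for all stochastic draws of the run.
    bounds : box constraints of the search space.
    chaos_init : initialize populations from a tent-chaos stream (default)
        instead of uniform pseudo-random draws.
    t0 : starting value of the tent stream.
    """

    num_sardines: int
    percent: float = 0.3
    A: float = 4.0
    epsilon: float = 0.001
    max_iter: int = 100
    seed: int = 0
    bounds: Bounds = None  # type: ignore[assignment]
    chaos_init: bool = True
    t0: float = 0.9

    def __post_init__(self) -> None:
        if self.num_sardines < 1:
            raise ValueError("num_sardines must be positive")
        if not (0.0 < self.percent <= 1.0):
            raise ValueError("percent must lie in (0, 1]")
        if self.A <= 0 or self.epsilon <= 0:
            raise ValueError("A and epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.bounds is None:
            raise ValueError("bounds are required")

    @property
    def num_sailfish(self) -> int:
        return max(1, round(self.num_sardines * self.percent))


@dataclass
class SwarmState:
    """Mutable bookkeeping of both populations during a run."""

    sailfish_pos: np.ndarray
    sailfish_fit: np.ndarray
    sardine_pos: np.ndarray
    sardine_fit: np.ndarray
    elite_pos: np.ndarray
    elite_fit: float
    injured_pos: np.ndarray
    injured_fit: float
    iter: int = 0

    def refresh_records(self) -> None:
        """Update elite (best sailfish ever) and injured (best current sardine)."""
        i = int(np.argmin(self.sailfish_fit))
        if self.sailfish_fit[i] < self.elite_fit:
            self.elite_fit = float(self.sailfish_fit[i])
            self.elite_pos = self.sailfish_pos[i].copy()
        if self.sardine_fit.size:
            j = int(np.argmin(self.sardine_fit))
            self.injured_fit = float(self.sardine_fit[j])
            self.injured_pos = self.sardine_pos[j].copy()


@dataclass
class OptResult:
    """Outcome of an optimizer run."""

    best_pos: np.ndarray
    best_fit: float
    history: np.ndarray  # best-so-far fitness after each iteration
    evaluations: int


def compute_pd(num_sf: int, num_sd: int) -> float:
    """Prey density ``1 - NumSF / (NumSF + NumSD)``; in [0, 1]."""
    if num_sf < 1 or num_sd < 0:
        raise ValueError("need at least one sailfish and a non-negative sardine count")
    return 1.0 - num_sf / (num_sf + num_sd)


def compute_mu(pd: float, r: float) -> float:
    """Step coefficient ``2 * r * pd - pd``; ranges over [-pd, +pd]."""
    return 2.0 * r * pd - pd


def compute_atk(iteration: int, A: float, epsilon: float) -> float:
    """Attack power ``A * (1 - 2 * iteration * epsilon)``, linear in the iteration."""
    return A * (1.0 - 2.0 * iteration * epsilon)


def update_sailfish(
    state: SwarmState, mu: float, rng: np.random.Generator, bounds: Bounds
) -> np.ndarray:
    """New sailfish positions, one fresh scalar r per sailfish, clipped to bounds."""
    mid = 0.5 * (state.elite_pos + state.injured_pos)
    r = rng.random(state.sailfish_pos.shape[0])[:, None]
    new = state.elite_pos - mu * r * (mid - state.sailfish_pos)
    return bounds.clip(new)


def update_sardines(
    state: SwarmState, atk: float, rng: np.random.Generator, bounds: Bounds
) -> np.ndarray:
    """New sardine positions under attack power ``atk``, clipped to bounds.

    Full update (every sardine, every coordinate) while ``atk >= 0.5``;
    below that only ``alpha`` randomly chosen sardines update ``beta``
    randomly chosen coordinates each (floored, at least 1 while atk > 0).
    """
    pos = state.sardine_pos.copy()
    n, d = pos.shape
    if n == 0:
        return pos
    if atk >= 0.5:
        r = rng.random((n, d))
        pos = r * (state.elite_pos - pos + atk)
    elif atk > 0.0:
        alpha = max(1, int(n * atk))
        beta = max(1, int(d * atk))
        chosen = rng.choice(n, size=min(alpha, n), replace=False)
        for j in chosen:
            dims = rng.choice(d, size=min(beta, d), replace=False)
            r = rng.random(dims.size)
            pos[j, dims] = r * (state.elite_pos[dims] - pos[j, dims] + atk)
    return bounds.clip(pos)


def capture_and_replace(state: SwarmState) -> SwarmState:
    """Sailfish capture strictly better sardines; captured sardines are removed.

    Sailfish are served worst-fitness first (ties to the lower index), each
    taking the best remaining sardine whose fitness strictly beats its own;
    at most one capture per sailfish per iteration.  Elite/injured records
    are refreshed afterwards.
    """
    if state.sardine_fit.size == 0:
        return state
    order = sorted(range(state.sailfish_fit.size), key=lambda i: (-state.sailfish_fit[i], i))
    alive = list(range(state.sardine_fit.size))
    for i in order:
        if not alive:
            break
        j_best = min(alive, key=lambda j: (state.sardine_fit[j], j))
        if state.sardine_fit[j_best] < state.sailfish_fit[i]:
            state.sailfish_pos[i] = state.sardine_pos[j_best]
            state.sailfish_fit[i] = state.sardine_fit[j_best]
            alive.remove(j_best)
    state.sardine_pos = state.sardine_pos[alive]
    state.sardine_fit = state.sardine_fit[alive]
    state.refresh_records()
    return state


def _evaluate(objective, X: np.ndarray) -> np.ndarray:
    """Row-wise objective values; non-finite results become +inf with a warning."""
    fit = np.empty(X.shape[0])
    for i, x in enumerate(X):
        v = float(objective(x))
        if not np.isfinite(v):
            logger.warning("objective returned non-finite value %r; using +inf", v)
            v = np.inf
        fit[i] = v
    return fit


def optimize(objective, config: SFOConfig) -> OptResult:
    """Run the chaos-initialized sailfish optimizer; returns the best-ever solution.

    Terminates early when the sardine population is exhausted.  Identical
    (objective, config) pairs yield bit-identical results.
    """
    bounds = config.bounds
    rng = np.random.default_rng(config.seed)
    nsf = config.num_sailfish

    if config.chaos_init:
        stream = TentStream(config.t0)
        sf_pos = init_population(nsf, bounds, stream=stream)
        sd_pos = init_population(config.num_sardines, bounds, stream=stream)
    else:
        sf_pos = rng.uniform(bounds.lower, bounds.upper, (nsf, bounds.dim))
        sd_pos = rng.uniform(bounds.lower, bounds.upper, (config.num_sardines, bounds.dim))

    sf_fit = _evaluate(objective, sf_pos)
    sd_fit = _evaluate(objective, sd_pos)
    evaluations = sf_fit.size + sd_fit.size

    state = SwarmState(
        sailfish_pos=sf_pos,
        sailfish_fit=sf_fit,
        sardine_pos=sd_pos,
        sardine_fit=sd_fit,
        elite_pos=sf_pos[np.argmin(sf_fit)].copy(),
        elite_fit=float(np.min(sf_fit)),
        injured_pos=sd_pos[np.argmin(sd_fit)].copy(),
        injured_fit=float(np.min(sd_fit)),
    )

    best_fit = min(state.elite_fit, state.injured_fit)
    best_pos = (state.elite_pos if state.elite_fit <= state.injured_fit else state.injured_pos).copy()
    history = []

    for k in range(config.max_iter):
        state.iter = k
        if state.sardine_fit.size == 0:
            # Prey exhausted mid-run: re-initialize the school from the
            # continuing chaos stream (or rng) so the remaining iteration
            # budget keeps exploring; the elite record is never lost.
            if config.chaos_init:
                state.sardine_pos = init_population(config.num_sardines, bounds, stream=stream)
            else:
                state.sardine_pos = rng.uniform(
                    bounds.lower, bounds.upper, (config.num_sardines, bounds.dim)
                )
            state.sardine_fit = _evaluate(objective, state.sardine_pos)
            evaluations += state.sardine_fit.size
            state.refresh_records()
            logger.info("iter=%d sardine school re-initialized", k)
        pd = compute_pd(nsf, state.sardine_fit.size)
        mu = compute_mu(pd, rng.random())
        state.sailfish_pos = update_sailfish(state, mu, rng, bounds)
        atk = compute_atk(k, config.A, config.epsilon)
        state.sardine_pos = update_sardines(state, atk, rng, bounds)
        state.sailfish_fit = _evaluate(objective, state.sailfish_pos)
        state.sardine_fit = _evaluate(objective, state.sardine_pos)
        evaluations += state.sailfish_fit.size + state.sardine_fit.size
        capture_and_replace(state)
        cur = state.elite_fit if state.sardine_fit.size == 0 else min(state.elite_fit, state.injured_fit)
        if cur < best_fit:
            best_fit = cur
            best_pos = (
                state.elite_pos if state.elite_fit <= cur else state.injured_pos
            ).copy()
        history.append(best_fit)
        logger.info(
            "iter=%d elite_fit=%.6g sardines=%d", k, state.elite_fit, state.sardine_fit.size
        )

    return OptResult(
        best_pos=best_pos,
        best_fit=best_fit,
        history=np.asarray(history),
        evaluations=evaluations,
    )
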