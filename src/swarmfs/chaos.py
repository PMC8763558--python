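"""Tent chaotic map and chaos-based population initialization.

The tent map is a piecewise-linear map on the open unit interval with a
breakpoint at 0.7:

    T_{i+1} = T_i / 0.7          if T_i <= 0.7
    T_{i+1} = (1 - T_i) / 0.3    if T_i >  0.7

Iterating it produces a deterministic but irregular sequence that spreads
initial swarm positions across the search box more evenly than a short
pseudo-random draw, which helps population-based optimizers keep early
diversity.  Positions are obtained by the affine map

    X[i, j] = T * (upper[j] - lower[j]) + lower[j]

with T taken from a single running tent stream consumed row-major, so the
whole initialization is reproducible from the starting value alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Bounds", "TentStream", "tent_next", "tent_sequence", "init_population"]

#: Breakpoint of the tent map.
TENT_BREAK = 0.7

#: Half-open guard band: iterates are kept inside (EPS, 1 - EPS).
EPS = 1e-12

#: Interior restart point used when an iterate collapses onto 0 or 1.
RESTART = 0.9


@dataclass(frozen=True)
class Bounds:
    """Per-dimension box constraints of a continuous search space."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("lower and upper must be 1-d arrays of equal length")
        if np.any(lower > upper):
            raise ValueError("each lower bound must not exceed its upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @classmethod
    def cube(cls, lower: float, upper: float, dim: int) -> "Bounds":
        """A symmetric box ``[lower, upper]^dim``."""
        return cls(np.full(dim, float(lower)), np.full(dim, float(upper)))

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


def tent_next(value: float, _counter: list | None = None) -> float:
    """One tent-map iterate, sanitized back into the open unit interval.

    The raw map can land exactly on 0 or 1 (0.7 -> 1.0 -> 0.0 -> 0 ...),
    after which the sequence is stuck.  Whenever an iterate leaves
    ``(EPS, 1 - EPS)`` it is replaced by ``RESTART`` plus a deterministic
    machine-epsilon jitter taken from a counter, so the stream stays chaotic
    while remaining a pure function of its starting value.
    """
    if not (0.0 < value < 1.0):
        raise ValueError(f"tent state must lie strictly inside (0, 1), got {value!r}")
    if value <= TENT_BREAK:
        nxt = value / TENT_BREAK
    else:
        nxt = (1.0 - value) / (1.0 - TENT_BREAK)
    if not (EPS < nxt < 1.0 - EPS):
        bump = 0 if _counter is None else _counter[0]
        if _counter is not None:
            _counter[0] += 1
        nxt = RESTART + (bump + 1) * np.finfo(float).eps
    return nxt


def tent_sequence(t0: float, n: int) -> np.ndarray:
    """The first ``n`` tent iterates starting from ``t0`` (t0 excluded)."""
    if n < 1:
        raise ValueError("sequence length must be at least 1")
    if not (0.0 < t0 < 1.0):
        raise ValueError(f"t0 must lie strictly inside (0, 1), got {t0!r}")
    out = np.empty(n)
    counter = [0]
    value = t0
    for i in range(n):
        value = tent_next(value, counter)
        out[i] = value
    return out


@dataclass
class TentStream:
    """A resumable tent-map stream.

    Consuming ``k`` values then ``m`` values yields the same numbers as
    consuming ``k + m`` in one call, so several population matrices can be
    carved deterministically out of one stream.
    """

    t0: float = 0.9
    _value: float = field(init=False)
    _counter: list = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.t0 < 1.0):
            raise ValueError(f"t0 must lie strictly inside (0, 1), got {self.t0!r}")
        self._value = self.t0
        self._counter = [0]

    def take(self, n: int) -> np.ndarray:
        out = np.empty(n)
        for i in range(n):
            self._value = tent_next(self._value, self._counter)
            out[i] = self._value
        return out


def init_population(
    count: int, bounds: Bounds, t0: float = 0.9, stream: TentStream | None = None
) -> np.ndarray:
    """Chaos-initialized position matrix of shape ``(count, bounds.dim)``.

    Entries are consumed row-major (individual-by-individual,
    dimension-by-dimension) from ``stream`` if given, else from a fresh
    stream started at ``t0``; each tent value is mapped affinely into the
    box, so every position respects the bounds exactly.
    """
    if count < 1:
        raise ValueError("population count must be at least 1")
    if stream is None:
        stream = TentStream(t0)
    d = bounds.dim
    ts = stream.take(count * d).reshape(count, d)
    return ts * (bounds.upper - bounds.lower) + bounds.lower
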