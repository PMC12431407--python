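"""Mixed hyperparameter + feature-mask search space.

A candidate position is a 52-vector: four XGBoost hyperparameter
dimensions (n_estimators, learning_rate, max_depth, min_child_weight)
followed by 48 continuous mask dimensions in [0, 1].  Optimizers move
candidates continuously; decoding rounds and clamps the integer
dimensions and thresholds each mask dimension at 0.5.  An all-below-
threshold mask is repaired by selecting the single largest mask
dimension (ties broken toward the lowest index), so every decoded
configuration is trainable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import N_FEATURES

logger = logging.getLogger(__name__)

N_HYPERPARAMS = 4
MASK_THRESHOLD = 0.5


@dataclass
class BoxSpace:
    """A plain box-bounded continuous space (used by optimizer tests
    and benchmark functions)."""

    lower_bounds: np.ndarray
    upper_bounds: np.ndarray

    def __post_init__(self) -> None:
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        if self.lower_bounds.shape != self.upper_bounds.shape:
            raise ValueError("bound vectors must share a shape")
        if np.any(self.lower_bounds > self.upper_bounds):
            raise ValueError("every dimension needs lower <= upper")

    @classmethod
    def cube(cls, n_dim: int, low: float, high: float) -> "BoxSpace":
        return cls(np.full(n_dim, low), np.full(n_dim, high))

    @property
    def n_dim(self) -> int:
        return self.lower_bounds.size

    @property
    def lower(self) -> np.ndarray:
        return self.lower_bounds

    @property
    def upper(self) -> np.ndarray:
        return self.upper_bounds


@dataclass
class SearchSpace:
    """Box bounds for the 52-dimensional wrapper search."""

    n_estimators_bounds: tuple[int, int] = (100, 300)
    learning_rate_bounds: tuple[float, float] = (0.001, 0.2)
    max_depth_bounds: tuple[int, int] = (3, 7)
    min_child_weight_bounds: tuple[int, int] = (1, 10)
    n_mask: int = N_FEATURES

    def __post_init__(self) -> None:
        lower, upper = self.lower, self.upper
        if np.any(lower >= upper):
            raise ValueError("every dimension needs lower < upper")

    @property
    def n_dim(self) -> int:
        return N_HYPERPARAMS + self.n_mask

    @property
    def lower(self) -> np.ndarray:
        return np.concatenate([
            [self.n_estimators_bounds[0], self.learning_rate_bounds[0],
             self.max_depth_bounds[0], self.min_child_weight_bounds[0]],
            np.zeros(self.n_mask),
        ])

    @property
    def upper(self) -> np.ndarray:
        return np.concatenate([
            [self.n_estimators_bounds[1], self.learning_rate_bounds[1],
             self.max_depth_bounds[1], self.min_child_weight_bounds[1]],
            np.ones(self.n_mask),
        ])


@dataclass
class Candidate:
    """A position in the search space with (optionally) its fitness."""

    position: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass(frozen=True)
class DecodedConfig:
    """A trainable classifier configuration decoded from a position."""

    n_estimators: int
    learning_rate: float
    max_depth: int
    min_child_weight: int
    mask: tuple[bool, ...]

    @property
    def selected_indices(self) -> list[int]:
        return [i for i, m in enumerate(self.mask) if m]


def init_position(space: SearchSpace, rng: np.random.Generator) -> Candidate:
    """Uniform draw within the box (Y = Ymin + rand * (Ymax - Ymin))."""
    lower, upper = space.lower, space.upper
    return Candidate(position=lower + rng.random(space.n_dim) * (upper - lower))


def clamp(position: np.ndarray, space: SearchSpace,
          rng: np.random.Generator | None = None) -> np.ndarray:
    """Project elementwise onto the box; idempotent.

    Non-finite coordinates are replaced by fresh uniform draws (with a
    logged warning) so optimizer arithmetic can never poison the
    population.
    """
    position = np.asarray(position, dtype=float).copy()
    bad = ~np.isfinite(position)
    if np.any(bad):
        logger.warning("replacing %d non-finite coordinate(s)", int(bad.sum()))
        if rng is None:
            rng = np.random.default_rng(0)
        lower, upper = space.lower, space.upper
        position[bad] = lower[bad] + rng.random(int(bad.sum())) * (upper - lower)[bad]
    return np.minimum(np.maximum(position, space.lower), space.upper)


def decode(candidate: Candidate | np.ndarray, space: SearchSpace) -> DecodedConfig:
    """Decode a position into a trainable configuration (total function)."""
    position = candidate.position if isinstance(candidate, Candidate) else np.asarray(candidate, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position must be finite; clamp first")
    p = clamp(position, space)

    def _int(value: float, bounds: tuple[int, int]) -> int:
        return int(np.clip(np.rint(value), bounds[0], bounds[1]))

    mask_vals = p[N_HYPERPARAMS:]
    mask = mask_vals >= MASK_THRESHOLD
    if not mask.any():
        mask[int(np.argmax(mask_vals))] = True  # repair: keep best single dim
    return DecodedConfig(
        n_estimators=_int(p[0], space.n_estimators_bounds),
        learning_rate=float(np.clip(p[1], *space.learning_rate_bounds)),
        max_depth=_int(p[2], space.max_depth_bounds),
        min_child_weight=_int(p[3], space.min_child_weight_bounds),
        mask=tuple(bool(b) for b in mask),
    )
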