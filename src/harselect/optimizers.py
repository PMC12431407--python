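"""Golden Jackal Optimization and War Strategy Optimization.

Both are population metaheuristics over a bounded continuous space,
implemented here as maximizers with a shared driver and convergence
history.

GJO models paired jackal hunting: the best (male) and second-best
(female) positions steer every other member (the prey).  A prey-energy
term E = c1*(1 - t/T)*(2r - 1) decays over iterations; |E| >= 1 keeps
the search in exploration (wide moves around the leaders, perturbed by
Levy-flight steps), |E| < 1 switches to exploitation (encircling).  The
candidate for the next iteration is the mean of the male- and
female-driven moves.

WARSO models army manoeuvres: soldiers move either in attack (toward a
blend of the commander and king) or defense (toward the king with a
random soldier as reference) formation, accept a move only when fitness
does not degrade, accumulate rank on success, and decay a per-soldier
step weight with rank.  Each iteration the single weakest soldier is
relocated -- by default pulled between the army median and the king
("retraining"); uniform random replacement is available as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .space import Candidate, SearchSpace, clamp, init_position

logger = logging.getLogger(__name__)


@dataclass
class OptimizationResult:
    """Best solution, its fitness, and the running-best trajectory."""

    best_position: np.ndarray
    best_fitness: float
    trajectory: list[float]
    n_evaluations: int


def levy_flight(dim: int, beta: float, scale: float,
                rng: np.random.Generator) -> np.ndarray:
    """Mantegna heavy-tailed step vector.

    u ~ N(0, sigma_u^2), v ~ N(0, 1), step = scale * u / |v|^(1/beta),
    with sigma_u the standard Mantegna scale for the given beta.
    """
    if not 1.0 < beta <= 2.0:
        raise ValueError("beta must lie in (1, 2]")
    sigma_u = (
        math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
        / (math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
    ) ** (1.0 / beta)
    u = rng.normal(0.0, sigma_u, size=dim)
    v = rng.normal(0.0, 1.0, size=dim)
    return scale * u / np.abs(v) ** (1.0 / beta)


def _evaluate(objective, position: np.ndarray) -> float:
    """Objective wrapper: non-finite fitness discards the candidate."""
    value = float(objective(position))
    if not math.isfinite(value):
        logger.warning("objective returned non-finite fitness; discarding candidate")
        return -math.inf
    return value


# ---------------------------------------------------------------------------
# Golden Jackal Optimization


@dataclass
class GJOState:
    population: list[Candidate]
    space: SearchSpace
    rng: np.random.Generator
    max_iter: int
    t: int = 0
    c1: float = 1.5
    levy_beta: float = 1.5
    levy_scale: float = 0.01
    use_abs: bool = True
    male: Candidate = None
    female: Candidate = None
    n_evaluations: int = 0
    n_explore: int = 0
    n_exploit: int = 0

    def __post_init__(self) -> None:
        if self.male is None or self.female is None:
            self.rank_leaders()

    def rank_leaders(self) -> None:
        """Male = best, female = second-best of the current population."""
        order = sorted(self.population, key=lambda c: c.fitness, reverse=True)
        self.male = Candidate(order[0].position.copy(), order[0].fitness)
        second = order[1] if len(order) > 1 else order[0]
        self.female = Candidate(second.position.copy(), second.fitness)


def gjo_step(state: GJOState, objective) -> GJOState:
    """One GJO iteration (in place; returns the state for chaining)."""
    if state.t >= state.max_iter:
        raise ValueError("iteration budget exhausted")
    e1 = state.c1 * (1.0 - state.t / state.max_iter)  # prey energy envelope
    dim = state.space.n_dim
    ym = state.male.position
    yfm = state.female.position
    for prey in state.population:
        e0 = 2.0 * state.rng.random() - 1.0
        e = e1 * e0
        rl = levy_flight(dim, state.levy_beta, state.levy_scale, state.rng)
        if abs(e) >= 1.0:  # exploration: leaders back off from the prey
            state.n_explore += 1
            d1 = ym - rl * prey.position
            d2 = yfm - rl * prey.position
        else:  # exploitation: leaders encircle the prey
            state.n_exploit += 1
            d1 = rl * ym - prey.position
            d2 = rl * yfm - prey.position
        if state.use_abs:
            d1, d2 = np.abs(d1), np.abs(d2)
        y1 = ym - e * d1
        y2 = yfm - e * d2
        new_pos = clamp((y1 + y2) / 2.0, state.space, state.rng)
        new_fit = _evaluate(objective, new_pos)
        state.n_evaluations += 1
        if new_fit > prey.fitness:
            prey.position = new_pos
            prey.fitness = new_fit
    state.rank_leaders()
    state.t += 1
    return state


# ---------------------------------------------------------------------------
# War Strategy Optimization


@dataclass
class WARSOState:
    population: list[Candidate]
    space: SearchSpace
    rng: np.random.Generator
    max_iter: int
    alpha: float = 0.5
    attack_probability: float = 0.5
    weak_relocation: str = "median"
    ranks: np.ndarray = None
    weights: np.ndarray = None
    king: Candidate = None
    commander: Candidate = None
    n_evaluations: int = 0

    def __post_init__(self) -> None:
        n = len(self.population)
        if self.ranks is None:
            self.ranks = np.zeros(n, dtype=int)
        if self.weights is None:
            self.weights = np.ones(n, dtype=float)
        if self.weak_relocation not in ("median", "random"):
            raise ValueError("weak_relocation must be 'median' or 'random'")
        if self.king is None or self.commander is None:
            self.rank_leaders()

    def rank_leaders(self) -> None:
        order = sorted(self.population, key=lambda c: c.fitness, reverse=True)
        self.king = Candidate(order[0].position.copy(), order[0].fitness)
        second = order[1] if len(order) > 1 else order[0]
        self.commander = Candidate(second.position.copy(), second.fitness)


def warso_step(state: WARSOState, objective) -> WARSOState:
    """One WARSO iteration (in place; returns the state for chaining)."""
    rng = state.rng
    king = state.king.position
    commander = state.commander.position
    n = len(state.population)
    for i, soldier in enumerate(state.population):
        rho = rng.random()
        r = rng.random()
        w = state.weights[i]
        if rng.random() < state.attack_probability:
            # attack formation: advance on the king-commander axis
            new_pos = (
                soldier.position
                + 2.0 * rho * (commander - king)
                + r * (w * king - soldier.position)
            )
        else:
            # defense formation: shield the king, cohere with the commander
            reference = state.population[rng.integers(n)].position
            new_pos = (
                soldier.position
                + 2.0 * rho * (king - reference)
                + r * w * (commander - soldier.position)
            )
        new_pos = clamp(new_pos, state.space, rng)
        new_fit = _evaluate(objective, new_pos)
        state.n_evaluations += 1
        if new_fit >= soldier.fitness:  # accept only non-degrading moves
            soldier.position = new_pos
            soldier.fitness = new_fit
            state.ranks[i] += 1
            decay = max(0.0, 1.0 - state.ranks[i] / state.max_iter)
            state.weights[i] *= decay ** state.alpha
    # relocate the single weakest soldier
    worst = int(np.argmin([c.fitness for c in state.population]))
    if state.weak_relocation == "median":
        median = np.median(
            np.vstack([c.position for c in state.population]), axis=0
        )
        r_g = rng.normal()
        new_pos = -(1.0 - r_g) * (state.population[worst].position - median) + king
    else:
        lower, upper = state.space.lower, state.space.upper
        new_pos = lower + rng.random(state.space.n_dim) * (upper - lower)
    new_pos = clamp(new_pos, state.space, rng)
    state.population[worst].position = new_pos
    state.population[worst].fitness = _evaluate(objective, new_pos)
    state.n_evaluations += 1
    state.rank_leaders()
    return state


# ---------------------------------------------------------------------------
# Shared driver

METHODS = ("gjo", "warso")


def optimize(
    method: str,
    objective,
    space: SearchSpace,
    population: int = 30,
    epochs: int = 50,
    seed: int = 0,
    **params,
) -> OptimizationResult:
    """Run a full optimization and return the global best.

    ``objective`` maps a position vector to a real fitness (maximized).
    Deterministic given ``seed``.  Extra keyword arguments are forwarded
    to the optimizer state (c1, levy_beta, levy_scale for GJO; alpha,
    attack_probability, weak_relocation for WARSO).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if population < 2:
        raise ValueError("population must be >= 2")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    rng = np.random.default_rng(seed)
    pop = [init_position(space, rng) for _ in range(population)]
    for cand in pop:
        cand.fitness = _evaluate(objective, cand.position)
    n_init_evals = population

    if method == "gjo":
        state = GJOState(population=pop, space=space, rng=rng,
                         max_iter=epochs, **params)
        step = gjo_step
    else:
        state = WARSOState(population=pop, space=space, rng=rng,
                           max_iter=epochs, **params)
        step = warso_step

    best = max(pop, key=lambda c: c.fitness)
    best_pos, best_fit = best.position.copy(), best.fitness
    trajectory: list[float] = []
    for _ in range(epochs):
        step(state, objective)
        it_best = max(state.population, key=lambda c: c.fitness)
        if it_best.fitness > best_fit:
            best_pos, best_fit = it_best.position.copy(), it_best.fitness
        trajectory.append(best_fit)
    return OptimizationResult(
        best_position=best_pos,
        best_fitness=best_fit,
        trajectory=trajectory,
        n_evaluations=n_init_evals + state.n_evaluations,
    )
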