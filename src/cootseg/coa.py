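"""Coot Optimization Algorithm (COA): a population metaheuristic over box bounds.

The population imitates a coot flock on water: most birds are *followers*
that either wander towards a random point of the box, move in chain towards
the previous bird, or track an assigned *leader*; the few leaders themselves
move around the best position found so far (gBest). The movement amplitudes
A = 1 - t/IterMax and B = 2 - t/IterMax shrink linearly over iterations, so
the search contracts from exploration to exploitation. gBest is elitist: it
only ever improves. All randomness flows from a single seeded generator with
a fixed draw order, so runs are fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from .exceptions import ArgumentError, DomainError

__all__ = ["CoaParams", "CootState", "CoaResult", "init_population", "coa_minimize", "assign_leader"]


@dataclass(frozen=True)
class CoaParams:
    """Population size N, leader count NL, leader-branch probability P,
    iteration budget, per-dimension (LB, UB) bounds, and RNG seed."""

    n_coots: int = 30
    n_leaders: Optional[int] = None  # default ceil(0.1 * N)
    p: float = 0.5
    iter_max: int = 50
    bounds: Tuple[float, float] = (-1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        nl = self.resolved_n_leaders
        if not (1 <= nl < self.n_coots):
            raise ArgumentError(f"require 1 <= NL < N, got NL={nl}, N={self.n_coots}")
        if not (0.0 <= self.p <= 1.0):
            raise ArgumentError("P must lie in [0, 1]")
        if self.iter_max < 0:
            raise ArgumentError("iter_max must be >= 0")
        lb, ub = self.bounds_arrays(1)
        if np.any(lb >= ub):
            raise ArgumentError("require LB < UB per dimension")

    @property
    def resolved_n_leaders(self) -> int:
        return self.n_leaders if self.n_leaders is not None else math.ceil(0.1 * self.n_coots)

    def bounds_arrays(self, dim: int) -> Tuple[np.ndarray, np.ndarray]:
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim == 1:  # single (LB, UB) shared across dimensions
            lb = np.full(dim, b[0])
            ub = np.full(dim, b[1])
        else:
            if b.shape[0] != dim:
                raise DomainError(f"bounds rows ({b.shape[0]}) must match dim ({dim})")
            lb, ub = b[:, 0].copy(), b[:, 1].copy()
        return lb, ub


@dataclass
class CootState:
    """Follower and leader positions/fitnesses plus the elitist global best."""

    positions: np.ndarray
    fitnesses: np.ndarray
    leader_positions: np.ndarray
    leader_fitnesses: np.ndarray
    gbest: np.ndarray
    gbest_fitness: float
    history: List[float] = field(default_factory=list)
    n_evaluations: int = 0


@dataclass
class CoaResult:
    gbest: np.ndarray
    gbest_fitness: float
    history: np.ndarray
    n_evaluations: int


def assign_leader(i: int, n_leaders: int) -> int:
    """1-based leader index of follower i: Lind = 1 + (i MOD NL)."""
    if n_leaders < 1:
        raise ArgumentError("n_leaders must be >= 1")
    return 1 + (i % n_leaders)


def _safe_fitness(fitness: Callable, x: np.ndarray) -> float:
    v = float(fitness(x))
    return v if np.isfinite(v) else np.inf


def init_population(params: CoaParams, dim: int, fitness: Callable, rng=None) -> CootState:
    """Uniform positions on [LB, UB]^dim; NL random members become leaders."""
    if dim < 1:
        raise ArgumentError("dim must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    lb, ub = params.bounds_arrays(dim)
    n, nl = params.n_coots, params.resolved_n_leaders
    pos = rng.random((n, dim)) * (ub - lb) + lb
    leader_rows = rng.choice(n, size=nl, replace=False)
    is_leader = np.zeros(n, dtype=bool)
    is_leader[leader_rows] = True
    fit = np.array([_safe_fitness(fitness, x) for x in pos])
    best = int(np.argmin(fit))
    state = CootState(
        positions=pos[~is_leader].copy(),
        fitnesses=fit[~is_leader].copy(),
        leader_positions=pos[is_leader].copy(),
        leader_fitnesses=fit[is_leader].copy(),
        gbest=pos[best].copy(),
        gbest_fitness=float(fit[best]),
        n_evaluations=n,
    )
    return state


def coa_minimize(fitness: Callable, params: CoaParams, dim: int) -> CoaResult:
    """Minimize a black-box fitness over the box with the coot flock rules.

    Per iteration: each follower tracks its assigned leader (prob 0.5), else
    moves in chain with its predecessor (prob 0.5, never the first follower)
    or wanders towards a random point of the box; followers swap roles with
    their leader on improvement. Leaders then move around gBest; gBest is
    updated elitistically. Positions are clamped to the bounds after every
    move.
    """
    rng = np.random.default_rng(params.seed)
    state = init_population(params, dim, fitness, rng)
    lb, ub = params.bounds_arrays(dim)
    nl = params.resolved_n_leaders
    n_followers = state.positions.shape[0]
    iter_max = params.iter_max
    state.history.append(state.gbest_fitness)

    for t in range(1, iter_max + 1):
        a = 1.0 - t / iter_max
        b = 2.0 - t / iter_max
        vector_draws = rng.random() < params.p  # R, R1, R3 vectors vs scalars

        def _draw(low, high):
            if vector_draws:
                return rng.random(dim) * (high - low) + low
            return float(rng.random() * (high - low) + low)

        for i in range(n_followers):
            k = assign_leader(i + 1, nl) - 1
            if rng.random() < 0.5:  # track the assigned leader
                leader = state.leader_positions[k]
                r1 = _draw(0.0, 1.0)
                rr = _draw(-1.0, 1.0)
                state.positions[i] = leader + 2.0 * r1 * np.cos(2.0 * np.pi * rr) * (
                    leader - state.positions[i]
                )
            elif rng.random() < 0.5 and i + 1 != 1:  # chain with the previous coot
                state.positions[i] = 0.5 * (state.positions[i - 1] + state.positions[i])
            else:  # random wandering towards a point of the box
                target = rng.random(dim) * (ub - lb) + lb
                rn2 = rng.random()
                state.positions[i] = state.positions[i] + a * rn2 * (target - state.positions[i])
            np.clip(state.positions[i], lb, ub, out=state.positions[i])
            fi = _safe_fitness(fitness, state.positions[i])
            state.n_evaluations += 1
            state.fitnesses[i] = fi
            if fi < state.leader_fitnesses[k]:  # swap follower with its leader
                state.positions[i], state.leader_positions[k] = (
                    state.leader_positions[k].copy(),
                    state.positions[i].copy(),
                )
                state.fitnesses[i], state.leader_fitnesses[k] = (
                    state.leader_fitnesses[k],
                    fi,
                )

        for k in range(nl):
            r4 = rng.random()
            if r4 < params.p:
                r3 = rng.random(dim)
                rr = rng.random(dim) * 2.0 - 1.0
            else:
                r3 = float(rng.random())
                rr = float(rng.random() * 2.0 - 1.0)
            newpos = b * r3 * np.cos(2.0 * np.pi * rr) * (
                state.gbest - state.leader_positions[k]
            ) + state.gbest
            newpos = np.clip(newpos, lb, ub)
            fk = _safe_fitness(fitness, newpos)
            state.n_evaluations += 1
            if fk < state.leader_fitnesses[k]:
                state.leader_positions[k] = newpos
                state.leader_fitnesses[k] = fk
            if fk < state.gbest_fitness:
                state.gbest = newpos.copy()
                state.gbest_fitness = float(fk)
        # elitist gBest also tracks follower improvements
        best_follower = int(np.argmin(state.fitnesses)) if n_followers else 0
        if n_followers and state.fitnesses[best_follower] < state.gbest_fitness:
            state.gbest = state.positions[best_follower].copy()
            state.gbest_fitness = float(state.fitnesses[best_follower])
        best_leader = int(np.argmin(state.leader_fitnesses))
        if state.leader_fitnesses[best_leader] < state.gbest_fitness:
            state.gbest = state.leader_positions[best_leader].copy()
            state.gbest_fitness = float(state.leader_fitnesses[best_leader])
        state.history.append(state.gbest_fitness)

    return CoaResult(
        gbest=state.gbest,
        gbest_fitness=state.gbest_fitness,
        history=np.asarray(state.history),
        n_evaluations=state.n_evaluations,
    )
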