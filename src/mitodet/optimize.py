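"""Swarm metaheuristic core: jellyfish-search and walrus-optimization moves.

Both optimizers operate on a bounded continuous search space with greedy
acceptance and are composed by the hybrid feature selector. The core is a
*minimizer*; maximization problems wrap their objective (the selector
minimizes ``1 - F1``).

Jellyfish search alternates between an ocean-current move toward the swarm
best and intra-swarm passive/active moves, gated by a stochastic time
control function that decays over iterations. The walrus algorithm cycles a
feeding (exploration) phase, a migration phase toward/away from random
partners, and an escape phase sampling a local neighborhood that shrinks
with the iteration count.

Conventions adopted where the published recurrences are ambiguous are
documented inline and in the methods note: the chaotic initializer is the
standard logistic map seeded at ``q0``; the out-of-bounds rule wraps a
coordinate past one limit to the opposite limit; walrus moves clamp to the
bounds; non-finite objective values are treated as +inf and never accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "SearchBounds",
    "JSOParams",
    "SwarmState",
    "chaotic_init",
    "time_control",
    "jso_step",
    "waoa_feed",
    "waoa_migrate",
    "waoa_escape",
    "hybrid_minimize",
]

#: logistic-map fixed/periodic points excluded as chaotic seeds
_LOGISTIC_EXCLUDED = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class SearchBounds:
    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self) -> None:
        self.lb = np.atleast_1d(np.asarray(self.lb, dtype=float))
        self.ub = np.atleast_1d(np.asarray(self.ub, dtype=float))
        if self.lb.shape != self.ub.shape or self.lb.ndim != 1:
            raise ValueError("lb and ub must be 1-D with equal shape")
        if not np.all(self.lb < self.ub):
            raise ValueError("require lb < ub elementwise")

    @property
    def d(self) -> int:
        return self.lb.size

    @property
    def span(self) -> np.ndarray:
        return self.ub - self.lb


@dataclass
class JSOParams:
    """Jellyfish-search constants: gate ``kappa`` (0.5), chaotic seed ``q0``,
    and the factor ``gamma_current`` multiplying the crowd term in the
    ocean-current move."""

    kappa: float = 0.5
    q0: float = 0.37
    gamma_current: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 < self.kappa < 1.0):
            raise ValueError("kappa must be in (0, 1)")
        if not (0.0 < self.q0 < 1.0) or any(
            abs(self.q0 - x) < 1e-12 for x in _LOGISTIC_EXCLUDED
        ):
            raise ValueError(
                f"q0 must be in (0,1) excluding {_LOGISTIC_EXCLUDED} "
                "(degenerate logistic orbits)"
            )


@dataclass
class SwarmState:
    """Agent positions, fitnesses, and incumbent best of a swarm."""

    positions: np.ndarray
    fitnesses: np.ndarray
    bounds: SearchBounds
    best_position: np.ndarray
    best_fitness: float
    t: int = 0
    t_max: int = 100
    n_rejected_moves: int = field(default=0)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def from_positions(cls, positions, bounds, objective, t_max=100) -> "SwarmState":
        positions = np.asarray(positions, dtype=float)
        if positions.shape[0] < 2:
            raise ValueError("swarm needs n >= 2 agents")
        fit = np.array([_safe_eval(objective, p) for p in positions])
        best = int(np.argmin(fit))
        return cls(
            positions=positions,
            fitnesses=fit,
            bounds=bounds,
            best_position=positions[best].copy(),
            best_fitness=float(fit[best]),
            t_max=t_max,
        )


def _safe_eval(objective: Callable, x: np.ndarray) -> float:
    v = objective(x)
    if v is None or not np.isfinite(v):
        return np.inf
    return float(v)


def _greedy_accept(state: SwarmState, i: int, candidate: np.ndarray,
                   objective: Callable) -> None:
    """Evaluate candidate; keep it iff the objective improves."""
    f = _safe_eval(objective, candidate)
    if f < state.fitnesses[i]:
        state.positions[i] = candidate
        state.fitnesses[i] = f
        if f < state.best_fitness:
            state.best_fitness = f
            state.best_position = candidate.copy()
    elif not np.isfinite(f):
        state.n_rejected_moves += 1


# ---------------------------------------------------------------------------
# Jellyfish search
# ---------------------------------------------------------------------------

def chaotic_init(n: int, bounds: SearchBounds, params: JSOParams) -> np.ndarray:
    """Logistic-map chaotic initialization.

    Iterates ``y <- 4 y (1 - y)`` from ``y0 = q0``, assigning successive
    iterates to agents/dimensions in row-major order, then maps [0, 1]
    affinely onto [lb, ub].
    """
    if n < 2:
        raise ValueError("need n >= 2 agents")
    d = bounds.d
    y = params.q0
    vals = np.empty(n * d)
    for k in range(n * d):
        y = 4.0 * y * (1.0 - y)
        vals[k] = y
    unit = vals.reshape(n, d)
    return bounds.lb + unit * bounds.span


def time_control(t: int, t_max: int, rng: np.random.Generator) -> float:
    """Time control function: ``|(1 - t/t_max) * (2 rand - 1)|`` in [0, 1]."""
    if t_max < 1 or not (0 <= t <= t_max):
        raise ValueError("require 0 <= t <= t_max, t_max >= 1")
    return float(abs((1.0 - t / t_max) * (2.0 * rng.uniform() - 1.0)))


def _wrap_bounds(x: np.ndarray, bounds: SearchBounds) -> np.ndarray:
    """Opposite-limit wrap: a coordinate past one bound re-enters from the
    other side; a residual overshoot is clipped."""
    x = x.copy()
    over = x > bounds.ub
    under = x < bounds.lb
    x[over] = (x[over] - bounds.ub[over]) + bounds.lb[over]
    x[under] = (x[under] - bounds.lb[under]) + bounds.ub[under]
    return np.clip(x, bounds.lb, bounds.ub)


def jso_step(
    state: SwarmState,
    params: JSOParams,
    objective: Callable,
    rng: np.random.Generator,
) -> SwarmState:
    """One jellyfish-search iteration over the whole swarm (in place).

    Per agent: draw one TCF value; if ``TCF >= kappa``, follow the ocean
    current ``Y' = Y + R * (Y* - gamma_current * R' * mean(Y))`` with fresh
    per-dimension draws; otherwise move within the swarm — passive (type A,
    a small bounded random walk) when a uniform draw exceeds ``1 - TCF``,
    else active (type B) toward a fitter random partner / away from a less
    fit one. Out-of-bounds coordinates wrap to the opposite limit; moves are
    accepted greedily.
    """
    d = state.bounds.d
    mean_pos = state.positions.mean(axis=0)
    for i in range(state.n):
        tcf = time_control(state.t, state.t_max, rng)
        y = state.positions[i]
        if tcf >= params.kappa:
            r1 = rng.uniform(size=d)
            r2 = rng.uniform(size=d)
            cand = y + r1 * (state.best_position - params.gamma_current * r2 * mean_pos)
        elif rng.uniform() > 1.0 - tcf:
            # type A: passive drift around the current location
            cand = y + rng.uniform(size=d) * 0.1 * state.bounds.span
        else:
            # type B: move relative to a random partner by fitness comparison
            j = _other_index(rng, state.n, i)
            r = rng.uniform(size=d)
            if state.fitnesses[i] >= state.fitnesses[j]:
                cand = y + r * (state.positions[j] - y)
            else:
                cand = y + r * (y - state.positions[j])
        cand = _wrap_bounds(cand, state.bounds)
        _greedy_accept(state, i, cand, objective)
    return state


def _other_index(rng: np.random.Generator, n: int, i: int) -> int:
    j = int(rng.integers(n - 1))
    return j if j < i else j + 1


# ---------------------------------------------------------------------------
# Walrus optimization phases
# ---------------------------------------------------------------------------

def waoa_feed(
    state: SwarmState, objective: Callable, rng: np.random.Generator
) -> SwarmState:
    """Feeding (exploration) phase: move toward the strongest walrus,
    ``Z' = Z + rand * (Wst - RI * Z)`` with per-dimension rand ~ U(0,1) and
    RI in {1, 2}; clamp to bounds; greedy acceptance."""
    d = state.bounds.d
    for i in range(state.n):
        z = state.positions[i]
        ri = rng.integers(1, 3, size=d)
        r = rng.uniform(size=d)
        cand = z + (state.best_position - ri * z) * r
        cand = np.clip(cand, state.bounds.lb, state.bounds.ub)
        _greedy_accept(state, i, cand, objective)
    return state


def waoa_migrate(
    state: SwarmState, objective: Callable, rng: np.random.Generator
) -> SwarmState:
    """Migration phase: move toward a fitter random partner, away from a
    less fit one; clamp; greedy acceptance."""
    if state.n < 2:
        raise ValueError("migration needs n >= 2")
    d = state.bounds.d
    for i in range(state.n):
        z = state.positions[i]
        l = _other_index(rng, state.n, i)
        ri = rng.integers(1, 3, size=d)
        r = rng.uniform(size=d)
        if state.fitnesses[l] < state.fitnesses[i]:
            cand = z + (state.positions[l] - ri * z) * r
        else:
            cand = z + (z - state.positions[l]) * r
        cand = np.clip(cand, state.bounds.lb, state.bounds.ub)
        _greedy_accept(state, i, cand, objective)
    return state


def waoa_escape(
    state: SwarmState,
    objective: Callable,
    rng: np.random.Generator,
    neighborhood_mode: str = "shrinking",
) -> SwarmState:
    """Escape/fight phase: sample a neighborhood around each walrus.

    ``Z' = Z + (LB_loc + (UB_loc - LB_loc) * rand)`` per dimension. In
    ``shrinking`` mode (default) the local bounds are the global bounds
    scaled by ``1/t``, so the perturbation contracts as iterations pass; in
    ``as_printed`` mode they equal the global bounds, which makes the phase
    a global random restart proposal (kept selectable because the published
    recurrence admits that literal reading). Greedy acceptance either way.
    """
    if neighborhood_mode not in ("shrinking", "as_printed"):
        raise ValueError(f"unknown neighborhood_mode {neighborhood_mode!r}")
    t = max(state.t, 1)
    if neighborhood_mode == "shrinking":
        # span scaled by 1/t, centered on zero offset (unbiased perturbation)
        half = state.bounds.span / (2.0 * t)
        lb_loc, ub_loc = -half, half
    else:
        lb_loc = state.bounds.lb
        ub_loc = state.bounds.ub
    d = state.bounds.d
    for i in range(state.n):
        r = rng.uniform(size=d)
        cand = state.positions[i] + (lb_loc + (ub_loc - lb_loc) * r)
        cand = np.clip(cand, state.bounds.lb, state.bounds.ub)
        _greedy_accept(state, i, cand, objective)
    return state


# ---------------------------------------------------------------------------
# Convenience driver
# ---------------------------------------------------------------------------

_WAOA_PHASES = (waoa_feed, waoa_migrate, waoa_escape)


def hybrid_minimize(
    objective: Callable,
    bounds: SearchBounds,
    n: int = 30,
    iterations: int = 200,
    seed: int = 0,
    params: Optional[JSOParams] = None,
    history_path=None,
):
    """Alternate one jellyfish step and one (cycling) walrus phase per
    iteration. Returns the final :class:`SwarmState` and the per-iteration
    best-fitness history (monotone non-increasing by greedy acceptance)."""
    params = params or JSOParams()
    rng = np.random.default_rng(seed)
    positions = chaotic_init(n, bounds, params)
    state = SwarmState.from_positions(positions, bounds, objective, t_max=iterations)
    history = []
    log = open(history_path, "w") if history_path else None
    try:
        for t in range(1, iterations + 1):
            state.t = t
            jso_step(state, params, objective, rng)
            _WAOA_PHASES[(t - 1) % 3](state, objective, rng)
            history.append(state.best_fitness)
            if log:
                log.write(json.dumps({
                    "iteration": t,
                    "best_fitness": state.best_fitness,
                    "mean_fitness": float(np.mean(state.fitnesses)),
                    "sd_fitness": float(np.std(state.fitnesses)),
                }) + "\n")
    finally:
        if log:
            log.close()
    return state, history
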