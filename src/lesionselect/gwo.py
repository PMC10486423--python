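"""Canonical continuous gray wolf optimizer (GWO).

GWO evolves a pack of candidate solutions ("wolves") in which the three
best-so-far solutions — alpha, beta, delta — pull every other wolf toward
themselves.  Each wolf x moves to the average of three leader-guided points

    x_k = leader_k − A_k · D_k,      D_k = |C_k · leader_k − x|,

with per-dimension coefficients A = 2·a·r1 − a and C = 2·r2 (r1, r2 uniform
on [0,1]) and a control scalar a decaying linearly from ``a_initial``
(default 2) to 0 over the run: large |A| favours exploration, small |A|
exploitation.  Leaders are replaced only by strict improvements, so the
best-so-far fitness trace is monotone.

The printed update rule in some descriptions wraps the leader displacement
in nested absolute values (x_k = |leader − |A·D||), which confines the
search to non-negative coordinates; pass ``literal_update=True`` to use that
variant for comparison.  The default is the canonical signed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "GWOConfig",
    "GWOState",
    "OptimizeResult",
    "init_pack",
    "coefficients",
    "encircle_distance",
    "leader_guided_position",
    "step",
    "optimize",
    "sphere",
    "rastrigin",
    "BENCHMARKS",
]

Sense = Literal["minimize", "maximize"]
Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class GWOConfig:
    """Run parameters for the optimizer.

    ``bounds`` is either one (lower, upper) pair applied to every dimension
    or a per-dimension sequence of pairs.  ``leader_count`` is fixed at 3
    (alpha, beta, delta).
    """

    n_wolves: int = 30
    n_iterations: int = 100
    bounds: tuple | Sequence[tuple[float, float]] = (0.0, 1.0)
    seed: int = 0
    a_initial: float = 2.0
    leader_count: int = 3

    def __post_init__(self) -> None:
        if self.n_wolves < 4:
            raise ValueError("n_wolves must be ≥ 4 (three leaders plus ≥ 1 omega wolf)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be ≥ 1")
        if self.leader_count != 3:
            raise ValueError("leader_count is fixed at 3")
        if self.a_initial <= 0:
            raise ValueError("a_initial must be positive")

    def bounds_array(self, dim: int) -> np.ndarray:
        """Per-dimension (lower, upper) as a (dim, 2) array."""
        b = np.asarray(self.bounds, dtype=np.float64)
        if b.shape == (2,):
            b = np.tile(b, (dim, 1))
        if b.shape != (dim, 2):
            raise ValueError(f"bounds shape {b.shape} incompatible with dim={dim}")
        if not (b[:, 0] < b[:, 1]).all():
            raise ValueError("each lower bound must be strictly below its upper bound")
        return b


@dataclass
class GWOState:
    """Mutable optimizer state: pack positions, leader triple, schedules."""

    config: GWOConfig
    positions: np.ndarray  # (n_wolves, dim)
    fitnesses: np.ndarray  # (n_wolves,), in the objective's own sense
    alpha: tuple[np.ndarray, float]
    beta: tuple[np.ndarray, float]
    delta: tuple[np.ndarray, float]
    iteration: int
    a: float
    sense: Sense
    bounds: np.ndarray  # (dim, 2)
    rng: np.random.Generator

    @property
    def dim(self) -> int:
        return int(self.positions.shape[1])

    @property
    def best_position(self) -> np.ndarray:
        return self.alpha[0]

    @property
    def best_fitness(self) -> float:
        return self.alpha[1]


@dataclass(frozen=True)
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness, length n_iterations + 1


def _better(f: float, g: float, sense: Sense) -> bool:
    return f < g if sense == "minimize" else f > g


def _evaluate(objective: Objective, positions: np.ndarray) -> np.ndarray:
    fits = np.empty(positions.shape[0], dtype=np.float64)
    for i, x in enumerate(positions):
        f = float(objective(x))
        if not np.isfinite(f):
            raise ValueError(f"objective returned non-finite value {f!r} for wolf {i}")
        fits[i] = f
    return fits


def _rank_leaders(
    positions: np.ndarray, fitnesses: np.ndarray, sense: Sense
) -> list[tuple[np.ndarray, float]]:
    order = np.argsort(fitnesses, kind="stable")
    if sense == "maximize":
        order = order[::-1]
    return [(positions[i].copy(), float(fitnesses[i])) for i in order[:3]]


def init_pack(
    config: GWOConfig, dim: int, objective: Objective, sense: Sense = "minimize"
) -> GWOState:
    """Seeded uniform initialization within bounds; leaders set to the three best."""
    bounds = config.bounds_array(dim)
    rng = np.random.default_rng(config.seed)
    span = bounds[:, 1] - bounds[:, 0]
    positions = bounds[:, 0] + rng.random((config.n_wolves, dim)) * span
    fitnesses = _evaluate(objective, positions)
    alpha, beta, delta = _rank_leaders(positions, fitnesses, sense)
    return GWOState(
        config=config,
        positions=positions,
        fitnesses=fitnesses,
        alpha=alpha,
        beta=beta,
        delta=delta,
        iteration=0,
        a=config.a_initial,
        sense=sense,
        bounds=bounds,
        rng=rng,
    )


def coefficients(
    a: float, dim: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Fresh per-dimension coefficient vectors A ∈ [−a, a] and C ∈ [0, 2]."""
    r1 = rng.random(dim)
    r2 = rng.random(dim)
    return 2.0 * a * r1 - a, 2.0 * r2


def encircle_distance(C: np.ndarray, prey: np.ndarray, wolf: np.ndarray) -> np.ndarray:
    """Componentwise encircling distance |C·prey − wolf| (non-negative)."""
    C, prey, wolf = (np.asarray(v, dtype=np.float64) for v in (C, prey, wolf))
    if not (C.shape == prey.shape == wolf.shape):
        raise ValueError(
            f"dimension mismatch: C{C.shape}, prey{prey.shape}, wolf{wolf.shape}"
        )
    return np.abs(C * prey - wolf)


def leader_guided_position(
    state: GWOState,
    wolf: np.ndarray,
    rng: np.random.Generator | None = None,
    literal_update: bool = False,
) -> np.ndarray:
    """Move one wolf to the mean of its three leader-guided points, clamped to bounds.

    Draws fresh (A, C) per leader.  With ``literal_update`` the nested
    absolute-value variant x_k = |leader − |A·D|| is used instead of the
    canonical signed displacement.
    """
    rng = state.rng if rng is None else rng
    wolf = np.asarray(wolf, dtype=np.float64)
    parts = []
    for leader_pos, _ in (state.alpha, state.beta, state.delta):
        A, C = coefficients(state.a, wolf.size, rng)
        D = encircle_distance(C, leader_pos, wolf)
        if literal_update:
            parts.append(np.abs(leader_pos - np.abs(A * D)))
        else:
            parts.append(leader_pos - A * D)
    new = (parts[0] + parts[1] + parts[2]) / 3.0
    return np.clip(new, state.bounds[:, 0], state.bounds[:, 1])


def _update_leaders(state: GWOState) -> None:
    # classic cascade: strict improvements only, preserving alpha ≥ beta ≥ delta
    for pos, fit in zip(state.positions, state.fitnesses):
        if _better(fit, state.alpha[1], state.sense):
            state.delta = state.beta
            state.beta = state.alpha
            state.alpha = (pos.copy(), float(fit))
        elif _better(fit, state.beta[1], state.sense):
            state.delta = state.beta
            state.beta = (pos.copy(), float(fit))
        elif _better(fit, state.delta[1], state.sense):
            state.delta = (pos.copy(), float(fit))


def step(state: GWOState, objective: Objective, literal_update: bool = False) -> GWOState:
    """One iteration: move every wolf, re-evaluate, refresh leaders and schedules."""
    new_positions = np.empty_like(state.positions)
    for i in range(state.positions.shape[0]):
        new_positions[i] = leader_guided_position(
            state, state.positions[i], literal_update=literal_update
        )
    state.positions = new_positions
    state.fitnesses = _evaluate(objective, new_positions)
    _update_leaders(state)
    state.iteration += 1
    T = state.config.n_iterations
    state.a = state.config.a_initial * (1.0 - min(state.iteration, T) / T)
    return state


def optimize(
    config: GWOConfig,
    dim: int,
    objective: Objective,
    sense: Sense = "minimize",
    literal_update: bool = False,
) -> OptimizeResult:
    """Run the full optimizer: init plus ``n_iterations`` steps.

    The returned trace holds the best-so-far fitness after initialization
    and after each step (length ``n_iterations + 1``).
    """
    state = init_pack(config, dim, objective, sense)
    trace = [state.best_fitness]
    for _ in range(config.n_iterations):
        step(state, objective, literal_update=literal_update)
        trace.append(state.best_fitness)
    return OptimizeResult(
        best_position=state.best_position.copy(),
        best_fitness=state.best_fitness,
        trace=np.asarray(trace),
    )


# ---------------------------------------------------------------------------
# analytic benchmark functions


def sphere(x: np.ndarray) -> float:
    """Σ x_i²; global minimum 0 at the origin."""
    x = np.asarray(x)
    return float(np.dot(x, x))


def rastrigin(x: np.ndarray) -> float:
    """10·d + Σ (x_i² − 10·cos 2πx_i); highly multimodal, minimum 0 at origin."""
    x = np.asarray(x)
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


BENCHMARKS: dict[str, tuple[Objective, tuple[float, float]]] = {
    "sphere": (sphere, (-5.12, 5.12)),
    "rastrigin": (rastrigin, (-5.12, 5.12)),
}
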