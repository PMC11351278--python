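"""Particle swarm optimization over fixed-size feature subsets.

Particles live in the continuous unit box [0, 1]^29; a position decodes
to a feature subset by taking the 10 largest components (ties to the
lower index), which keeps the velocity/position updates in their
standard continuous form while enforcing the subset size exactly.

Velocity update: v' = w*v + c1*r1*(Pbest - y) + c2*r2*(Gbest - y), with
per-component r1, r2 ~ U[0, 1], clamped to +/-v_max; position update:
y' = y + v', clamped to the box.  The defaults c1 = c2 = 1.4962 and
w = 0.7298 are the Clerc-Kennedy constriction-equivalent pair.  Fitness
is the across-participant mean of fold-mean MCC under within-subject CV
on the masked features.  Search stops when (i) the iteration cap is hit,
(ii) a fitness of 1 is reached, or (iii) the global best has not changed
for ``stall_limit`` consecutive iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .classification import CVConfig, run_within_subject_cv, stratified_folds

__all__ = [
    "PSOConfig",
    "SwarmState",
    "PSOResult",
    "init_swarm",
    "velocity_update",
    "position_update",
    "decode_mask",
    "make_cv_fitness",
    "run_pso",
    "select_features",
]


@dataclass(frozen=True)
class PSOConfig:
    n_particles: int = 20
    max_iterations: int = 100
    c1: float = 1.4962
    c2: float = 1.4962
    inertia_w: float = 0.7298
    subset_size: int = 10
    stall_limit: int = 10
    v_max: float = 0.5
    #: |change in gbest fitness| below this counts as "unchanged" for the stall rule
    stall_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.stall_limit < 1:
            raise ValueError("stall_limit must be >= 1")


@dataclass
class SwarmState:
    positions: np.ndarray  # (P, N) in [0, 1]
    velocities: np.ndarray  # (P, N), |v| <= v_max
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray  # (P,)
    gbest_position: np.ndarray
    gbest_fitness: float
    iteration: int = 0
    stall_counter: int = 0
    fitness_history: list[float] = field(default_factory=list)


@dataclass
class PSOResult:
    mask: np.ndarray  # sorted feature indices, len = subset_size
    gbest_fitness: float
    fitness_history: list[float]
    n_iterations: int
    stop_reason: str  # 'max_iterations' | 'fitness_reached' | 'stalled'
    gbest_position: np.ndarray


def decode_mask(position: np.ndarray, subset_size: int) -> np.ndarray:
    """Indices of the subset_size largest components, ties to the lower index.

    Returned sorted ascending; always exactly ``subset_size`` distinct
    indices.
    """
    pos = np.asarray(position, dtype=float)
    if len(pos) < subset_size:
        raise ValueError("position shorter than subset_size")
    order = np.argsort(-pos, kind="stable")  # stable: equal values keep index order
    return np.sort(order[:subset_size])


def init_swarm(
    dim: int,
    cfg: PSOConfig,
    rng: np.random.Generator,
    fitness_fn: Callable[[np.ndarray], float],
) -> SwarmState:
    """Uniform-random positions, zero velocities, pbest = start, gbest = best start."""
    if dim < cfg.subset_size:
        raise ValueError(f"search dimension {dim} smaller than subset_size {cfg.subset_size}")
    positions = rng.random((cfg.n_particles, dim))
    fitness = np.array([fitness_fn(decode_mask(p, cfg.subset_size)) for p in positions])
    best = int(np.argmax(fitness))
    return SwarmState(
        positions=positions,
        velocities=np.zeros_like(positions),
        pbest_positions=positions.copy(),
        pbest_fitness=fitness,
        gbest_position=positions[best].copy(),
        gbest_fitness=float(fitness[best]),
        fitness_history=[float(fitness[best])],
    )


def velocity_update(
    velocities: np.ndarray,
    positions: np.ndarray,
    pbest_positions: np.ndarray,
    gbest_position: np.ndarray,
    cfg: PSOConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inertia + cognitive + social velocity update, clamped to +/-v_max."""
    r1 = rng.random(positions.shape)
    r2 = rng.random(positions.shape)
    v = (
        cfg.inertia_w * velocities
        + cfg.c1 * r1 * (pbest_positions - positions)
        + cfg.c2 * r2 * (gbest_position - positions)
    )
    return np.clip(v, -cfg.v_max, cfg.v_max)


def position_update(positions: np.ndarray, velocities: np.ndarray) -> np.ndarray:
    """y' = y + v', clamped to the unit box."""
    return np.clip(positions + velocities, 0.0, 1.0)


def run_pso(
    fitness_fn: Callable[[np.ndarray], float],
    dim: int,
    cfg: PSOConfig = PSOConfig(),
    rng: np.random.Generator | None = None,
    cache: bool = True,
) -> PSOResult:
    """Maximize ``fitness_fn(mask)`` over fixed-size subsets of ``dim`` features.

    pbest/gbest update on strict improvement (ties keep the incumbent),
    so the recorded gbest fitness is non-decreasing.  Fitness values are
    cached per decoded mask by default (the fitness is deterministic for
    a fixed mask within one search).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    evaluate = fitness_fn
    if cache:
        memo: dict[tuple[int, ...], float] = {}

        def evaluate(mask: np.ndarray, _fn=fitness_fn) -> float:  # type: ignore[misc]
            key = tuple(int(i) for i in mask)
            if key not in memo:
                memo[key] = float(_fn(np.asarray(key)))
            return memo[key]

    state = init_swarm(dim, cfg, rng, evaluate)
    stop_reason = "max_iterations"
    if state.gbest_fitness >= 1.0 - 1e-12:
        stop_reason = "fitness_reached"
    else:
        for t in range(1, cfg.max_iterations + 1):
            state.velocities = velocity_update(
                state.velocities, state.positions, state.pbest_positions,
                state.gbest_position, cfg, rng,
            )
            state.positions = position_update(state.positions, state.velocities)
            prev_gbest = state.gbest_fitness
            for i in range(cfg.n_particles):
                f = evaluate(decode_mask(state.positions[i], cfg.subset_size))
                if f > state.pbest_fitness[i]:
                    state.pbest_fitness[i] = f
                    state.pbest_positions[i] = state.positions[i].copy()
                    if f > state.gbest_fitness:
                        state.gbest_fitness = float(f)
                        state.gbest_position = state.positions[i].copy()
            state.iteration = t
            state.fitness_history.append(state.gbest_fitness)
            if state.gbest_fitness >= 1.0 - 1e-12:
                stop_reason = "fitness_reached"
                break
            if abs(state.gbest_fitness - prev_gbest) < cfg.stall_tol:
                state.stall_counter += 1
            else:
                state.stall_counter = 0
            if state.stall_counter >= cfg.stall_limit:
                stop_reason = "stalled"
                break

    return PSOResult(
        mask=decode_mask(state.gbest_position, cfg.subset_size),
        gbest_fitness=state.gbest_fitness,
        fitness_history=state.fitness_history,
        n_iterations=state.iteration,
        stop_reason=stop_reason,
        gbest_position=state.gbest_position,
    )


def make_cv_fitness(
    cohort: Mapping[str, tuple[np.ndarray, np.ndarray]],
    cv_cfg: CVConfig,
    rng: np.random.Generator,
) -> Callable[[np.ndarray], float]:
    """Mean-MCC fitness over a cohort with fold splits frozen per search.

    One CV pass per participant per evaluation; every particle sees the
    same folds, so comparisons between masks are paired.  Note the folds
    used for fitness are the same CV folds later used for reporting --
    the selection signal is the CV test performance itself (a nested,
    leakage-free variant is available via :func:`select_features`).
    """
    pids = sorted(cohort.keys())
    frozen: dict[str, list[np.ndarray]] = {}
    seeds: dict[str, np.random.SeedSequence] = {}
    for p_idx, pid in enumerate(pids):
        _, y = cohort[pid]
        fold_seq = np.random.SeedSequence(entropy=int(rng.integers(2**31 - 1)), spawn_key=(p_idx,))
        frozen[pid] = stratified_folds(np.asarray(y).astype(int), cv_cfg.k_folds,
                                       np.random.default_rng(fold_seq))
        seeds[pid] = fold_seq

    def fitness(mask: np.ndarray) -> float:
        values = []
        for pid in pids:
            X, y = cohort[pid]
            _, fold_mean = run_within_subject_cv(
                np.asarray(X)[:, np.asarray(mask, dtype=int)], y, cv_cfg,
                seed_seq=seeds[pid], folds=frozen[pid],
            )
            values.append(fold_mean.mcc)
        return float(np.nanmean(values))

    return fitness


def select_features(
    cohort: Mapping[str, tuple[np.ndarray, np.ndarray]],
    n_features: int,
    pso_cfg: PSOConfig = PSOConfig(),
    cv_cfg: CVConfig = CVConfig(),
    nested: bool = False,
) -> PSOResult:
    """Run the PSO wrapper search for the best feature subset of a cohort.

    With ``nested=True`` the fitness is computed on an inner split of the
    training data only (selection never sees the reporting folds); the
    default mirrors the simpler scheme where CV test MCC itself is the
    fitness.
    """
    rng = np.random.default_rng(pso_cfg.seed)
    if nested:
        inner = {
            pid: _inner_half(cohort[pid], np.random.default_rng((pso_cfg.seed, 17, i)))
            for i, pid in enumerate(sorted(cohort.keys()))
        }
        fitness = make_cv_fitness(inner, cv_cfg, rng)
    else:
        fitness = make_cv_fitness(cohort, cv_cfg, rng)
    return run_pso(fitness, dim=n_features, cfg=pso_cfg, rng=rng)


def _inner_half(data: tuple[np.ndarray, np.ndarray], rng: np.random.Generator):
    """Stratified half of one participant's trials (nested-selection split)."""
    X, y = np.asarray(data[0]), np.asarray(data[1]).astype(int)
    keep: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        keep.extend(idx[: max(len(idx) // 2, 1)])
    keep_arr = np.sort(np.asarray(keep))
    return X[keep_arr], y[keep_arr]
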