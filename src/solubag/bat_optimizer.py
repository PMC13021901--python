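"""Bat-algorithm hyperparameter search.

The bat algorithm is a population metaheuristic inspired by echolocation:
each candidate ("bat") carries a position and velocity in the search box,
and every iteration draws a random frequency vector F ~ Uniform[0, f_max]^d
that pulls the bat toward the best position found so far:

    v_i(t+1) = v_i(t) + F_i(t) * (X_best - X_i(t))
    X_i(t+1) = v_i(t+1) + X_i(t)

Positions are clipped to the box after every move and an elitist archive
retains the best solution ever evaluated, so the best-fitness trace is
monotone non-increasing.  The classic loudness / pulse-rate dynamics and
the local random walk are deliberately omitted: the two update equations
above plus clipping and elitism are the whole algorithm.

Minimization is assumed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .base_models import RegressorConfig
from .ensemble import fit_bagged, predict_bagged

DimKind = Literal["integer", "continuous", "log-continuous"]

DEFAULT_F_MAX = 1.0
DEFAULT_N_BATS = 20
DEFAULT_N_ITERS = 50


@dataclass(frozen=True)
class Dimension:
    name: str
    kind: DimKind
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"dim {self.name!r}: lower must be < upper")
        if self.kind == "log-continuous" and self.lower <= 0:
            raise ValueError(f"dim {self.name!r}: log dims need lower > 0")


@dataclass(frozen=True)
class HyperparameterSpace:
    """Box-constrained mixed integer/continuous search domain.

    Internally the optimizer works on a continuous box; ``decode`` maps a
    raw position to usable values (integers round to nearest,
    log-continuous dims are searched on log10 scale).
    """

    dims: tuple[Dimension, ...]

    def __post_init__(self) -> None:
        if not self.dims:
            raise ValueError("empty search space")

    @property
    def n_dims(self) -> int:
        return len(self.dims)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array(
            [np.log10(d.lower) if d.kind == "log-continuous" else d.lower
             for d in self.dims]
        )
        hi = np.array(
            [np.log10(d.upper) if d.kind == "log-continuous" else d.upper
             for d in self.dims]
        )
        return lo, hi

    def decode(self, position: np.ndarray) -> dict[str, float | int]:
        lo, hi = self.bounds()
        pos = np.clip(position, lo, hi)
        out: dict[str, float | int] = {}
        for i, d in enumerate(self.dims):
            v = pos[i]
            if d.kind == "log-continuous":
                out[d.name] = float(10.0 ** v)
            elif d.kind == "integer":
                out[d.name] = int(np.clip(round(v), d.lower, d.upper))
            else:
                out[d.name] = float(v)
        return out


@dataclass
class BatState:
    position: np.ndarray
    velocity: np.ndarray
    frequency_vector: np.ndarray
    fitness: float


@dataclass
class BatPopulation:
    bats: list[BatState]
    best_position: np.ndarray
    best_fitness: float
    iteration: int
    rng_seed: int
    rng: np.random.Generator = field(repr=False, default=None)


def _evaluate(objective: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    try:
        value = float(objective(x))
    except (ArithmeticError, np.linalg.LinAlgError):
        return np.inf
    return value if np.isfinite(value) else np.inf


def init_population(
    space: HyperparameterSpace,
    objective: Callable[[np.ndarray], float],
    n_bats: int,
    seed: int,
) -> BatPopulation:
    """Positions uniform in the box, velocities zero, all bats evaluated."""
    if n_bats < 2:
        raise ValueError("need at least 2 bats")
    rng = np.random.default_rng(seed)
    lo, hi = space.bounds()
    bats = []
    for _ in range(n_bats):
        x = rng.uniform(lo, hi)
        bats.append(
            BatState(
                position=x,
                velocity=np.zeros_like(x),
                frequency_vector=np.zeros_like(x),
                fitness=_evaluate(objective, x),
            )
        )
    best = min(range(n_bats), key=lambda i: bats[i].fitness)
    return BatPopulation(
        bats=bats,
        best_position=bats[best].position.copy(),
        best_fitness=bats[best].fitness,
        iteration=0,
        rng_seed=seed,
        rng=rng,
    )


def bat_update(
    position: np.ndarray,
    velocity: np.ndarray,
    frequency: np.ndarray,
    best_position: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """The two update equations, before bound clipping:
    ``v' = v + F * (X_best - X)`` then ``X' = v' + X``."""
    new_v = velocity + frequency * (best_position - position)
    return new_v, new_v + position


def ba_step(
    pop: BatPopulation,
    objective: Callable[[np.ndarray], float],
    space: HyperparameterSpace,
    f_max: float = DEFAULT_F_MAX,
) -> BatPopulation:
    """One synchronous iteration of the velocity/position updates (in place).

    A bat whose objective comes back non-finite keeps its previous position
    and carries fitness +inf for this iteration; the elitist archive is
    unaffected.
    """
    if f_max <= 0:
        raise ValueError("f_max must be > 0")
    lo, hi = space.bounds()
    for bat in pop.bats:
        F = pop.rng.uniform(0.0, f_max, size=space.n_dims)
        new_v, raw_x = bat_update(bat.position, bat.velocity, F, pop.best_position)
        new_x = np.clip(raw_x, lo, hi)
        fitness = _evaluate(objective, new_x)
        bat.frequency_vector = F
        if np.isfinite(fitness):
            bat.velocity = new_v
            bat.position = new_x
            bat.fitness = fitness
            if fitness < pop.best_fitness:
                pop.best_fitness = fitness
                pop.best_position = new_x.copy()
        else:
            bat.velocity = new_v
            bat.fitness = np.inf
    pop.iteration += 1
    return pop


def optimize(
    space: HyperparameterSpace,
    objective: Callable[[np.ndarray], float],
    n_bats: int = DEFAULT_N_BATS,
    n_iters: int = DEFAULT_N_ITERS,
    f_max: float = DEFAULT_F_MAX,
    seed: int = 0,
) -> tuple[np.ndarray, float, list[float]]:
    """Run the full search; returns (best position, best fitness, trace).

    The trace has ``n_iters + 1`` entries (initialization included) and is
    monotone non-increasing by the elitist archive.
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    pop = init_population(space, objective, n_bats, seed)
    trace = [pop.best_fitness]
    for _ in range(n_iters):
        ba_step(pop, objective, space, f_max)
        trace.append(pop.best_fitness)
    return pop.best_position.copy(), pop.best_fitness, trace


# ---------------------------------------------------------------------------
# hyperparameter tuning of bagged base learners
# ---------------------------------------------------------------------------

N_ESTIMATORS_RANGE = (10, 200)
#: BA budget for tune_model; small because each evaluation is a full
#: k-fold CV of a bagged ensemble.
TUNE_N_BATS = 10
TUNE_N_ITERS = 15


def family_space(family: str, n_train: int) -> HyperparameterSpace:
    """Declared per-family search domains."""
    n_lo, n_hi = N_ESTIMATORS_RANGE
    est = Dimension("n_estimators", "integer", n_lo, n_hi)
    if family == "polynomial" or family == "gamma":
        return HyperparameterSpace(
            (
                Dimension("degree", "integer", 1, 6),
                Dimension("regularization", "log-continuous", 1e-8, 1.0),
                est,
            )
        )
    if family == "knn":
        k_max = max(2, min(20, n_train - 1))
        return HyperparameterSpace(
            (Dimension("k_neighbors", "integer", 1, k_max), est)
        )
    raise ValueError(f"unknown family {family!r}")


def _make_folds(n: int, k_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic shuffled near-equal folds; folds with < 2 points are
    merged into the previous fold."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    folds = [f for f in np.array_split(idx, k_folds)]
    merged: list[np.ndarray] = []
    for f in folds:
        if len(f) < 2 and merged:
            merged[-1] = np.concatenate([merged[-1], f])
        else:
            merged.append(f)
    return merged


def config_from_params(family: str, params: dict) -> RegressorConfig:
    if family == "knn":
        return RegressorConfig(family="knn", k_neighbors=int(params["k_neighbors"]))
    return RegressorConfig(
        family=family,
        degree=int(params["degree"]),
        regularization=float(params["regularization"]),
    )


def cv_rmse(
    X,
    y,
    config: RegressorConfig,
    n_estimators: int,
    folds: Sequence[np.ndarray],
    ensemble_seed: int,
) -> float:
    """Root-mean pooled squared held-out error of the bagged model."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    sq_sum, count = 0.0, 0
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        cfg = config
        if cfg.family == "knn" and cfg.k_neighbors > len(train_idx):
            return np.inf
        ens = fit_bagged(
            X[train_idx],
            y[train_idx],
            cfg,
            n_estimators=n_estimators,
            seed=ensemble_seed + 1000 * f,
        )
        resid = y[test_idx] - predict_bagged(ens, X[test_idx])
        sq_sum += float(np.sum(resid ** 2))
        count += len(test_idx)
    return float(np.sqrt(sq_sum / count))


def tune_model(
    X,
    y,
    family: str,
    seed: int,
    k_folds: int = 5,
    n_bats: int = TUNE_N_BATS,
    n_iters: int = TUNE_N_ITERS,
    f_max: float = DEFAULT_F_MAX,
) -> tuple[RegressorConfig, int, float]:
    """Minimize 5-fold CV RMSE of the bagged model over the family's space.

    The fold assignment and the per-fold ensemble seeds are fixed across
    all candidate evaluations, so the objective is deterministic in the
    position and the search is reproducible for a fixed seed.

    Returns ``(best config, best n_estimators, best CV RMSE)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    space = family_space(family, n_train=len(y) - len(y) // k_folds)
    folds = _make_folds(len(y), k_folds, seed=seed + 7919)
    ensemble_seed = seed + 104729

    def objective(position: np.ndarray) -> float:
        params = space.decode(position)
        try:
            cfg = config_from_params(family, params)
            return cv_rmse(
                X, y, cfg, int(params["n_estimators"]), folds, ensemble_seed
            )
        except (ValueError, np.linalg.LinAlgError, RuntimeError):
            return np.inf

    best_pos, best_fit, trace = optimize(
        space, objective, n_bats=n_bats, n_iters=n_iters, f_max=f_max, seed=seed
    )
    if not np.isfinite(best_fit):
        raise RuntimeError(
            f"all candidates failed for family {family!r}; trace={trace}"
        )
    params = space.decode(best_pos)
    return config_from_params(family, params), int(params["n_estimators"]), best_fit
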