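"""Artificial bee colony (ABC) optimizer for the fuzzy-regressor parameters.

Classic three-phase ABC: employed bees propose single-coordinate neighbor
moves around their food source, onlookers reinforce sources in proportion to
fitness (roulette selection), and a scout reinitializes the most exhausted
source once its trial counter passes ``limit``.  Selection is greedy per
source and the global best is tracked separately (elitism), so best fitness
is monotone non-decreasing across cycles.

Fitness of a candidate parameter vector on a labeled dataset of
(phase-lag vector, measured latency centroid) pairs is the reciprocal of the
sum of squared prediction errors, capped at ``1/eps`` for (near-)perfect
fits.  A candidate that fires no rule on some pair is penalized with the
squared width of the consequent search box for that pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .it2fls import (
    IT2FParams,
    N_INPUTS,
    N_MFS,
    N_PARAMS,
    N_RULES,
    predict_batch,
)
from .types import LatencyCentroid, NoRuleFiredError, PhaseLagVector

__all__ = [
    "TrainingDataset",
    "FoodSource",
    "ABCConfig",
    "default_bounds",
    "evaluate_fitness",
    "employed_phase",
    "onlooker_phase",
    "scout_phase",
    "train",
    "TrainResult",
]

FITNESS_EPS = 1e-12


@dataclass
class TrainingDataset:
    """Labeled calibration pairs.

    ``X`` is ``(K, 4)`` phase lags in degrees, ``y`` is ``(K,)`` measured
    latency centroids in ms.
    """

    X: np.ndarray
    y: np.ndarray
    split: str = "train"

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y must have the same number of pairs")
        if self.X.shape[0] < 1:
            raise ValueError("need at least one labeled pair")
        if self.X.shape[1] != N_INPUTS:
            raise ValueError(f"X must have {N_INPUTS} phase-lag columns")
        if np.any((self.y < 0) | (self.y > 1000)):
            raise ValueError("latency targets must lie in [0, 1000] ms")

    @classmethod
    def from_pairs(
        cls,
        pairs: list[tuple[PhaseLagVector, LatencyCentroid]],
        split: str = "train",
    ) -> "TrainingDataset":
        X = np.stack([p.as_array() for p, _ in pairs])
        y = np.array([c.value for _, c in pairs])
        return cls(X=X, y=y, split=split)

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass
class FoodSource:
    """One candidate parameter vector in the colony."""

    position: np.ndarray
    fitness: float = 0.0
    trial_counter: int = 0

    def decode(self) -> IT2FParams:
        return IT2FParams.from_vector(self.position, repair=True)


@dataclass
class ABCConfig:
    """Colony hyperparameters and search box.

    Defaults are desk-scale: a 30-source colony for a few hundred cycles
    comfortably fits the 42-dimensional parameter space of the diagonal
    rule base.
    """

    colony_size: int = 30
    limit: int = 50
    max_cycles: int = 500
    mean_bounds: tuple[float, float] = (0.0, 360.0)  # degrees
    sigma_bounds: tuple[float, float] = (5.0, 120.0)  # degrees
    consequent_bounds: tuple[float, float] = (200.0, 600.0)  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.colony_size < 2:
            raise ValueError("colony_size must be >= 2")
        if self.limit < 1:
            raise ValueError("limit must be >= 1")
        if self.max_cycles < 0:
            raise ValueError("max_cycles must be >= 0")


def default_bounds(cfg: ABCConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-coordinate (lower, upper) arrays matching the flat-vector codec
    of :class:`IT2FParams`: means, means, sigmas, then consequents."""
    k = N_INPUTS * N_MFS
    lo = np.concatenate(
        [
            np.full(2 * k, cfg.mean_bounds[0]),
            np.full(k, cfg.sigma_bounds[0]),
            np.full(2 * N_RULES, cfg.consequent_bounds[0]),
        ]
    )
    hi = np.concatenate(
        [
            np.full(2 * k, cfg.mean_bounds[1]),
            np.full(k, cfg.sigma_bounds[1]),
            np.full(2 * N_RULES, cfg.consequent_bounds[1]),
        ]
    )
    assert lo.size == N_PARAMS
    return lo, hi


def evaluate_fitness(
    candidate: FoodSource | np.ndarray,
    data: TrainingDataset,
    cfg: ABCConfig | None = None,
) -> float:
    """Reciprocal-SSE fitness of a candidate on the labeled dataset."""
    cfg = cfg or ABCConfig()
    position = candidate.position if isinstance(candidate, FoodSource) else candidate
    params = IT2FParams.from_vector(np.asarray(position, dtype=float), repair=True)
    span = cfg.consequent_bounds[1] - cfg.consequent_bounds[0]
    try:
        pred = predict_batch(data.X, params)
        sse = float(np.sum((pred - data.y) ** 2))
    except NoRuleFiredError:
        # per-pair fallback: silent rows incur the full-box penalty
        sse = 0.0
        for k in range(len(data)):
            try:
                p = predict_batch(data.X[k : k + 1], params)[0]
                sse += float((p - data.y[k]) ** 2)
            except NoRuleFiredError:
                sse += span**2
    if sse < FITNESS_EPS:
        return 1.0 / FITNESS_EPS
    return 1.0 / sse


def _neighbor_move(
    source: FoodSource,
    partner: FoodSource,
    bounds: tuple[np.ndarray, np.ndarray],
    data: TrainingDataset,
    cfg: ABCConfig,
    rng: np.random.Generator,
) -> FoodSource:
    """Standard ABC move: perturb one random coordinate toward/away from a
    partner, clip to bounds, keep greedily."""
    lo, hi = bounds
    j = int(rng.integers(N_PARAMS))
    phi = rng.uniform(-1.0, 1.0)
    v = source.position.copy()
    v[j] = np.clip(v[j] + phi * (v[j] - partner.position[j]), lo[j], hi[j])
    fit = evaluate_fitness(v, data, cfg)
    if fit > source.fitness:
        return FoodSource(position=v, fitness=fit, trial_counter=0)
    return FoodSource(
        position=source.position,
        fitness=source.fitness,
        trial_counter=source.trial_counter + 1,
    )


def employed_phase(
    colony: list[FoodSource],
    data: TrainingDataset,
    cfg: ABCConfig,
    rng: np.random.Generator,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[FoodSource]:
    """Each employed bee explores a neighbor of its own source."""
    if len(colony) < 2:
        raise ValueError("colony must have at least two sources")
    bounds = bounds or default_bounds(cfg)
    out = []
    for m, source in enumerate(colony):
        partner_idx = int(rng.integers(len(colony) - 1))
        if partner_idx >= m:
            partner_idx += 1
        out.append(_neighbor_move(source, colony[partner_idx], bounds, data, cfg, rng))
    return out


def onlooker_phase(
    colony: list[FoodSource],
    data: TrainingDataset,
    cfg: ABCConfig,
    rng: np.random.Generator,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[FoodSource]:
    """Onlookers revisit sources with probability proportional to fitness."""
    bounds = bounds or default_bounds(cfg)
    fitness = np.array([s.fitness for s in colony])
    total = fitness.sum()
    if total <= 0:
        raise ValueError("onlooker phase needs positive total fitness")
    probs = fitness / total
    out = list(colony)
    for _ in range(len(colony)):
        m = int(rng.choice(len(colony), p=probs))
        partner_idx = int(rng.integers(len(colony) - 1))
        if partner_idx >= m:
            partner_idx += 1
        out[m] = _neighbor_move(out[m], out[partner_idx], bounds, data, cfg, rng)
    return out


def scout_phase(
    colony: list[FoodSource],
    data: TrainingDataset,
    cfg: ABCConfig,
    rng: np.random.Generator,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[FoodSource]:
    """At most one scout per cycle: the most-exhausted source beyond
    ``limit`` is resampled uniformly in the search box."""
    bounds = bounds or default_bounds(cfg)
    lo, hi = bounds
    counters = np.array([s.trial_counter for s in colony])
    m = int(np.argmax(counters))
    if counters[m] <= cfg.limit:
        return list(colony)
    pos = rng.uniform(lo, hi)
    out = list(colony)
    out[m] = FoodSource(position=pos, fitness=evaluate_fitness(pos, data, cfg))
    return out


@dataclass
class TrainResult:
    """Outcome of one ABC run."""

    params: IT2FParams
    best_fitness: float
    history: np.ndarray  # best fitness per cycle (monotone non-decreasing)
    position: np.ndarray = field(repr=False, default=None)


def train(data: TrainingDataset, cfg: ABCConfig | None = None) -> TrainResult:
    """Run the full employed/onlooker/scout loop and return the best
    decoded parameter set plus the best-fitness history."""
    cfg = cfg or ABCConfig()
    rng = np.random.default_rng(cfg.seed)
    bounds = default_bounds(cfg)
    lo, hi = bounds
    colony = []
    for _ in range(cfg.colony_size):
        pos = rng.uniform(lo, hi)
        colony.append(FoodSource(position=pos, fitness=evaluate_fitness(pos, data, cfg)))
    best = max(colony, key=lambda s: s.fitness)
    best = FoodSource(position=best.position.copy(), fitness=best.fitness)
    history = []
    for _ in range(cfg.max_cycles):
        colony = employed_phase(colony, data, cfg, rng, bounds)
        colony = onlooker_phase(colony, data, cfg, rng, bounds)
        cycle_best = max(colony, key=lambda s: s.fitness)
        if cycle_best.fitness > best.fitness:
            best = FoodSource(position=cycle_best.position.copy(), fitness=cycle_best.fitness)
        colony = scout_phase(colony, data, cfg, rng, bounds)
        history.append(best.fitness)
    return TrainResult(
        params=IT2FParams.from_vector(best.position, repair=True),
        best_fitness=best.fitness,
        history=np.asarray(history),
        position=best.position,
    )
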