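"""Artificial bee colony: fitness, phases, invariants, and recovery."""

import numpy as np
import pytest

from sodbci import abc_trainer
from sodbci.abc_trainer import (
    ABCConfig,
    FITNESS_EPS,
    FoodSource,
    TrainingDataset,
    default_bounds,
    employed_phase,
    evaluate_fitness,
    onlooker_phase,
    scout_phase,
    train,
)
from sodbci.it2fls import IT2FParams, predict_batch


def lag_map_dataset(n_pairs: int = 16, base: float = 300.0) -> TrainingDataset:
    """Noiseless calibration pairs from the known delay -> latency map:
    lags follow the phase-lag identity, latency = base + delay."""
    delays = np.linspace(0.0, 46.875, n_pairs)
    X = np.stack(
        [(np.array([0.0, 90.0, 180.0, 270.0]) + d / 62.5 * 360.0) % 360.0 for d in delays]
    )
    return TrainingDataset(X=X, y=base + delays)


@pytest.fixture
def small_cfg():
    return ABCConfig(colony_size=10, limit=10, max_cycles=30, seed=0)


@pytest.fixture
def tiny_data():
    return lag_map_dataset(4)


def _constant_candidate(value: float, cfg: ABCConfig) -> np.ndarray:
    """A parameter vector predicting ``value`` for any input (wide MFs,
    degenerate consequents)."""
    m = np.tile([60.0, 180.0, 300.0], (4, 1))
    params = IT2FParams(
        m_low=m,
        m_high=m,
        sigma=np.full((4, 3), 120.0),
        c_l=np.full(3, value),
        c_r=np.full(3, value),
    )
    return params.position if hasattr(params, "position") else params.to_vector()


class TestFitness:
    def test_reciprocal_sse_arithmetic(self, small_cfg):
        # constant-output model vs targets offset by known residuals
        data = TrainingDataset(
            X=np.tile([90.0, 180.0, 270.0, 0.0], (2, 1)), y=np.array([310.0, 320.0])
        )
        vec = _constant_candidate(320.0, small_cfg)
        # residuals (10, 0) -> SSE 100 -> fitness 0.01
        assert evaluate_fitness(vec, data, small_cfg) == pytest.approx(0.01)

    def test_perfect_fit_capped(self, small_cfg):
        data = TrainingDataset(
            X=np.tile([90.0, 180.0, 270.0, 0.0], (2, 1)), y=np.array([320.0, 320.0])
        )
        vec = _constant_candidate(320.0, small_cfg)
        assert evaluate_fitness(vec, data, small_cfg) == 1.0 / FITNESS_EPS

    def test_doubling_residuals_quarters_fitness(self, small_cfg):
        X = np.tile([90.0, 180.0, 270.0, 0.0], (2, 1))
        d1 = TrainingDataset(X=X, y=np.array([310.0, 330.0]))  # residuals +-10
        d2 = TrainingDataset(X=X, y=np.array([300.0, 340.0]))  # residuals +-20
        vec = _constant_candidate(320.0, small_cfg)
        f1 = evaluate_fitness(vec, d1, small_cfg)
        f2 = evaluate_fitness(vec, d2, small_cfg)
        assert f1 / f2 == pytest.approx(4.0)


class TestPhases:
    def _colony(self, cfg, data, rng):
        lo, hi = default_bounds(cfg)
        out = []
        for _ in range(cfg.colony_size):
            pos = rng.uniform(lo, hi)
            out.append(FoodSource(position=pos, fitness=evaluate_fitness(pos, data, cfg)))
        return out

    def test_identical_colony_increments_counters(self, small_cfg, tiny_data, rng):
        lo, hi = default_bounds(small_cfg)
        pos = np.random.default_rng(5).uniform(lo, hi)
        fit = evaluate_fitness(pos, tiny_data, small_cfg)
        colony = [FoodSource(position=pos.copy(), fitness=fit) for _ in range(6)]
        out = employed_phase(colony, tiny_data, small_cfg, rng)
        # x - x_partner == 0 for every pair, so no proposal can improve
        assert all(s.trial_counter == 1 for s in out)
        for s in out:
            np.testing.assert_array_equal(s.position, pos)

    def test_employed_phase_deterministic(self, small_cfg, tiny_data):
        colony = self._colony(small_cfg, tiny_data, np.random.default_rng(3))
        a = employed_phase(list(colony), tiny_data, small_cfg, np.random.default_rng(7))
        b = employed_phase(list(colony), tiny_data, small_cfg, np.random.default_rng(7))
        for s, t in zip(a, b):
            np.testing.assert_array_equal(s.position, t.position)

    def test_greedy_never_decreases_best(self, small_cfg, tiny_data, rng):
        colony = self._colony(small_cfg, tiny_data, rng)
        best_before = max(s.fitness for s in colony)
        out = employed_phase(colony, tiny_data, small_cfg, rng)
        assert max(s.fitness for s in out) >= best_before

    def test_onlookers_flock_to_dominant_source(self, small_cfg, tiny_data, rng):
        colony = self._colony(small_cfg, tiny_data, np.random.default_rng(4))
        for i, s in enumerate(colony):
            s.fitness = 1.0 if i == 0 else 1e-12
            s.trial_counter = 0
        out = onlooker_phase(colony, tiny_data, small_cfg, rng)
        # every visit goes to source 0: others are untouched
        for i in range(1, len(out)):
            assert out[i].trial_counter == 0
            np.testing.assert_array_equal(out[i].position, colony[i].position)
        assert out[0].trial_counter > 0 or not np.array_equal(
            out[0].position, colony[0].position
        )

    def test_equal_fitness_visits_all_sources(self, small_cfg, tiny_data):
        """Roulette selection with equal weights spreads visits across the
        colony."""
        touched = np.zeros(4, dtype=int)
        for k in range(25):
            colony = self._colony(
                ABCConfig(colony_size=4, seed=0), tiny_data, np.random.default_rng(4)
            )
            for s in colony:
                s.fitness = 0.5
                s.trial_counter = 0
            out = onlooker_phase(colony, tiny_data, small_cfg, np.random.default_rng(k))
            for i in range(4):
                if out[i].trial_counter > 0 or not np.array_equal(
                    out[i].position, colony[i].position
                ):
                    touched[i] += 1
        assert (touched >= 5).all()

    def test_scout_replaces_exhausted_source(self, small_cfg, tiny_data, rng):
        colony = self._colony(small_cfg, tiny_data, rng)
        colony[3].trial_counter = small_cfg.limit + 1
        old = colony[3].position.copy()
        out = scout_phase(colony, tiny_data, small_cfg, rng)
        assert out[3].trial_counter == 0
        assert not np.array_equal(out[3].position, old)
        lo, hi = default_bounds(small_cfg)
        assert np.all(out[3].position >= lo) and np.all(out[3].position <= hi)

    def test_scout_noop_below_limit(self, small_cfg, tiny_data, rng):
        colony = self._colony(small_cfg, tiny_data, rng)
        out = scout_phase(colony, tiny_data, small_cfg, rng)
        for s, t in zip(colony, out):
            np.testing.assert_array_equal(s.position, t.position)


class TestTrain:
    def test_zero_cycles_returns_best_initial(self, tiny_data):
        cfg = ABCConfig(colony_size=8, max_cycles=0, seed=2)
        res = train(tiny_data, cfg)
        assert res.history.size == 0
        assert res.best_fitness > 0

    def test_history_monotone_and_deterministic(self, tiny_data):
        cfg = ABCConfig(colony_size=10, limit=10, max_cycles=40, seed=5)
        a = train(tiny_data, cfg)
        b = train(tiny_data, cfg)
        assert np.all(np.diff(a.history) >= 0)
        np.testing.assert_array_equal(a.history, b.history)
        np.testing.assert_array_equal(a.position, b.position)

    def test_positions_respect_bounds_and_invariants(self, tiny_data):
        cfg = ABCConfig(colony_size=8, limit=5, max_cycles=25, seed=9)
        res = train(tiny_data, cfg)
        p = res.params
        assert np.all(p.m_low <= p.m_high)
        assert np.all(p.sigma > 0)
        assert np.all(p.c_l <= p.c_r)
        assert np.all(p.c_l >= cfg.consequent_bounds[0] - 1e-9)
        assert np.all(p.c_r <= cfg.consequent_bounds[1] + 1e-9)

    def test_fit_improves_over_random_start(self):
        data = lag_map_dataset(8)
        cfg = ABCConfig(colony_size=15, limit=20, max_cycles=120, seed=3)
        res = train(data, cfg)
        assert res.best_fitness > res.history[0] or res.history[0] == res.best_fitness
        pred = predict_batch(data.X, res.params)
        rmse = float(np.sqrt(np.mean((pred - data.y) ** 2)))
        assert rmse < 20.0  # coarse fit with a small budget

    def test_dataset_validation(self):
        with pytest.raises(ValueError):
            TrainingDataset(X=np.zeros((2, 4)), y=np.array([100.0, 1500.0]))
        with pytest.raises(ValueError):
            TrainingDataset(X=np.zeros((2, 3)), y=np.array([100.0, 200.0]))
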