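"""Whale optimization: fitness components, dynamics, decoding, elitism."""

import numpy as np
import pytest

from poseload.woa import (SearchSpace, WoaConfig, a_schedule, decode, fitness,
                          frc, optimize, whale_step)


class TestFrc:
    def test_single_feature_has_no_pairs(self, rng):
        assert frc(rng.normal(size=(10, 1))) == 0.0

    def test_two_identical_columns(self, rng):
        col = rng.normal(size=20)
        assert np.isclose(frc(np.column_stack([col, col])), 0.25)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10_000, 2))
        assert frc(x) < 0.01

    def test_constant_columns_contribute_zero(self, rng):
        x = np.column_stack([rng.normal(size=15), np.full(15, 2.0)])
        assert frc(x) == 0.0

    def test_signed_mode_can_cancel(self, rng):
        col = rng.normal(size=30)
        x = np.column_stack([col, -col])
        assert np.isclose(frc(x, use_abs=False), -0.25)
        assert np.isclose(frc(x, use_abs=True), 0.25)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="2 rows"):
            frc(np.zeros((1, 3)))


class TestFitness:
    def test_printed_arithmetic(self):
        assert np.isclose(fitness(0.1, 0.2), 0.13)
        assert np.isclose(fitness(0.5, 0.0), 0.35)
        assert fitness(0.0, 0.0) == 0.0

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            fitness(1.0, 1.0, alpha=1.0)


def _space(dim=3):
    return SearchSpace(bounds={f"x{i}": (-2.0, 2.0, "float")
                               for i in range(dim)}, n_features=0)


class TestWhaleStep:
    def test_a_schedule_linear_two_to_zero(self):
        ts = np.arange(0, 51)
        values = np.array([a_schedule(t, 50) for t in ts])
        assert values[0] == 2.0 and values[-1] == 0.0
        assert np.allclose(np.diff(values), -2.0 / 50.0)

    def test_terminal_iteration_collapses_toward_best(self):
        # at t = max_iter, a = 0 so |A| = 0 < 1: random search unreachable
        # and the non-spiral branch is pure encircling of the best
        space = _space()
        cfg = WoaConfig(population=30, max_iter=50, random_search_prob=0.0,
                        seed=0)
        rng = np.random.default_rng(3)
        pop = rng.uniform(-2, 2, size=(30, 3))
        best = np.zeros(3)
        new = whale_step(pop, best, t=50, cfg=cfg, space=space, rng=rng)
        # encircling with A=0 lands exactly on best; spiral keeps |X*-X| scale
        dist_before = np.linalg.norm(pop - best, axis=1)
        dist_after = np.linalg.norm(new - best, axis=1)
        assert np.all(dist_after <= np.e * dist_before + 1e-9)
        assert np.any(np.isclose(dist_after, 0.0))

    def test_positions_stay_in_bounds(self, rng):
        space = _space()
        cfg = WoaConfig(population=10, max_iter=20, seed=0)
        pop = rng.uniform(-2, 2, size=(10, 3))
        for t in range(1, 21):
            pop = whale_step(pop, pop[0], t, cfg, space, rng)
            assert np.all(pop >= -2.0) and np.all(pop <= 2.0)

    def test_empty_population_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            whale_step(np.empty((0, 3)), np.zeros(3), 1,
                       WoaConfig(), _space(), rng)


class TestDecode:
    def test_top_k_with_decreasing_logits(self):
        space = SearchSpace(bounds={}, n_features=512, n_select=300)
        logits = np.linspace(1.0, 0.0, 512)
        _, feats = decode(logits, space)
        assert np.array_equal(feats, np.arange(300))

    def test_selected_count_always_300(self, rng):
        space = SearchSpace(bounds={}, n_features=512, n_select=300)
        for _ in range(10):
            _, feats = decode(rng.uniform(size=512), space)
            assert len(feats) == 300 and len(set(feats)) == 300

    def test_ties_break_to_lowest_index(self):
        space = SearchSpace(bounds={}, n_features=6, n_select=3)
        _, feats = decode(np.array([0.5, 0.5, 0.5, 0.5, 0.5, 0.5]), space)
        assert np.array_equal(feats, [0, 1, 2])

    def test_integer_rounding_half_up(self):
        space = SearchSpace(bounds={"d": (1.0, 8.0, "int")}, n_features=0)
        hypers, _ = decode(np.array([3.5]), space)
        assert hypers["d"] == 4

    def test_log_scale_learning_rate(self):
        space = SearchSpace(bounds={"lr": (1e-5, 1e-2, "log")}, n_features=0)
        lo, _ = decode(np.array([1e-5]), space)
        hi, _ = decode(np.array([1e-2]), space)
        assert np.isclose(lo["lr"], 1e-5) and np.isclose(hi["lr"], 1e-2)


class TestOptimize:
    def test_elitist_trace_non_increasing_and_reproducible(self):
        space = _space(4)
        cfg = WoaConfig(population=10, max_iter=15, seed=5)
        ev = lambda h, f: (sum(v * v for v in h.values()), 0.0)
        r1 = optimize(ev, space, cfg)
        r2 = optimize(ev, space, cfg)
        assert np.all(np.diff(r1.trace) <= 0)
        assert np.array_equal(r1.trace, r2.trace)
        assert len(r1.trace) == 16  # initial + 15 iterations

    def test_failed_candidates_get_infinite_fitness(self):
        space = _space(2)
        calls = {"n": 0}

        def flaky(h, f):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("proxy training failed")
            return sum(v * v for v in h.values()), 0.0

        res = optimize(flaky, space, WoaConfig(population=6, max_iter=5, seed=1))
        assert np.isfinite(res.best.fitness)

    def test_sphere_converges(self):
        space = _space(5)
        ev = lambda h, f: (sum(v * v for v in h.values()), 0.0)
        res = optimize(ev, space, WoaConfig(population=30, max_iter=50, seed=0))
        sphere = sum(v * v for v in res.hyperparameters.values())
        assert sphere < 1e-2
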