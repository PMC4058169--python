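import numpy as np
import pytest

from swarmsvm.optimizers import (
    Candidate,
    ConvergenceTrace,
    CuckooSearch,
    Dimension,
    HybridCSPSO,
    ParticleSwarm,
    RealCodedGA,
    SearchSpace,
    levy_flight,
    mantegna_steps,
    optimize_hybrid,
)


@pytest.fixture
def bowl_space():
    return SearchSpace([Dimension("x", -5.0, 5.0), Dimension("y", -5.0, 5.0)])


def bowl(v):
    return -float(np.dot(v, v))


class TestSearchSpace:
    def test_log_dimensions_decode_to_natural_units(self):
        space = SearchSpace.for_svm("rbf")
        z = np.array([space.lower[0], space.upper[1]])
        decoded = space.decode_dict(z)
        assert decoded["C"] == pytest.approx(2.0**-5)
        assert decoded["sigma"] == pytest.approx(2.0**4)

    def test_samples_respect_bounds(self):
        space = SearchSpace.for_svm("rbf")
        z = space.sample(np.random.default_rng(0), 100)
        assert np.all(z >= space.lower) and np.all(z <= space.upper)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            Dimension("x", 1.0, 1.0)
        with pytest.raises(ValueError):
            Dimension("x", -1.0, 1.0, "log")


class TestLevyFlight:
    def test_zero_drift_when_current_equals_best(self, bowl_space):
        rng = np.random.default_rng(0)
        x = np.array([1.0, 2.0])
        out = levy_flight(x, x, rng, alpha=0.5)
        np.testing.assert_array_equal(out, x)

    def test_zero_alpha_returns_current(self, bowl_space):
        rng = np.random.default_rng(0)
        x, b = np.array([1.0, 2.0]), np.array([0.0, 0.0])
        np.testing.assert_array_equal(levy_flight(x, b, rng, alpha=0.0), x)

    def test_steps_are_heavy_tailed(self):
        """Mantegna steps at exponent 1.5: kurtosis far above Gaussian and a
        survival-function tail index near lam - 1 = 0.5."""
        rng = np.random.default_rng(123)
        s = mantegna_steps(rng, 1.5, 100_000)
        kurt = np.mean((s - s.mean()) ** 4) / np.var(s) ** 2
        assert kurt > 100  # Gaussian would be 3
        # Hill estimator on the top 1% of |s|
        tail = np.sort(np.abs(s))[-1000:]
        hill = 1.0 / np.mean(np.log(tail / tail[0]))
        assert 0.3 < hill < 0.75

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            mantegna_steps(np.random.default_rng(0), 1.0, 10)

    def test_proposals_clamped_to_bounds(self, bowl_space):
        rng = np.random.default_rng(7)
        for _ in range(200):
            out = levy_flight(
                np.array([4.9, -4.9]), np.array([0.0, 0.0]), rng, alpha=10.0,
                bounds=(bowl_space.lower, bowl_space.upper),
            )
            assert np.all(out >= bowl_space.lower) and np.all(out <= bowl_space.upper)


class TestParticleSwarm:
    def test_stationary_when_no_attraction(self, bowl_space):
        """w=1, zero velocity, particle at its own pbest = gbest: stays put."""
        pso = ParticleSwarm(bowl_space, pop_size=2, n_iters=1, inertia=1.0)
        pos = np.array([[1.0, 1.0], [1.0, 1.0]])
        fit = np.array([bowl(p) for p in pos])
        state = pso.init_state_from(pos, fit, Candidate(pos[0].copy(), fit[0], True))
        pso.step(state, bowl, np.random.default_rng(0), w=1.0)
        np.testing.assert_allclose(state.positions, pos)

    def test_finds_bowl_minimum(self, bowl_space):
        best, trace = ParticleSwarm(bowl_space, 20, 100, seed=3).run(bowl)
        assert np.linalg.norm(best.position) < 1e-2
        assert trace.is_monotone()

    def test_budget_is_pop_times_iters_plus_init(self, bowl_space):
        pso = ParticleSwarm(bowl_space, pop_size=12, n_iters=30, seed=0)
        pso.run(bowl)
        assert pso.n_evaluations == 12 * 31


class TestCuckooSearch:
    def test_constant_objective_keeps_best(self, bowl_space):
        best, trace = CuckooSearch(bowl_space, 10, 20, seed=0).run(lambda v: 1.0)
        assert trace.best_fitness == [1.0] * 20

    def test_best_fitness_never_decreases_within_run(self, bowl_space):
        cs = CuckooSearch(bowl_space, 15, 40, seed=5)
        rng = np.random.default_rng(5)
        f = cs._make_objective(bowl)
        nests = cs.init_state(f, rng)
        prev = nests.best_fitness
        for _ in range(40):
            cs.step(nests, f, rng)
            assert nests.best_fitness >= prev
            prev = nests.best_fitness

    def test_finds_bowl_minimum(self, bowl_space):
        best, trace = CuckooSearch(bowl_space, 20, 100, seed=3).run(bowl)
        assert np.linalg.norm(best.position) < 1e-2

    def test_budget_formula(self, bowl_space):
        cs = CuckooSearch(bowl_space, pop_size=20, n_iters=50, pa=0.25, seed=0)
        cs.run(bowl)
        assert cs.n_evaluations == 20 + 50 * (20 + round(0.25 * 20))

    def test_invalid_pa_rejected(self, bowl_space):
        with pytest.raises(ValueError):
            CuckooSearch(bowl_space, 10, 10, pa=1.0)


class TestRealCodedGA:
    def test_no_variation_operators_copies_parents(self, bowl_space):
        """p_c = p_m = 0: children are selected copies of current members
        (plus the documented random-immigrant slot); the best survives."""
        ga = RealCodedGA(bowl_space, pop_size=10, n_iters=1, p_c=0.0, p_m=0.0, seed=0)
        rng = np.random.default_rng(0)
        pos = bowl_space.sample(rng, 10)
        fit = np.array([bowl(p) for p in pos])
        children, child_fit = ga.step(pos.copy(), fit, bowl, rng)
        originals = {tuple(p) for p in pos}
        copies = sum(tuple(c) in originals for c in children)
        assert copies >= 9  # all but the immigrant slot
        assert child_fit.max() >= fit.max()

    def test_full_mutation_decorrelates_population(self, bowl_space):
        ga = RealCodedGA(bowl_space, pop_size=10, n_iters=1, p_c=0.0, p_m=1.0,
                         mutation_sigma_frac=0.5, seed=0)
        rng = np.random.default_rng(1)
        pos = bowl_space.sample(rng, 10)
        fit = np.array([bowl(p) for p in pos])
        children, _ = ga.step(pos.copy(), fit, bowl, rng)
        originals = {tuple(p) for p in pos}
        # with per-gene sigma = half the range, essentially no child is an
        # exact copy of any current member (the elite re-insert may be one)
        fresh = sum(tuple(c) not in originals for c in children)
        assert fresh >= 9

    def test_finds_bowl_neighborhood(self, bowl_space):
        best, trace = RealCodedGA(bowl_space, 20, 100, seed=3).run(bowl)
        assert np.linalg.norm(best.position) < 0.1
        assert trace.is_monotone()

    def test_all_equal_fitness_falls_back_to_uniform(self, bowl_space):
        ga = RealCodedGA(bowl_space, pop_size=10, n_iters=1, seed=0)
        idx = ga._select(np.zeros(10), np.random.default_rng(0))
        assert len(idx) == 10

    def test_odd_population_rejected(self, bowl_space):
        with pytest.raises(ValueError):
            RealCodedGA(bowl_space, pop_size=7)

    def test_budget_is_pop_times_iters_plus_init(self, bowl_space):
        ga = RealCodedGA(bowl_space, pop_size=10, n_iters=25, seed=0)
        ga.run(bowl)
        assert ga.n_evaluations == 10 * 26


class TestHybrid:
    def test_trace_length_equals_total_iterations(self, bowl_space):
        best, trace = optimize_hybrid(bowl_space, bowl, pop_size=20, total_iters=100, seed=0)
        assert len(trace) == 100
        assert trace.is_monotone()

    def test_pso_stage_never_loses_cs_best(self, bowl_space):
        hyb = HybridCSPSO(bowl_space, 10, 30, cs_fraction=0.5, seed=1)
        best, trace = hyb.run(bowl)
        cs_stage_best = trace.best_fitness[hyb.cs_iters - 1]
        assert best.fitness >= cs_stage_best

    def test_finds_bowl_minimum(self, bowl_space):
        best, _ = HybridCSPSO(bowl_space, 20, 100, seed=3).run(bowl)
        assert np.linalg.norm(best.position) < 1e-2

    def test_best_transfer_mode(self, bowl_space):
        best, trace = HybridCSPSO(bowl_space, 10, 20, transfer="best", seed=2).run(bowl)
        assert len(trace) == 20 and trace.is_monotone()

    def test_invalid_cs_fraction_rejected(self, bowl_space):
        with pytest.raises(ValueError):
            HybridCSPSO(bowl_space, 10, 10, cs_fraction=1.5)


@pytest.mark.parametrize("cls", [ParticleSwarm, CuckooSearch, RealCodedGA, HybridCSPSO])
class TestSharedInvariants:
    def test_seed_determinism(self, cls, bowl_space):
        r1 = cls(bowl_space, 10, 15, seed=7).run(bowl)
        r2 = cls(bowl_space, 10, 15, seed=7).run(bowl)
        assert r1[1].best_fitness == r2[1].best_fitness
        np.testing.assert_array_equal(r1[0].position, r2[0].position)

    def test_monotone_trace_and_bounded_best(self, cls, bowl_space):
        best, trace = cls(bowl_space, 10, 15, seed=3).run(bowl)
        assert trace.is_monotone()
        assert np.all(best.position >= bowl_space.lower - 1e-12)
        assert np.all(best.position <= bowl_space.upper + 1e-12)

    def test_evaluated_positions_stay_in_bounds(self, cls, bowl_space):
        seen = []

        def spy(v):
            seen.append(np.array(v))
            return bowl(v)

        cls(bowl_space, 10, 10, seed=1).run(spy)
        arr = np.array(seen)
        # objective receives decoded (natural-unit) positions; for this
        # linear space decoded == scaled
        assert np.all(arr >= bowl_space.lower - 1e-12)
        assert np.all(arr <= bowl_space.upper + 1e-12)


def test_trace_export_columns(tmp_path, bowl_space):
    _, trace = ParticleSwarm(bowl_space, 6, 8, seed=0).run(bowl)
    path = tmp_path / "trace.csv"
    trace.write_csv(path, bowl_space)
    import pandas as pd

    df = pd.read_csv(path)
    assert list(df.columns) == ["generation", "best_fitness", "mean_fitness", "best_x", "best_y"]
    assert len(df) == 8
    assert df["best_fitness"].is_monotonic_increasing or np.all(np.diff(df["best_fitness"]) >= 0)
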