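"""Finite-population engine tests: selection probabilities against binomial
oracles, generation-filling contracts (conservation, fill-time law,
inheritance), mutation behaviour, oldest-old bookkeeping, determinism, and
the discrete-time survival test."""

import numpy as np
import pytest
from scipy import stats

from evoaging import (
    EvolutionConfig,
    ExtinctionError,
    GenerationRecord,
    HazardFamily,
    HazardParams,
    choose_parent,
    init_population,
    mutate_offspring,
    run_evolution,
    run_generation_continuous,
    run_generation_discrete,
)
from evoaging.experiments import default_hazard


@pytest.fixture(scope="module")
def hz200():
    return default_hazard(HazardFamily.HRM, 0.045, N=200)


def make_parents(x, death):
    x = np.asarray(x, dtype=float)
    return GenerationRecord(x=x, death_time=np.asarray(death, dtype=float),
                            oldest_old=np.zeros(x.size, dtype=bool))


class TestInitPopulation:
    def test_traits_uniform(self, rng):
        cfg = EvolutionConfig(N=100_000, G=1, replicates=1, seed=0)
        hz = default_hazard(HazardFamily.HRM, 0.045)
        gen = init_population(cfg, hz, rng)
        assert gen.x.min() >= 0 and gen.x.max() <= 1
        se = gen.x.std() / np.sqrt(gen.x.size)
        assert abs(gen.x.mean() - 0.5) < 3 * se
        assert (gen.death_time > 0).all()

    def test_same_seed_identical(self, hz200):
        cfg = EvolutionConfig(N=500, G=1, replicates=1, seed=3)
        a = init_population(cfg, hz200, np.random.default_rng(42))
        b = init_population(cfg, hz200, np.random.default_rng(42))
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.death_time, b.death_time)


class TestChooseParent:
    def test_sole_survivor_always_chosen(self, rng):
        """A lone individual reproduces with probability one, whatever its
        trait — including a trait of exactly zero."""
        for x in (0.0, 1e-6, 0.9):
            assert choose_parent([x], rng) == 0

    def test_two_individuals_exact_weights(self, rng):
        picks = np.array([choose_parent([0.2, 0.8], rng)
                          for _ in range(20_000)])
        p = (picks == 1).mean()
        assert abs(p - 0.8) < 3 * np.sqrt(0.8 * 0.2 / 20_000)

    def test_three_way_frequencies(self, rng):
        w = np.array([0.1, 0.3, 0.6])
        picks = np.array([choose_parent(w, rng) for _ in range(100_000)])
        for i, pi in enumerate(w):
            freq = (picks == i).mean()
            assert abs(freq - pi) < 3 * np.sqrt(pi * (1 - pi) / picks.size)

    def test_all_zero_traits_uniform(self, rng):
        picks = np.array([choose_parent([0.0, 0.0], rng)
                          for _ in range(5000)])
        assert abs(picks.mean() - 0.5) < 3 * np.sqrt(0.25 / 5000)

    def test_empty_is_extinction(self, rng):
        with pytest.raises(ExtinctionError):
            choose_parent([], rng)


class TestMutation:
    def test_no_mutation_is_identity(self, rng):
        cfg = EvolutionConfig(pm=0.0)
        assert mutate_offspring(0.371, cfg, rng) == 0.371

    def test_uniform_reset_forgets_parent(self, rng):
        cfg = EvolutionConfig(pm=1.0)
        out = mutate_offspring(np.full(100_000, 0.9), cfg, rng)
        assert stats.ks_1samp(out, stats.uniform.cdf).statistic < 0.01

    def test_gaussian_kernel_respects_bounds(self, rng):
        cfg = EvolutionConfig(pm=1.0, kernel="gaussian", kernel_sd=0.3)
        out = mutate_offspring(rng.random(50_000), cfg, rng)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_mutation_rate_honoured(self, rng):
        cfg = EvolutionConfig(pm=0.25)
        parent = np.full(100_000, 0.5)
        out = mutate_offspring(parent, cfg, rng)
        frac = (out != parent).mean()   # uniform redraw a.s. differs
        assert abs(frac - 0.25) < 3 * np.sqrt(0.25 * 0.75 / parent.size)


class TestContinuousGeneration:
    def test_fills_exactly_n(self, hz200, rng):
        cfg = EvolutionConfig(N=200, G=1, replicates=1, seed=0)
        parents = init_population(cfg, hz200, rng)
        child = run_generation_continuous(parents, cfg, hz200, rng)
        assert not child.extinct
        assert child.size == 200

    def test_clonal_inheritance_without_mutation(self, rng):
        cfg = EvolutionConfig(N=100, G=1, replicates=1, seed=0, pm=0.0)
        hz = default_hazard(HazardFamily.HRM, 0.02, N=100)
        parents = make_parents(np.full(100, 0.37), np.full(100, 1e9))
        child = run_generation_continuous(parents, cfg, hz, rng)
        assert np.allclose(child.x, 0.37)

    def test_fill_time_is_gamma_n(self, rng):
        """With immortal parents the filling time is a sum of N unit-rate
        exponential gaps: mean N, variance N."""
        cfg = EvolutionConfig(N=100, G=1, replicates=1, seed=0, pm=0.0)
        hz = default_hazard(HazardFamily.HRM, 0.02, N=100)
        fills = []
        for _ in range(1000):
            parents = make_parents(np.full(100, 0.5), np.full(100, 1e12))
            run_generation_continuous(parents, cfg, hz, rng)
            fills.append(parents.fill_time)
        fills = np.asarray(fills)
        assert abs(fills.mean() - 100.0) < 3 * 10.0 / np.sqrt(1000)

    def test_oldest_old_flags(self, hz200, rng):
        cfg = EvolutionConfig(N=200, G=1, replicates=1, seed=0)
        parents = init_population(cfg, hz200, rng)
        run_generation_continuous(parents, cfg, hz200, rng)
        assert np.array_equal(parents.oldest_old,
                              parents.death_time > parents.fill_time)
        assert parents.oldest_old.any()   # long-lived low-trait founders

    def test_extinction_when_parents_die_early(self, rng):
        cfg = EvolutionConfig(N=200, G=1, replicates=1, seed=0)
        hz = default_hazard(HazardFamily.HRM, 0.045, N=200)
        parents = make_parents(np.full(200, 0.9), np.full(200, 1.0))
        child = run_generation_continuous(parents, cfg, hz, rng)
        assert child.extinct
        assert child.size < 200

    def test_positive_frequency_dependence_within_generation(self, rng):
        """Low-trait parents gain reproductive share as high-trait parents
        die during the filling: their offspring concentrate late."""
        cfg = EvolutionConfig(N=200, G=1, replicates=1, seed=0, pm=0.0)
        hz = default_hazard(HazardFamily.HRM, 0.08, N=200)
        x = np.concatenate([np.full(100, 0.05), np.full(100, 0.9)])
        from evoaging import draw_death_time
        death = draw_death_time(hz, x, rng)
        parents = make_parents(x, death)
        child = run_generation_continuous(parents, cfg, hz, rng)
        assert not child.extinct
        low = child.x < 0.5          # offspring arrive in event order
        first, second = low[:100], low[100:]
        assert second.mean() > first.mean()

    def test_sexual_offspring_is_parental_mean(self, rng):
        cfg = EvolutionConfig(N=100, G=1, replicates=1, seed=0, pm=0.0,
                              reproduction="sexual")
        hz = default_hazard(HazardFamily.HRM, 0.02, N=100)
        x = np.where(np.arange(100) % 2 == 0, 0.2, 0.8)
        parents = make_parents(x, np.full(100, 1e9))
        child = run_generation_continuous(parents, cfg, hz, rng)
        assert set(np.round(np.unique(child.x), 10)) <= {0.2, 0.5, 0.8}
        assert (np.isclose(child.x, 0.5)).any()

    def test_maturation_delays_reproduction(self, rng):
        cfg = EvolutionConfig(N=100, G=1, replicates=1, seed=0, pm=0.0,
                              maturation=50.0)
        hz = default_hazard(HazardFamily.HRM, 0.02, N=100)
        parents = make_parents(np.full(100, 0.5), np.full(100, 1e9))
        run_generation_continuous(parents, cfg, hz, rng)
        assert parents.fill_time > 50.0


class TestDiscreteGeneration:
    def test_one_step_survivor_fraction(self, rng):
        """Survival through one step matches 1 - mu within binomial error."""
        hz = HazardParams(family="HRM", a=0.05, b=0.0)
        cfg = EvolutionConfig(N=2000, G=1, replicates=1, seed=0,
                              engine="discrete", pm=0.0)
        parents = make_parents(np.full(2000, 0.5), np.full(2000, np.nan))
        run_generation_discrete(parents, cfg, hz, rng)
        died_first_step = (parents.death_time == 1.0).mean()
        assert abs(died_first_step - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000)

    def test_fills_exactly_n(self, rng):
        cfg = EvolutionConfig(N=100, G=1, replicates=1, seed=0,
                              engine="discrete")
        hz = default_hazard(HazardFamily.HRM, 0.045, N=100)
        parents = init_population(cfg, hz, rng)
        child = run_generation_discrete(parents, cfg, hz, rng)
        assert not child.extinct
        assert child.size == 100

    def test_hazard_clamp_warns(self, rng):
        hz = HazardParams(family="HRM", a=2.0, b=0.0)   # hazard 2 > 1
        cfg = EvolutionConfig(N=20, G=1, replicates=1, seed=0,
                              engine="discrete")
        parents = make_parents(np.full(20, 0.5), np.full(20, np.nan))
        with pytest.warns(UserWarning, match="clamped"):
            run_generation_discrete(parents, cfg, hz, rng)


class TestRunEvolution:
    def test_bit_identical_reruns(self):
        cfg = EvolutionConfig(N=60, G=15, replicates=4, seed=9,
                              record_last=5)
        hz = default_hazard(HazardFamily.HRM, 0.045, N=60)
        r1 = run_evolution(cfg, hz)
        r2 = run_evolution(cfg, hz)
        assert np.array_equal(r1.hist, r2.hist, equal_nan=True)
        assert np.array_equal(r1.final_death, r2.final_death,
                              equal_nan=True)

    def test_population_conserved_every_generation(self, tiny_run):
        cfg, hz, res = tiny_run
        ok = res.surviving
        # every recorded generation of a surviving replicate holds N traits
        assert np.isfinite(res.final_x[ok]).all()
        assert res.final_x[ok].shape[-1] == cfg.N

    def test_trait_invariance_under_neutral_conditions(self):
        """All traits equal and no mutation: the distribution never moves."""
        cfg = EvolutionConfig(N=50, G=10, replicates=2, seed=4, pm=0.0,
                              record_last=5)
        hz = default_hazard(HazardFamily.HRM, 0.02, N=50)
        rng = np.random.default_rng(0)
        gen = make_parents(np.full(50, 0.5),
                           np.full(50, 1e12))
        for _ in range(5):
            child = run_generation_continuous(gen, cfg, hz, rng)
            assert np.allclose(child.x, 0.5)
            child.death_time = np.full(50, 1e12)
            gen = child

    def test_all_extinct_raises_with_parameters(self):
        cfg = EvolutionConfig(N=30, G=5, replicates=3, seed=2)
        hz = HazardParams(family="HRM", a=0.5, b=0.5)   # nobody survives
        with pytest.raises(ExtinctionError, match="HRM"):
            run_evolution(cfg, hz)

    def test_oldest_old_pooling(self, tiny_run):
        _, _, res = tiny_run
        life_ex, old_ex = res.pooled_lifespans(include_oldest_old=False)
        life_in, old_in = res.pooled_lifespans(include_oldest_old=True)
        assert life_in.size >= life_ex.size
        assert not old_ex.any()
        # oldest-old removal never increases late-age exposure
        horizon = np.nanmean(res.fill_times)
        late_in = np.minimum(life_in[np.isfinite(life_in)], 10 * horizon)
        late_ex = np.minimum(life_ex, 10 * horizon)
        assert late_in.sum() >= late_ex.sum()
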