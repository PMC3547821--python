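"""Infinite-population operator tests: conservation and degenerate-input
contracts, discretization convergence, fixed-point behaviour, and the
Gamma-frailty closed form as an independent oracle for the mixture hazard."""

import numpy as np
import pytest
from scipy import stats

from evoaging import (
    HazardFamily,
    HazardParams,
    MutationKernel,
    TraitDistribution,
    apply_generation_operator,
    find_stationary,
    mortality_from_distribution,
    survival_from_distribution,
    within_generation_state,
)
from evoaging.deterministic import _Workspace
from evoaging.experiments import default_hazard


@pytest.fixture(scope="module")
def hz():
    return default_hazard(HazardFamily.HRM, 0.04)


class TestTraitDistribution:
    def test_validation(self):
        with pytest.raises(ValueError):
            TraitDistribution(grid=np.array([0.2, 0.1]),
                              mass=np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            TraitDistribution(grid=np.array([0.1, 0.2]),
                              mass=np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            TraitDistribution(grid=np.array([0.5, 1.2]),
                              mass=np.array([0.5, 0.5]))

    def test_uniform_and_coarsen(self):
        d = TraitDistribution.uniform(200)
        assert d.mass.sum() == pytest.approx(1.0, abs=1e-12)
        c = d.coarsen(50)
        assert c.mass.sum() == pytest.approx(1.0, abs=1e-12)
        assert c.mean() == pytest.approx(d.mean(), abs=1e-12)

    def test_from_samples(self, rng):
        d = TraitDistribution.from_samples(rng.random(10_000), 50)
        assert d.mass.sum() == pytest.approx(1.0)
        assert d.mean() == pytest.approx(0.5, abs=0.02)


class TestMutationKernel:
    def test_columns_are_distributions(self):
        d = TraitDistribution.uniform(100)
        for kern in (MutationKernel(pm=0.1),
                     MutationKernel(pm=0.1, kind="gaussian", sd=0.3)):
            m = kern.matrix(d)
            assert np.allclose(m.sum(axis=0), 1.0, atol=1e-9)
            assert (m >= 0).all()

    def test_gaussian_reflection_keeps_draws_in_unit_interval(self, rng):
        kern = MutationKernel(pm=1.0, kind="gaussian", sd=0.3)
        out = kern.draw(np.full(20_000, 0.05), rng)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_uniform_reset_draws_are_uniform(self, rng):
        kern = MutationKernel(pm=1.0)
        out = kern.draw(np.full(100_000, 0.9), rng)
        assert stats.ks_1samp(out, stats.uniform.cdf).statistic < 0.01


class TestWithinGenerationState:
    def test_initial_state_is_the_distribution(self, hz):
        d = TraitDistribution.uniform(100)
        assert np.allclose(within_generation_state(d, hz, 0.0), d.mass)

    def test_pointwise_nonincreasing_in_time(self, hz):
        d = TraitDistribution.uniform(100)
        n1 = within_generation_state(d, hz, 50.0)
        n2 = within_generation_state(d, hz, 200.0)
        assert (n2 <= n1 + 1e-15).all()

    def test_htm_zero_trait_mass_is_conserved(self):
        p = HazardParams(family="HTM", a=1e-3, b=0.02)
        # mass concentrated in the lowest bin; with a grid that includes
        # x = 0 exactly via a delta at the left edge the state is constant
        d = TraitDistribution(grid=np.array([0.0, 0.5]),
                              mass=np.array([1.0, 0.0]))
        for t in (10.0, 500.0):
            assert within_generation_state(d, p, t)[0] == pytest.approx(1.0)


class TestGenerationOperator:
    def test_full_mutation_yields_uniform(self, hz):
        start = TraitDistribution.delta(0.8, 100)
        out = apply_generation_operator(start, hz,
                                        MutationKernel(pm=1.0), 500.0)
        assert np.allclose(out.mass, 1.0 / 100, atol=1e-12)

    def test_no_mutation_keeps_delta(self, hz):
        start = TraitDistribution.delta(0.6, 100)
        out = apply_generation_operator(start, hz, None, 500.0)
        assert out.mass[np.argmax(start.mass)] == pytest.approx(1.0)

    def test_output_is_normalized(self, hz):
        out = apply_generation_operator(TraitDistribution.uniform(200), hz,
                                        MutationKernel(pm=0.05), 500.0)
        assert out.mass.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mass_scaling_cancels(self, hz):
        """The operator is invariant to the input's overall scale."""
        d = TraitDistribution.uniform(100)
        ws = _Workspace(hz, d, MutationKernel(pm=0.02), 500.0, 0.0, None)
        out1, _, _ = ws.apply(d.mass)
        out2, _, _ = ws.apply(7.3 * d.mass)
        assert np.allclose(out1, out2, atol=1e-14)

    def test_halving_dt_changes_output_below_tolerance(self, hz):
        d = TraitDistribution.uniform(200)
        out1 = apply_generation_operator(d, hz, MutationKernel(pm=0.01),
                                         500.0, dt=0.1)
        out2 = apply_generation_operator(d, hz, MutationKernel(pm=0.01),
                                         500.0, dt=0.05)
        assert np.abs(out1.mass - out2.mass).sum() < 1e-6

    def test_extinction_flagged_when_everyone_dies(self):
        # homogeneous frail population under a brutal hazard: the
        # reproductive weight underflows long before the window closes
        p = HazardParams(family="HRM", a=0.5, b=1.0)
        d = TraitDistribution.delta(0.9, 50)
        out, info = apply_generation_operator(d, p, None, 2000.0,
                                              full_output=True)
        assert info["extinct"]
        assert np.isfinite(info["extinction_time"])


class TestFindStationary:
    def test_no_mutation_converges_to_dominant_peak(self, hz):
        """Without mutation the distribution collapses onto one dominant
        strategy. (At mid-range environments a small second atom can
        persist at the high-investment end — the time-partitioned
        coexistence that maintains heterogeneity — so dominance, not total
        fixation, is asserted.)"""
        dist, info = find_stationary(hz, None, n_bins=100, t_fill=500.0,
                                     dt=0.5, tol=1e-10,
                                     max_generations=20000)
        assert info["converged"]
        assert dist.mass.max() > 0.9

    def test_fixed_point_is_stable(self, hz):
        dist, info = find_stationary(hz, MutationKernel(pm=0.01),
                                     n_bins=100, t_fill=500.0, dt=0.5,
                                     tol=1e-8, max_generations=25000)
        assert info["converged"]
        again = apply_generation_operator(dist, hz, MutationKernel(pm=0.01),
                                          500.0, dt=0.5)
        assert dist.l1_distance(again) < 1e-7

    def test_mean_trait_decreases_with_b(self):
        """Harsher environments select for maintenance (lower mean trait)."""
        means = []
        for b in (0.02, 0.04, 0.08):
            hz_b = default_hazard(HazardFamily.HRM, b)
            dist, _ = find_stationary(hz_b, MutationKernel(pm=0.01),
                                      n_bins=100, t_fill=500.0, dt=0.5,
                                      tol=1e-8, max_generations=25000)
            means.append(dist.mean())
        assert means[0] > means[1] > means[2]

    def test_nonconvergence_reported(self, hz):
        with pytest.warns(UserWarning, match="did not reach"):
            _, info = find_stationary(hz, MutationKernel(pm=0.01),
                                      n_bins=100, t_fill=500.0, dt=0.5,
                                      tol=1e-12, max_generations=5)
        assert not info["converged"]
        assert info["generations"] == 5


class TestMixtureMortality:
    def test_delta_equals_individual_hazard(self, hz):
        from evoaging import hazard as hazard_fn
        d = TraitDistribution.delta(0.5, 200)
        x_bin = d.grid[np.argmax(d.mass)]
        t_grid = np.linspace(0.0, 300.0, 31)
        curve = mortality_from_distribution(d, hz, t_grid)
        expect = hazard_fn(hz, x_bin, curve.ages)
        assert np.allclose(curve.hazard, expect, rtol=1e-12)

    def test_mixture_bounded_by_max_component(self, hz):
        from evoaging import hazard as hazard_fn
        d = TraitDistribution.uniform(100)
        t_grid = np.linspace(0.0, 400.0, 41)
        curve = mortality_from_distribution(d, hz, t_grid)
        upper = hazard_fn(hz, d.grid.max(), curve.ages)
        assert (curve.hazard <= upper + 1e-12).all()

    def test_gamma_frailty_closed_form(self):
        """Multiplicative Gamma frailty on the timing model reproduces the
        logistic population hazard a e^{bt} / (1 + (a s^2 / b)(e^{bt} - 1)).
        """
        a, b, var = 1e-3, 0.05, 0.5
        p = HazardParams(family="HTM", a=a, b=b, k=1.0)
        shape, scale = 1.0 / var, var      # mean 1, variance var
        z = np.linspace(1e-4, 12.0, 6000)
        mass = stats.gamma.pdf(z, shape, scale=scale)
        mass /= mass.sum()
        t_grid = np.linspace(0.0, 120.0, 61)
        curve = mortality_from_distribution((z, mass), p, t_grid)
        t = curve.ages
        expect = a * np.exp(b * t) / (1 + (a * var / b) * np.expm1(b * t))
        assert np.allclose(curve.hazard, expect, rtol=1e-3)

    def test_conditioned_curve_diverges_at_horizon(self, hz):
        d = TraitDistribution.uniform(100)
        t_grid = np.linspace(0.0, 500.0, 101)
        cond = mortality_from_distribution(d, hz, t_grid,
                                           condition_on_death_before=500.0)
        free = mortality_from_distribution(d, hz, t_grid)
        # conditioning on dying before the horizon inflates late hazards
        assert cond.hazard[-1] > 10 * free.hazard[-1]

    def test_survival_curve_contract(self, hz):
        d = TraitDistribution.uniform(100)
        sc = survival_from_distribution(d, hz, np.linspace(0, 400, 81))
        assert sc.fraction[0] == pytest.approx(1.0)
        assert (np.diff(sc.fraction) <= 1e-12).all()
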