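"""Infinite-population (deterministic) evolutionary dynamics.

The stochastic generation process has a deterministic counterpart acting on
densities: a generation is a trait distribution ``p(x)`` on [0, 1]; within a
generation individuals die according to their hazard, so the unnormalized
state at time ``t`` is ``n(x, t) = p(x) * S(x, t)``. Reproduction happens at
overall unit rate among the living, each birth choosing a parent with
probability proportional to its trait, so the offspring influx density is

    r(x, t) = x * n(x, t) / integral( x' * n(x', t) dx' ).

Because the total reproduction rate is constant, limiting the population
size is equivalent to limiting the overall time ``T_fill`` allowed for
reproduction (default ``T_fill = N = 500``: filling ``N`` slots at unit rate
takes about ``N`` time units). Accumulating births over the filling window,
with each birth mutating with probability ``pm`` through a kernel
``M(x | x')``, gives the next generation:

    q(x)  =  integral_m^T [ (1 - pm) * r(x, t) + pm * (M r)(x, t) ] dt,

normalized to unit mass. Iterating this operator converges to a stationary
trait distribution — the infinite-population analogue of the stochastic
quasi-stationary state — whose frailty-mixture population hazard

    mu_pop(t) = sum_x mu(x, t) p(x) S(x, t) / sum_x p(x) S(x, t)

produces the deterministic mortality curves.

Traits are discretized on a uniform midpoint grid (default 200 bins); time
integrals use the trapezoid rule with an adaptive step (default 0.1 time
units at the default window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sstats

from .demography import MortalityCurve, SurvivalCurve
from .hazards import (
    HazardParams,
    _intrinsic_cumulative,
    _intrinsic_hazard,
)

__all__ = [
    "TraitDistribution",
    "MutationKernel",
    "within_generation_state",
    "apply_generation_operator",
    "find_stationary",
    "mortality_from_distribution",
    "survival_from_distribution",
]

_UNDERFLOW = 1e-300


@dataclass
class TraitDistribution:
    """Discretized trait density: midpoints ``grid`` on [0, 1], ``mass`` sums to 1."""

    grid: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.mass.shape:
            raise ValueError("grid and mass must be 1-d arrays of equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.grid[0] < 0 or self.grid[-1] > 1:
            raise ValueError("grid must lie within [0, 1]")
        if np.any(self.mass < -1e-15):
            raise ValueError("masses must be nonnegative")
        self.mass = np.maximum(self.mass, 0.0)
        total = self.mass.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError(f"masses must sum to 1, got {total!r}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def uniform(cls, n_bins: int = 200) -> "TraitDistribution":
        grid = (np.arange(n_bins) + 0.5) / n_bins
        return cls(grid=grid, mass=np.full(n_bins, 1.0 / n_bins))

    @classmethod
    def delta(cls, x0: float, n_bins: int = 200) -> "TraitDistribution":
        """All mass in the bin containing ``x0``."""
        grid = (np.arange(n_bins) + 0.5) / n_bins
        mass = np.zeros(n_bins)
        mass[np.argmin(np.abs(grid - x0))] = 1.0
        return cls(grid=grid, mass=mass)

    @classmethod
    def from_samples(cls, x, n_bins: int = 200) -> "TraitDistribution":
        x = np.asarray(x, dtype=float)
        counts, _ = np.histogram(x, bins=n_bins, range=(0.0, 1.0))
        if counts.sum() == 0:
            raise ValueError("no samples in [0, 1]")
        grid = (np.arange(n_bins) + 0.5) / n_bins
        return cls(grid=grid, mass=counts / counts.sum())

    # -- helpers -----------------------------------------------------------

    @property
    def bin_width(self) -> float:
        return float(self.grid[1] - self.grid[0]) if self.grid.size > 1 else 1.0

    @property
    def edges(self) -> np.ndarray:
        w = self.bin_width
        return np.concatenate([self.grid - w / 2, [self.grid[-1] + w / 2]])

    def mean(self) -> float:
        return float(np.sum(self.grid * self.mass))

    def l1_distance(self, other: "TraitDistribution") -> float:
        return float(np.abs(self.mass - other.mass).sum())

    def coarsen(self, n_bins: int) -> "TraitDistribution":
        """Aggregate to a coarser uniform grid (must divide evenly)."""
        factor, rem = divmod(self.grid.size, n_bins)
        if rem:
            raise ValueError("coarse bin count must divide the grid size")
        mass = self.mass.reshape(n_bins, factor).sum(axis=1)
        grid = (np.arange(n_bins) + 0.5) / n_bins
        return TraitDistribution(grid=grid, mass=mass)


@dataclass
class MutationKernel:
    """Mutation process: with probability ``pm`` the offspring trait is redrawn.

    ``uniform_reset`` redraws from Uniform(0, 1) regardless of the parent;
    ``gaussian`` perturbs the parent value with a Normal(parent, sd) reflected
    into [0, 1].
    """

    pm: float
    kind: str = "uniform_reset"
    sd: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.pm <= 1:
            raise ValueError("mutation probability pm must lie in [0, 1]")
        if self.kind not in ("uniform_reset", "gaussian"):
            raise ValueError(f"unknown mutation kernel {self.kind!r}")
        if self.kind == "gaussian" and not self.sd > 0:
            raise ValueError("gaussian kernel needs sd > 0")

    def matrix(self, dist: TraitDistribution) -> np.ndarray:
        """Column-stochastic matrix M[i, j] = P(offspring bin i | parent bin j)."""
        n = dist.grid.size
        if self.kind == "uniform_reset":
            return np.full((n, n), 1.0 / n)
        edges = dist.edges
        mu = dist.grid[None, :]                      # parent values, columns
        m = np.zeros((n + 1, n))
        # reflected gaussian on [0, 1]: image centers 2k + mu and 2k - mu
        for kimg in range(-4, 5):
            for sign in (+1, -1):
                center = 2.0 * kimg + sign * mu
                m += _sstats.norm.cdf(edges[:, None], loc=center, scale=self.sd)
        mass = np.diff(m, axis=0)
        return mass / mass.sum(axis=0, keepdims=True)

    def draw(self, parent_x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Sample offspring traits for an array of parent traits."""
        parent_x = np.asarray(parent_x, dtype=float)
        out = parent_x.copy()
        hit = rng.random(parent_x.shape) < self.pm
        k = int(hit.sum())
        if k:
            if self.kind == "uniform_reset":
                out[hit] = rng.random(k)
            else:
                v = rng.normal(parent_x[hit], self.sd)
                folded = np.mod(np.abs(v), 2.0)
                out[hit] = np.minimum(folded, 2.0 - folded)
        return out


# ---------------------------------------------------------------------------
# within-generation dynamics and the generation operator


def _survival_matrix(hazard: HazardParams, grid: np.ndarray,
                     t: np.ndarray) -> np.ndarray:
    """S[i, j] = survival of trait grid[i] to time t[j]."""
    h = _intrinsic_cumulative(hazard.family, hazard.a, hazard.b, hazard.k,
                              grid[:, None], t[None, :])
    return np.exp(-(h + hazard.ext * t[None, :]))


def within_generation_state(dist: TraitDistribution, hazard: HazardParams,
                            t) -> np.ndarray:
    """Unnormalized trait-mass profile ``n(x, t) = p(x) * S(x, t)``.

    ``t`` may be a scalar (returns shape ``(bins,)``) or an array (returns
    ``(bins, len(t))``).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    s = _survival_matrix(hazard, dist.grid, t_arr)
    n = dist.mass[:, None] * s
    return n[:, 0] if np.ndim(t) == 0 else n


class _Workspace:
    """Precomputed quantities for repeated applications of the operator."""

    def __init__(self, hazard: HazardParams, dist: TraitDistribution,
                 kernel: MutationKernel | None, t_fill: float,
                 maturation: float, dt: float | None):
        if t_fill <= 0:
            raise ValueError("t_fill must be > 0")
        if maturation < 0:
            raise ValueError("maturation must be >= 0")
        window = t_fill
        n_steps = int(np.ceil(window / (0.1 if dt is None else dt)))
        n_steps = max(n_steps, 16)
        self.t = maturation + np.linspace(0.0, window, n_steps + 1)
        self.grid = dist.grid
        self.surv = _survival_matrix(hazard, dist.grid, self.t)
        self.xw = dist.grid  # reproduction weight ~ trait value
        # trapezoid weights over the time grid
        step = window / n_steps
        self.tw = np.full(n_steps + 1, step)
        self.tw[0] = self.tw[-1] = step / 2
        self.kernel = kernel
        self.kmat = None
        if kernel is not None and kernel.pm > 0:
            self.kmat = kernel.matrix(dist)

    def apply(self, mass: np.ndarray) -> tuple[np.ndarray, bool, float]:
        """One generation: returns (new mass, extinct flag, extinction time)."""
        w0 = self.xw * mass                      # x * p(x), decays as S(t)
        wtot = w0 @ self.surv                    # integral x' n(x', t) dx'
        alive = wtot > _UNDERFLOW
        extinct = not alive.all()
        t_ext = float(self.t[np.argmin(alive)]) if extinct else np.inf
        coef = np.where(alive, self.tw / np.where(alive, wtot, 1.0), 0.0)
        q = w0 * (self.surv @ coef)              # integral of r(x, t) dt
        total = q.sum()
        if total <= 0:
            return mass.copy(), True, t_ext
        q /= total
        if self.kernel is not None and self.kernel.pm > 0:
            pm = self.kernel.pm
            q = (1.0 - pm) * q + pm * (self.kmat @ q)
        q /= q.sum()
        return q, extinct, t_ext


def apply_generation_operator(dist: TraitDistribution, hazard: HazardParams,
                              kernel: MutationKernel | None = None,
                              t_fill: float = 500.0, *,
                              maturation: float = 0.0,
                              dt: float | None = None,
                              full_output: bool = False):
    """One application of the generation-to-generation operator.

    Returns the offspring :class:`TraitDistribution`; with ``full_output``,
    also a diagnostics dict (``extinct`` flags reproductive-weight underflow
    before the filling window closed — the infinite-population analogue of a
    generation failing to fill).
    """
    ws = _Workspace(hazard, dist, kernel, t_fill, maturation, dt)
    mass, extinct, t_ext = ws.apply(dist.mass)
    out = TraitDistribution(grid=dist.grid.copy(), mass=mass)
    if full_output:
        return out, {"extinct": extinct, "extinction_time": t_ext}
    return out


def find_stationary(hazard: HazardParams,
                    kernel: MutationKernel | None = None, *,
                    n_bins: int = 200, t_fill: float = 500.0,
                    maturation: float = 0.0, dt: float | None = None,
                    init: TraitDistribution | None = None,
                    tol: float = 1e-8, max_generations: int = 2000
                    ) -> tuple[TraitDistribution, dict]:
    """Iterate the generation operator to its fixed point.

    Starting from ``init`` (uniform by default), generations are applied
    until the L1 distance between successive distributions drops below
    ``tol`` or ``max_generations`` is reached. Returns the distribution and
    diagnostics (``generations``, ``final_distance``, ``converged``,
    ``extinct``).
    """
    dist = TraitDistribution.uniform(n_bins) if init is None else init
    ws = _Workspace(hazard, dist, kernel, t_fill, maturation, dt)
    mass = dist.mass.copy()
    distance = np.inf
    extinct_any = False
    gens = 0
    for gens in range(1, max_generations + 1):
        new_mass, extinct, _ = ws.apply(mass)
        extinct_any |= extinct
        distance = float(np.abs(new_mass - mass).sum())
        mass = new_mass
        if distance < tol:
            break
    converged = distance < tol
    if not converged:
        warnings.warn(
            f"operator iteration did not reach tol={tol} within "
            f"{max_generations} generations (final distance {distance:.3g})",
            stacklevel=2)
    out = TraitDistribution(grid=dist.grid.copy(), mass=mass)
    info = {"generations": gens, "final_distance": distance,
            "converged": converged, "extinct": extinct_any}
    return out, info


# ---------------------------------------------------------------------------
# population-level observables of a frozen trait distribution


def _mixture_arrays(dist, hazard: HazardParams, t: np.ndarray):
    """(mu_pop, S_pop) of the frailty mixture on the time grid ``t``.

    ``dist`` may be a TraitDistribution or a plain ``(grid, mass)`` pair; the
    grid need not lie in [0, 1] (e.g. an unbounded multiplicative frailty)."""
    if hasattr(dist, "grid"):
        grid, mass = dist.grid, dist.mass
    else:
        grid, mass = dist
        grid = np.asarray(grid, dtype=float)
        mass = np.asarray(mass, dtype=float)
        mass = mass / mass.sum()
    ch = _intrinsic_cumulative(hazard.family, hazard.a, hazard.b, hazard.k,
                               grid[:, None], t[None, :])
    s = np.exp(-(ch + hazard.ext * t[None, :]))
    mu = _intrinsic_hazard(hazard.family, hazard.a, hazard.b, hazard.k,
                           grid[:, None], t[None, :]) + hazard.ext
    s_pop = mass @ s
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_pop = (mass @ (mu * s)) / s_pop
    return mu_pop, s_pop


def mortality_from_distribution(dist, hazard: HazardParams, t_grid, *,
                                condition_on_death_before: float | None = None,
                                cohort: float = 1e6) -> MortalityCurve:
    """Population hazard of a frozen trait (frailty) distribution.

    ``t_grid`` supplies the bin edges; the hazard is evaluated exactly at bin
    midpoints as ``sum mu(x,t) p(x) S(x,t) / sum p(x) S(x,t)``. With
    ``condition_on_death_before = T`` the population is restricted to
    individuals dying before ``T`` (the deterministic counterpart of
    excluding the oldest-old), i.e. the hazard becomes
    ``f(t) / (S(t) - S(T))``. Bins where the denominator underflows are
    dropped and the curve flagged truncated. ``deaths``/``exposure`` are
    scaled to a nominal cohort so downstream weighting behaves as for
    estimated curves.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing with at least two points")
    if np.any(t_grid < 0):
        raise ValueError("t_grid must be >= 0")
    mids = 0.5 * (t_grid[:-1] + t_grid[1:])
    mu_mid, s_mid = _mixture_arrays(dist, hazard, mids)
    _, s_edge = _mixture_arrays(dist, hazard, t_grid)

    if condition_on_death_before is not None:
        big_t = float(condition_on_death_before)
        _, s_t = _mixture_arrays(dist, hazard, np.array([big_t]))
        s_tail = float(s_t[0])
        denom_mid = s_mid - s_tail
        denom_edge = np.maximum(s_edge - s_tail, 0.0)
        norm = 1.0 - s_tail
        if norm <= _UNDERFLOW:
            raise ValueError("no mass dies before the conditioning horizon")
        with np.errstate(invalid="ignore", divide="ignore"):
            haz = mu_mid * s_mid / denom_mid
        ok = denom_mid > _UNDERFLOW
        deaths = cohort * np.maximum(-np.diff(denom_edge), 0.0) / norm
        exposure = cohort * np.diff(t_grid) * denom_mid / norm
    else:
        haz = mu_mid
        ok = s_mid > _UNDERFLOW
        deaths = cohort * np.maximum(-np.diff(s_edge), 0.0)
        exposure = cohort * np.diff(t_grid) * s_mid

    reported = ok & np.isfinite(haz)
    truncated = bool((~reported).any())
    return MortalityCurve(edges=t_grid, deaths=np.where(reported, deaths, 0.0),
                          exposure=np.where(reported, exposure, 0.0),
                          hazard=np.where(reported, haz, np.nan),
                          reported=reported, truncated=truncated)


def survival_from_distribution(dist, hazard: HazardParams,
                               t_grid) -> SurvivalCurve:
    """Population survival ``S_pop(t) = sum p(x) S(x, t)`` of a frozen mixture."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0:
        t_grid = np.concatenate([[0.0], t_grid])
    _, s_pop = _mixture_arrays(dist, hazard, t_grid)
    return SurvivalCurve(ages=t_grid, fraction=s_pop)
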