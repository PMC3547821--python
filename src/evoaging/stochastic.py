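"""Finite-population evolutionary dynamics.

A generation is a cohort of ``N`` individuals, synchronized at age zero,
each carrying a heritable trait ``x`` in [0, 1]. The next generation is
filled by a competition for reproduction among the living:

* **continuous time** (used for all headline results): every individual's
  death time is drawn exactly from its hazard up front; reproduction events
  arrive as a unit-rate Poisson process (inter-event gaps ~ Exp(1), these
  being the only stochastic events once death times are known). At each
  event one parent is chosen among those still alive with probability
  proportional to its trait — a sole survivor therefore reproduces with
  probability one whatever its trait — and contributes one offspring, which
  mutates with probability ``pm``. The generation is filled when ``N``
  offspring exist; the elapsed time is the generation's ``fill_time``.
* **discrete time**: ages advance in unit steps; each step every living
  individual survives with probability ``1 - min(hazard, 1)`` (clamping is
  counted and warned about), then a Poisson(1) number of reproduction events
  occur among the survivors — matching the unit-rate continuous model in
  expectation.

Parents still alive when the next generation is complete never reproduce
again; they are the "oldest-old", flagged on the generation they reproduced
in and excluded from mortality curves unless explicitly included. If every
parent dies before the generation is filled the replicate goes extinct — a
flagged outcome, not an exception, except when every replicate dies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .deterministic import MutationKernel, TraitDistribution
from .hazards import HazardParams, draw_death_time

__all__ = [
    "EvolutionConfig",
    "GenerationRecord",
    "EvolutionResult",
    "ExtinctionError",
    "init_population",
    "choose_parent",
    "mutate_offspring",
    "run_generation_continuous",
    "run_generation_discrete",
    "run_evolution",
    "stabilization_generation",
]

logger = logging.getLogger("evoaging")


class ExtinctionError(RuntimeError):
    """Raised when evolution cannot proceed (e.g. every replicate extinct)."""


@dataclass(frozen=True)
class EvolutionConfig:
    """Parameters of the evolutionary algorithm.

    Defaults follow the headline setting: populations of 500 individuals
    evolved for 400 generations, mutation probability 0.01 with uniform
    redraw, asexual reproduction, no maturation delay, continuous-time
    engine, 300 replicates.
    """

    N: int = 500
    G: int = 400
    pm: float = 0.01
    kernel: str = "uniform_reset"          # or "gaussian"
    kernel_sd: float = 0.3
    reproduction: str = "asexual"          # or "sexual"
    maturation: float = 0.0
    engine: str = "continuous"             # or "discrete"
    replicates: int = 300
    seed: int = 0
    hist_bins: int = 50
    record_last: int = 5                   # stationary generations kept in full
    discrete_horizon_factor: float = 20.0  # post-fill death-tracking horizon

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if self.G < 1:
            raise ValueError("generations G must be >= 1")
        if not 0 <= self.pm <= 1:
            raise ValueError("mutation probability pm must lie in [0, 1]")
        if self.maturation < 0:
            raise ValueError("maturation delay must be >= 0")
        if self.kernel not in ("uniform_reset", "gaussian"):
            raise ValueError(f"unknown mutation kernel {self.kernel!r}")
        if self.reproduction not in ("asexual", "sexual"):
            raise ValueError(f"unknown reproduction mode {self.reproduction!r}")
        if self.engine not in ("continuous", "discrete", "deterministic"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.record_last < 1:
            raise ValueError("record_last must be >= 1")

    @property
    def effective_record_last(self) -> int:
        """Recorded stationary generations, capped by the run length."""
        return min(self.record_last, self.G)

    @property
    def mutation_kernel(self) -> MutationKernel:
        return MutationKernel(pm=self.pm, kind=self.kernel, sd=self.kernel_sd)


@dataclass
class GenerationRecord:
    """One cohort: traits, exact death times, and oldest-old flags.

    ``oldest_old`` marks parents whose death time exceeded the time it took
    to fill the *next* generation (the one they reproduced in); it is set
    when that next generation is built. ``fill_time`` is the time this
    cohort itself took to fill, measured on its parents' clock.
    """

    x: np.ndarray
    death_time: np.ndarray
    oldest_old: np.ndarray
    fill_time: float = np.nan
    extinct: bool = False
    generation_index: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.death_time = np.asarray(self.death_time, dtype=float)
        self.oldest_old = np.asarray(self.oldest_old, dtype=bool)

    @property
    def size(self) -> int:
        return self.x.size


def init_population(config: EvolutionConfig, hazard: HazardParams,
                    rng: np.random.Generator) -> GenerationRecord:
    """Founding cohort: traits ~ Uniform(0, 1), death times from the hazard."""
    x = rng.random(config.N)
    death = draw_death_time(hazard, x, rng)
    return GenerationRecord(x=x, death_time=death,
                            oldest_old=np.zeros(config.N, dtype=bool),
                            generation_index=0)


def choose_parent(alive_traits, rng: np.random.Generator) -> int:
    """Index of the reproducing parent among the living.

    Selection probability is ``x_i / sum(x_alive)``; if every living trait is
    zero the choice is uniform, so a sole survivor reproduces with
    probability one regardless of its trait.
    """
    alive_traits = np.asarray(alive_traits, dtype=float)
    if alive_traits.size == 0:
        raise ExtinctionError("no living individuals to choose a parent from")
    total = alive_traits.sum()
    if total <= 0:
        return int(rng.integers(alive_traits.size))
    cum = np.cumsum(alive_traits)
    return int(np.searchsorted(cum, rng.random() * total, side="right"))


def mutate_offspring(parent_x, config: EvolutionConfig,
                     rng: np.random.Generator):
    """Offspring trait: the parent's, or a kernel redraw with probability pm."""
    parent_x = np.asarray(parent_x, dtype=float)
    if np.any(parent_x < 0) or np.any(parent_x > 1):
        raise ValueError("parent trait must lie in [0, 1]")
    out = config.mutation_kernel.draw(np.atleast_1d(parent_x), rng)
    return float(out[0]) if parent_x.ndim == 0 else out


def _weighted_pick(cum_w: np.ndarray, m: np.ndarray,
                   u: np.ndarray) -> np.ndarray:
    """Vectorized weighted choice among the first ``m_j`` entries per event.

    ``cum_w`` is the prefix-sum of weights of parents sorted by decreasing
    death time, so the living set at any event is exactly a prefix. Events
    whose living prefix has zero total weight fall back to a uniform pick.
    """
    totals = cum_w[m - 1]
    idx = np.searchsorted(cum_w, u * totals, side="right")
    idx = np.minimum(idx, m - 1)
    zero = totals <= 0
    if zero.any():
        idx[zero] = np.floor(u[zero] * m[zero]).astype(np.int64)
        idx[zero] = np.minimum(idx[zero], m[zero] - 1)
    return idx


def _second_parent(order_x: np.ndarray, cum_w: np.ndarray, m: np.ndarray,
                   first: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Second weighted draw without replacement (sexual reproduction).

    Rejection against the first pick, with an exact fallback for events
    where the first parent carries (almost) all the weight. Events with a
    single living individual self: the sole survivor reproduces alone.
    """
    idx2 = _weighted_pick(cum_w, m, rng.random(first.size))
    clash = (idx2 == first) & (m > 1)
    for _ in range(20):
        if not clash.any():
            break
        idx2[clash] = _weighted_pick(cum_w[:], m[clash],
                                     rng.random(int(clash.sum())))
        clash = (idx2 == first) & (m > 1)
    if clash.any():
        for j in np.flatnonzero(clash):
            w = order_x[:m[j]].copy()
            w[first[j]] = 0.0
            tot = w.sum()
            if tot <= 0:
                others = np.flatnonzero(np.arange(m[j]) != first[j])
                idx2[j] = others[rng.integers(others.size)]
            else:
                idx2[j] = np.searchsorted(np.cumsum(w), rng.random() * tot,
                                          side="right")
    return idx2


def run_generation_continuous(parents: GenerationRecord,
                              config: EvolutionConfig, hazard: HazardParams,
                              rng: np.random.Generator) -> GenerationRecord:
    """Fill the next generation in continuous time (pre-drawn death times).

    Mutates ``parents`` in place only to set its ``fill_time`` and
    ``oldest_old`` flags once the offspring generation is complete.
    """
    if parents.extinct:
        raise ExtinctionError("cannot breed from an extinct generation")
    n = config.N
    order = np.argsort(-parents.death_time, kind="stable")
    d_sorted = parents.death_time[order]
    x_sorted = parents.x[order]
    cum_w = np.cumsum(x_sorted)

    times = config.maturation + np.cumsum(rng.exponential(1.0, size=n))
    # living count at each event: parents with death_time > t form a prefix
    asc = d_sorted[::-1]
    m = parents.size - np.searchsorted(asc, times, side="right")
    m = m.astype(np.int64)

    dead_at = np.flatnonzero(m == 0)
    n_off = int(dead_at[0]) if dead_at.size else n
    extinct = n_off < n
    times = times[:n_off]
    m = m[:n_off]
    fill_time = float(times[-1]) if n_off else float(config.maturation)

    if n_off:
        first = _weighted_pick(cum_w, m, rng.random(n_off))
        if config.reproduction == "sexual":
            second = _second_parent(x_sorted, cum_w, m, first, rng)
            child_x = 0.5 * (x_sorted[first] + x_sorted[second])
        else:
            child_x = x_sorted[first].copy()
        child_x = config.mutation_kernel.draw(child_x, rng)
        child_death = draw_death_time(hazard, child_x, rng)
    else:
        child_x = np.empty(0)
        child_death = np.empty(0)

    parents.fill_time = fill_time
    parents.oldest_old = parents.death_time > fill_time
    if extinct:
        parents.oldest_old[:] = False  # nobody outlived an unfilled generation
    return GenerationRecord(x=child_x, death_time=child_death,
                            oldest_old=np.zeros(n_off, dtype=bool),
                            extinct=extinct,
                            generation_index=parents.generation_index + 1)


def run_generation_discrete(parents: GenerationRecord,
                            config: EvolutionConfig, hazard: HazardParams,
                            rng: np.random.Generator) -> GenerationRecord:
    """Fill the next generation in unit time steps.

    Each step: every living parent survives with probability
    ``1 - min(mu(x, age), 1)`` (hazard used as a death probability; values
    above one are clamped and logged), then Poisson(1) reproduction events
    draw parents among the survivors. After the generation fills, the
    survivors' deaths keep being simulated (without reproduction) up to
    ``discrete_horizon_factor * fill_time`` so their lifespans and
    oldest-old status are known; stragglers get the infinity sentinel.
    """
    if parents.extinct:
        raise ExtinctionError("cannot breed from an extinct generation")
    from .hazards import hazard as hazard_fn

    n = config.N
    alive = np.ones(parents.size, dtype=bool)
    death = np.full(parents.size, np.inf)
    child_x: list[float] = []
    clamped = 0
    age = 0
    fill_time = np.nan
    extinct = False

    horizon = None
    while True:
        age += 1
        mu = hazard_fn(hazard, parents.x[alive], float(age))
        mu = np.atleast_1d(mu)
        over = mu > 1.0
        if over.any():
            clamped += int(over.sum())
        p_die = np.minimum(mu, 1.0)
        dies = rng.random(p_die.size) < p_die
        idx_alive = np.flatnonzero(alive)
        death[idx_alive[dies]] = float(age)
        alive[idx_alive[dies]] = False

        filling = len(child_x) < n
        if filling:
            if not alive.any():
                extinct = True
                break
            if age > config.maturation:
                k = rng.poisson(1.0)
                traits_alive = parents.x[alive]
                for _ in range(int(k)):
                    if len(child_x) >= n:
                        break
                    child_x.append(traits_alive[choose_parent(traits_alive, rng)])
            if len(child_x) >= n:
                fill_time = float(age)
                horizon = max(config.discrete_horizon_factor * fill_time,
                              fill_time + 1)
        else:
            if not alive.any() or age >= horizon:
                break

    if clamped:
        msg = f"hazard exceeded 1 in {clamped} survival tests; clamped"
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)

    parents.death_time = death
    parents.fill_time = fill_time
    if extinct:
        parents.oldest_old = np.zeros(parents.size, dtype=bool)
    else:
        parents.oldest_old = death > fill_time

    child_x_arr = np.asarray(child_x, dtype=float)
    if config.pm > 0 and child_x_arr.size:
        child_x_arr = config.mutation_kernel.draw(child_x_arr, rng)
    return GenerationRecord(x=child_x_arr,
                            death_time=np.full(child_x_arr.size, np.nan),
                            oldest_old=np.zeros(child_x_arr.size, dtype=bool),
                            extinct=extinct,
                            generation_index=parents.generation_index + 1)


@dataclass
class EvolutionResult:
    """Multi-replicate evolution output.

    ``hist`` holds per-replicate, per-generation trait histograms
    (frequencies over ``hist_edges``), shape ``(R, G + 1, bins)``. The last
    ``record_last`` quasi-stationary generations of each surviving replicate
    are kept in full — traits, exact death times and oldest-old flags, shape
    ``(R, K, N)`` — so lifespans can be pooled over both replicates and
    stationary generations. Extinct replicates carry NaN histograms from
    their extinction generation on and are excluded from ensemble averages.
    """

    config: EvolutionConfig
    hazard: HazardParams
    hist_edges: np.ndarray
    hist: np.ndarray
    final_x: np.ndarray            # (R, K, N), NaN for extinct replicates
    final_death: np.ndarray        # (R, K, N)
    final_oldest_old: np.ndarray   # (R, K, N)
    fill_times: np.ndarray         # (R, G)
    extinct_at: np.ndarray         # (R,) generation of extinction, -1 if none
    replicate_seeds: list = field(default_factory=list)

    @property
    def surviving(self) -> np.ndarray:
        return self.extinct_at < 0

    @property
    def extinction_fraction(self) -> float:
        return float((~self.surviving).mean())

    def ensemble_histogram(self, generation: int) -> np.ndarray:
        """Trait histogram at one generation, averaged over surviving replicates."""
        h = self.hist[self.surviving, generation, :]
        if h.size == 0:
            raise ExtinctionError("no surviving replicates")
        return h.mean(axis=0)

    def ensemble_l1_series(self) -> np.ndarray:
        """L1 distance between consecutive ensemble-averaged histograms."""
        h = self.hist[self.surviving, :, :].mean(axis=0)
        return np.abs(np.diff(h, axis=0)).sum(axis=1)

    def pooled_lifespans(self, include_oldest_old: bool = False
                         ) -> tuple[np.ndarray, np.ndarray]:
        """(lifespan, oldest_old flag) pooled over surviving replicates and
        the recorded quasi-stationary generations."""
        keep = self.surviving
        life = self.final_death[keep].ravel()
        old = self.final_oldest_old[keep].ravel()
        ok = np.isfinite(life) | include_oldest_old
        if not include_oldest_old:
            ok &= ~old
        return life[ok], old[ok]

    def pooled_traits(self) -> np.ndarray:
        return self.final_x[self.surviving].ravel()

    def pooled_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(trait, lifespan) pairs pooled over replicates and recorded
        generations (finite lifespans only)."""
        keep = self.surviving
        x = self.final_x[keep].ravel()
        life = self.final_death[keep].ravel()
        ok = np.isfinite(life)
        return x[ok], life[ok]

    def stationary_distribution(self, n_bins: int = 200) -> TraitDistribution:
        return TraitDistribution.from_samples(self.pooled_traits(), n_bins)


def _run_replicate(config: EvolutionConfig, hazard: HazardParams,
                   rng: np.random.Generator, edges: np.ndarray):
    """One replicate; returns (hist, last-K records or None, fill_times, ext_gen)."""
    runner = (run_generation_continuous if config.engine == "continuous"
              else run_generation_discrete)
    gen = init_population(config, hazard, rng)
    hist = np.full((config.G + 1, edges.size - 1), np.nan)
    fill_times = np.full(config.G, np.nan)
    hist[0] = np.histogram(gen.x, bins=edges)[0] / gen.size
    kept: list[GenerationRecord] = []
    k = config.effective_record_last
    for g in range(1, config.G + 1):
        child = runner(gen, config, hazard, rng)
        fill_times[g - 1] = gen.fill_time
        if child.extinct:
            return hist, None, fill_times, g
        hist[g] = np.histogram(child.x, bins=edges)[0] / child.size
        if g > config.G - k:
            kept.append(gen)  # flags already set by this filling
        gen = child
    # one extra filling determines the final generation's oldest-old flags
    flagger = runner(gen, config, hazard, rng)
    if flagger.extinct:
        return hist, None, fill_times, config.G + 1
    kept.append(gen)
    return hist, kept[-k:], fill_times, -1


def run_evolution(config: EvolutionConfig,
                  hazard: HazardParams) -> EvolutionResult:
    """Evolve ``replicates`` independent populations for ``G`` generations.

    Replicate random streams are spawned deterministically from the master
    seed, so the same configuration reproduces bit-identical results. The
    final generation of each surviving replicate is bred one extra time
    (discarded) purely to measure its filling period and flag its
    oldest-old. Raises :class:`ExtinctionError` if every replicate dies out.
    """
    if config.engine == "deterministic":
        raise ValueError("run_evolution handles the stochastic engines; "
                         "use deterministic.find_stationary (or "
                         "experiments.evolve_stationary) instead")
    edges = np.linspace(0.0, 1.0, config.hist_bins + 1)
    seed_seq = np.random.SeedSequence(config.seed)
    children = seed_seq.spawn(config.replicates)

    k = config.effective_record_last
    hist = np.full((config.replicates, config.G + 1, config.hist_bins), np.nan)
    final_x = np.full((config.replicates, k, config.N), np.nan)
    final_death = np.full((config.replicates, k, config.N), np.nan)
    final_old = np.zeros((config.replicates, k, config.N), dtype=bool)
    fill_times = np.full((config.replicates, config.G), np.nan)
    extinct_at = np.full(config.replicates, -1, dtype=int)

    for r, child_seq in enumerate(children):
        rng = np.random.default_rng(child_seq)
        h, kept, ft, ext = _run_replicate(config, hazard, rng, edges)
        hist[r] = h
        fill_times[r] = ft
        extinct_at[r] = ext
        if kept is not None:
            for j, rec in enumerate(kept):
                final_x[r, j] = rec.x
                final_death[r, j] = rec.death_time
                final_old[r, j] = rec.oldest_old

    if (extinct_at >= 0).all():
        raise ExtinctionError(
            f"all {config.replicates} replicates went extinct "
            f"(N={config.N}, family={hazard.family.value}, a={hazard.a}, "
            f"b={hazard.b}, pm={config.pm})")
    n_ext = int((extinct_at >= 0).sum())
    if n_ext:
        logger.warning("%d/%d replicates went extinct", n_ext,
                       config.replicates)

    return EvolutionResult(config=config, hazard=hazard, hist_edges=edges,
                           hist=hist, final_x=final_x,
                           final_death=final_death,
                           final_oldest_old=final_old, fill_times=fill_times,
                           extinct_at=extinct_at,
                           replicate_seeds=[c.entropy for c in children])


def stabilization_generation(result: EvolutionResult,
                             tol: float = 0.01) -> int:
    """First generation from which consecutive ensemble-averaged trait
    histograms stay within L1 distance ``tol`` of each other.

    Returns ``G`` (the last simulated generation) if the sequence never
    settles below ``tol`` within the run.
    """
    d = result.ensemble_l1_series()
    above = np.flatnonzero(d >= tol)
    if above.size == 0:
        return 0
    first = int(above[-1]) + 1
    return min(first, result.config.G)
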