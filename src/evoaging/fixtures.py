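"""Constructed small datasets exercising every analysis path.

All fixtures are generated programmatically and deterministically from a
seed: piecewise log-linear mortality curves covering the five shape classes,
unimodal/bimodal lifespan samples, a two-group "medfly-like" Gompertz
mixture with a long-lived subgroup, and a tiny evolution run.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .demography import MortalityCurve
from .experiments import default_b_grid, default_hazard
from .hazards import HazardFamily, HazardParams, draw_death_time
from .stochastic import EvolutionConfig, run_evolution

__all__ = [
    "piecewise_log_hazard_curve",
    "SHAPE_FIXTURE_SEGMENTS",
    "bimodal_lifespans",
    "unimodal_lifespans",
    "medfly_mixture",
    "tiny_evolution",
    "make_fixtures",
]

#: Piecewise log-hazard slopes (duration, slope) per shape class, one bin per
#: unit age. Mirrors the canonical exponential-X-exponential patterns.
SHAPE_FIXTURE_SEGMENTS = {
    "kink": [(60, 0.05), (40, 0.2)],
    "slowdown": [(40, 0.1), (30, 0.03), (30, 0.1)],
    "plateau": [(40, 0.1), (30, 0.0), (30, 0.1)],
    "decrease": [(40, 0.1), (20, -0.02), (40, 0.1)],
    "u_shape": [(40, 0.1), (20, -0.06), (40, 0.1)],
}


def piecewise_log_hazard_curve(kind: str, *, log_h0: float = -7.0,
                               exposure: float = 1e6) -> MortalityCurve:
    """Noise-free mortality curve with the given piecewise log-linear shape."""
    segments = SHAPE_FIXTURE_SEGMENTS[kind]
    slopes = np.concatenate([np.full(n, s) for n, s in segments])
    logh = log_h0 + np.concatenate([[0.0], np.cumsum(slopes)])[:-1] \
        + slopes * 0.5
    n = slopes.size
    edges = np.arange(n + 1, dtype=float)
    hazard = np.exp(logh)
    expo = np.full(n, exposure)
    return MortalityCurve(edges=edges, deaths=hazard * expo, exposure=expo,
                          hazard=hazard, reported=np.ones(n, dtype=bool))


def bimodal_lifespans(rng: np.random.Generator, n: int = 2000) -> np.ndarray:
    """Two well-separated clusters of lifespans."""
    k = n // 2
    return np.concatenate([rng.normal(30.0, 3.0, k),
                           rng.normal(70.0, 4.0, n - k)])


def unimodal_lifespans(rng: np.random.Generator, n: int = 2000) -> np.ndarray:
    return rng.normal(50.0, 8.0, n)


def medfly_mixture(rng: np.random.Generator, n: int = 100_000,
                   long_lived_fraction: float = 0.05) -> np.ndarray:
    """Lifespan mixture exhibiting the five medfly mortality features.

    The bulk has a high initial mortality and mild aging, so the population
    hazard rises to a first local maximum and collapses once the bulk is
    gone (the U-dip). A small long-lived subgroup with a far lower initial
    mortality but a steeper aging slope then drives the hazard to a second,
    higher maximum; heterogeneity of aging rate inside that subgroup makes
    the frailest of it die first, so the very end of the curve declines.
    """
    fast = HazardParams(family=HazardFamily.HRM, a=0.02, b=0.02)
    slow = HazardParams(family=HazardFamily.HRM, a=1e-5, b=0.1)
    n_slow = int(round(n * long_lived_fraction))
    n_tail = int(round(0.3 * n_slow))
    life_fast = draw_death_time(fast, np.ones(n - n_slow), rng)
    # concentrated core -> sharp second peak; dispersed rates -> decline
    x_slow = np.concatenate([rng.uniform(0.85, 1.0, n_slow - n_tail),
                             rng.uniform(0.55, 0.85, n_tail)])
    life_slow = draw_death_time(slow, x_slow, rng)
    return np.concatenate([life_fast, life_slow])


def tiny_evolution(seed: int = 0):
    """A seconds-scale evolution run (N=50, G=20, R=5) for smoke tests."""
    config = EvolutionConfig(N=50, G=20, replicates=5, seed=seed,
                             record_last=5)
    hazard = default_hazard(HazardFamily.HRM,
                            default_b_grid(HazardFamily.HRM)[2], N=config.N)
    return config, hazard, run_evolution(config, hazard)


def make_fixtures(seed: int, outdir: Path) -> list[Path]:
    """Write every fixture as a small CSV; fully reproducible from ``seed``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []

    for kind in SHAPE_FIXTURE_SEGMENTS:
        curve = piecewise_log_hazard_curve(kind)
        df = pd.DataFrame({"t_left": curve.edges[:-1],
                           "t_right": curve.edges[1:],
                           "deaths": curve.deaths,
                           "exposure": curve.exposure,
                           "hazard": curve.hazard})
        p = outdir / f"shape_{kind}.csv"
        df.to_csv(p, index=False)
        paths.append(p)

    samples = {
        "lifespans_bimodal": bimodal_lifespans(rng, 2000),
        "lifespans_unimodal": unimodal_lifespans(rng, 2000),
        "lifespans_medfly": medfly_mixture(rng, 20_000),
    }
    for name, life in samples.items():
        p = outdir / f"{name}.csv"
        pd.DataFrame({"death_time": life}).to_csv(p, index=False)
        paths.append(p)

    config, hazard, result = tiny_evolution(seed)
    rows = []
    for r in np.flatnonzero(result.surviving):
        for j in range(config.record_last):
            rows.append(pd.DataFrame({
                "replicate": r, "generation": config.G - config.record_last + 1 + j,
                "x": result.final_x[r, j],
                "death_time": result.final_death[r, j],
                "oldest_old": result.final_oldest_old[r, j].astype(int)}))
    p = outdir / "tiny_lifespans.csv"
    pd.concat(rows, ignore_index=True).to_csv(p, index=False)
    paths.append(p)
    return paths
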