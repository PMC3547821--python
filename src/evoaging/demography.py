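"""Population-level observables from individual lifespans.

Age-specific mortality is estimated as a central death rate (deaths divided
by person-time exposure per age bin), the convention that stays stable under
coarse binning. Survival curves are plain empirical survivor functions (the
simulations are uncensored). On top of these sit the qualitative tools used
to compare simulated populations with experimental aging data:

* a shape classifier for log-mortality curves, labelling the canonical
  progression ``kink -> slowdown -> plateau -> decrease -> u_shape`` seen
  across species as the environment parameter grows;
* a modality analysis of lifespan distributions (kernel-density mode count
  plus the Hartigan dip statistic with a bootstrap p-value), used to probe
  the notion of "subpopulations";
* tail truncation of trait distributions, which dissolves lifespan
  bimodality when the trait-lifespan map is strongly non-linear.

The dip statistic is computed with a prefix-hull formulation: for every
candidate modal position the best unimodal cdf deviates from the empirical
cdf by half the largest hull violation on either side, and the optimum is
found by bisection over the (monotone) left/right deviation profiles.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal, stats

__all__ = [
    "MortalityCurve",
    "SurvivalCurve",
    "Shape",
    "ShapeLabel",
    "ModalityResult",
    "estimate_mortality",
    "estimate_survival",
    "classify_shape",
    "lifespan_modality",
    "dip_statistic",
    "dip_test",
    "truncate_trait_tail",
]


# ---------------------------------------------------------------------------
# curve containers


@dataclass
class MortalityCurve:
    """Binned age-specific mortality.

    ``hazard`` is deaths/exposure for estimated curves, or the exact mixture
    hazard for curves derived from a trait distribution. ``reported`` masks
    bins whose exposure passed the reporting threshold.
    """

    edges: np.ndarray          # bin edges, length n+1
    deaths: np.ndarray         # deaths per bin, length n
    exposure: np.ndarray       # person-time per bin, length n
    hazard: np.ndarray         # per unit time, length n
    reported: np.ndarray       # bool mask, length n
    truncated: bool = False    # curve cut short by exposure/denominator underflow

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=float)
        self.hazard = np.asarray(self.hazard, dtype=float)
        self.reported = np.asarray(self.reported, dtype=bool)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.deaths < 0):
            raise ValueError("deaths must be >= 0")

    @property
    def ages(self) -> np.ndarray:
        """Bin midpoints."""
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def log_hazard(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.hazard)

    def reported_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(ages, log_hazard) restricted to reported bins with positive hazard."""
        m = self.reported & np.isfinite(self.hazard) & (self.hazard > 0)
        return self.ages[m], np.log(self.hazard[m])


@dataclass
class SurvivalCurve:
    """Empirical (or mixture) survivor function: nonincreasing, S(0) = 1."""

    ages: np.ndarray
    fraction: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.ages[0] != 0 or not np.isclose(self.fraction[0], 1.0):
            raise ValueError("survival curve must start at S(0) = 1")
        if np.any(np.diff(self.fraction) > 1e-12):
            raise ValueError("survival curve must be nonincreasing")

    def evaluate(self, t) -> np.ndarray:
        """Right-continuous step/linear evaluation of S(t)."""
        idx = np.searchsorted(self.ages, np.asarray(t, dtype=float), side="right") - 1
        idx = np.clip(idx, 0, self.fraction.size - 1)
        return self.fraction[idx]


class Shape(str, enum.Enum):
    """Qualitative mortality-curve patterns between the two exponential phases."""

    KINK = "kink"
    SLOWDOWN = "slowdown"
    PLATEAU = "plateau"
    DECREASE = "decrease"
    U_SHAPE = "u_shape"


@dataclass
class ShapeLabel:
    shape: Shape
    boundaries: tuple[float, float]     # ages bracketing the mid-age transition
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.boundaries
        if hi < lo:
            raise ValueError("phase boundaries must be ordered")


@dataclass
class ModalityResult:
    mode_count: int
    dip: float
    p_value: float


# ---------------------------------------------------------------------------
# estimators


def _as_edges(lifespans: np.ndarray, bins) -> np.ndarray:
    finite = lifespans[np.isfinite(lifespans)]
    if bins is None:
        bins = 100
    if np.isscalar(bins):
        upper = float(finite.max()) if finite.size else 1.0
        edges = np.linspace(0.0, upper * (1 + 1e-9), int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    return edges


def estimate_mortality(lifespans, bins=None, *, oldest_old=None,
                       include_oldest_old=False,
                       min_exposure=0.0) -> MortalityCurve:
    """Central death rate per age bin from exact lifespans.

    Each individual contributes person-time ``min(death, bin_right) -
    bin_left`` to every bin it is alive in, and one death event to the bin
    containing its death. Individuals flagged ``oldest_old`` (those outliving
    their generation's filling period) are dropped entirely unless
    ``include_oldest_old``; infinite lifespans (the never-dying sentinel)
    contribute exposure but no death, and only appear when the flag is on.

    Bins with exposure below ``min_exposure`` (or zero) are left unreported.
    """
    lifespans = np.asarray(lifespans, dtype=float)
    if lifespans.size == 0:
        raise ValueError("no lifespans supplied")
    if np.any(lifespans[np.isfinite(lifespans)] <= 0):
        raise ValueError("lifespans must be positive")
    if oldest_old is not None:
        oldest_old = np.asarray(oldest_old, dtype=bool)
        if not include_oldest_old:
            lifespans = lifespans[~oldest_old]
    if not include_oldest_old:
        lifespans = lifespans[np.isfinite(lifespans)]
    if lifespans.size == 0:
        raise ValueError("no lifespans remain after oldest-old exclusion")

    edges = _as_edges(lifespans, bins)
    n = lifespans.size
    finite = np.sort(lifespans[np.isfinite(lifespans)])
    deaths, _ = np.histogram(finite, bins=edges)
    deaths = deaths.astype(float)

    # total person-time lived before t: sum_i min(d_i, t)
    cums = np.concatenate([[0.0], np.cumsum(finite)])

    def person_time(t: np.ndarray) -> np.ndarray:
        k = np.searchsorted(finite, t, side="right")
        return cums[k] + (n - k) * t

    pt = person_time(edges)
    exposure = np.diff(pt)

    reported = exposure > max(min_exposure, 0.0)
    if not reported.any():
        warnings.warn("all bins suppressed by the exposure threshold",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        haz = np.where(exposure > 0, deaths / np.where(exposure > 0, exposure, 1.0),
                       np.nan)
    return MortalityCurve(edges=edges, deaths=deaths, exposure=exposure,
                          hazard=haz, reported=reported)


def estimate_survival(lifespans) -> SurvivalCurve:
    """Empirical survivor function, S(t) = fraction with lifespan > t."""
    lifespans = np.asarray(lifespans, dtype=float)
    if lifespans.size == 0:
        raise ValueError("no lifespans supplied")
    n = lifespans.size
    finite = np.sort(lifespans[np.isfinite(lifespans)])
    ages, counts = np.unique(finite, return_counts=True)
    frac = 1.0 - np.cumsum(counts) / n
    return SurvivalCurve(ages=np.concatenate([[0.0], ages]),
                         fraction=np.concatenate([[1.0], frac]))


# ---------------------------------------------------------------------------
# shape classification


def _smooth_log_hazard(curve: MortalityCurve, smoothing: float | None = None):
    """Weighted smoothing spline of log-hazard over reported bins.

    Weights are sqrt(deaths), so Poisson noise in the log-rate has unit
    weighted variance and the default smoothing factor (one per bin) is on
    the chi-square scale.
    """
    ages, logh = curve.reported_arrays()
    if ages.size < 10:
        raise ValueError(f"need >= 10 reported bins, have {ages.size}")
    m = curve.reported & np.isfinite(curve.hazard) & (curve.hazard > 0)
    w = np.sqrt(np.maximum(curve.deaths[m], 1.0))
    s = float(ages.size) if smoothing is None else smoothing
    k = 3 if ages.size > 3 else ages.size - 1
    spl = interpolate.UnivariateSpline(ages, logh, w=w, k=k, s=s)
    return spl, ages


def classify_shape(curve: MortalityCurve, *, theta0: float = 0.1,
                   theta1: float = 0.5, delta: float = 0.5,
                   recovery_min: float = 0.1,
                   early_frac: float = 0.15, late_frac: float = 0.15,
                   smoothing: float | None = None) -> ShapeLabel:
    """Label the qualitative pattern of a log-mortality curve.

    The log-hazard is smoothed with a spline; its derivative over the
    mid-age window — between the early exponential phase (whose end is
    detected as the first downcross of the derivative below ``theta1``
    times the initial slope, falling back to ``early_frac`` of the age
    span) and the late phase (last ``late_frac`` of the span) — is compared
    with the early-phase slope ``s_e``:

    * ``kink``:     mid derivative stays >= ``theta1 * s_e`` (two exponential
      regimes, no deceleration);
    * ``slowdown``: mid derivative positive but below ``theta1 * s_e``;
    * ``plateau``:  |mid derivative| < ``theta0 * s_e`` somewhere;
    * ``decrease``: mid derivative < ``-theta0 * s_e`` with total mid-age
      drop < ``delta`` log-units;
    * ``u_shape``:  drop >= ``delta`` log-units followed by a recovery of at
      least ``recovery_min`` log-units.
    """
    spl, ages = _smooth_log_hazard(curve, smoothing)
    lo, hi = ages[0], ages[-1]
    span = hi - lo
    grid = np.linspace(lo, hi, 512)
    f = spl(grid)
    df = spl.derivative()(grid)
    # locally averaged derivative: a pointwise spline-derivative minimum is
    # dominated by knot-scale wiggles; sustained mid-age declines span a
    # macroscopic fraction of the age range
    win = max(grid.size // 10, 5)
    kernel = np.ones(win) / win
    df_s = np.convolve(df, kernel, mode="same")
    # the convolution shrinks toward the ends; restore edge values
    half = win // 2
    df_s[:half] = df_s[half]
    df_s[-half:] = df_s[-half - 1]

    # The early exponential phase ends where the derivative first drops
    # below theta1 times the initial slope (the position of that transition
    # moves with the environment parameter, so it is detected, not fixed).
    s0 = float(np.median(df[grid <= lo + 0.08 * span]))
    early_end = lo + early_frac * span
    if s0 > 0:
        candidates = np.flatnonzero((grid >= lo + 0.05 * span)
                                    & (df_s < theta1 * s0))
        if candidates.size:
            early_end = float(grid[candidates[0]])
    late_start = hi - late_frac * span
    if early_end >= late_start:
        early_end = lo + early_frac * span

    early = grid <= early_end
    late = grid >= late_start
    mid = ~early & ~late
    s_e = float(df[early].mean())
    s_l = float(df[late].mean())
    scale = max(abs(s_e), 1e-12)

    dmin = float(df_s[mid].min())
    f_mid = f[mid]
    running_max = np.maximum.accumulate(f_mid)
    drop = float(np.max(running_max - f_mid))
    # recovery: rise of the smoothed curve after its mid-age minimum,
    # looking through to the end of the reported range
    i_mid0 = int(np.flatnonzero(mid)[0])
    i_min = i_mid0 + int(np.argmin(f_mid))
    recovery = float(np.max(f[i_min:]) - f[i_min])

    if dmin < -theta0 * scale:
        if drop >= delta and recovery >= recovery_min:
            shape = Shape.U_SHAPE
        else:
            shape = Shape.DECREASE
    elif dmin < theta0 * scale:
        shape = Shape.PLATEAU
    elif dmin < theta1 * s_e:
        shape = Shape.SLOWDOWN
    else:
        shape = Shape.KINK

    # transition boundaries: where the derivative leaves the early regime
    below = np.flatnonzero(mid & (df_s < theta1 * max(s_e, 0.0)))
    if below.size:
        boundaries = (float(grid[below[0]]), float(grid[below[-1]]))
    else:
        mid_idx = np.flatnonzero(mid)
        boundaries = (float(grid[mid_idx[0]]), float(grid[mid_idx[-1]]))

    metrics = {
        "early_slope": s_e, "late_slope": s_l, "mid_min_derivative": dmin,
        "drop": drop, "recovery": recovery,
        "theta0": theta0, "theta1": theta1, "delta": delta,
        "recovery_min": recovery_min,
    }
    return ShapeLabel(shape=shape, boundaries=boundaries, metrics=metrics)


# ---------------------------------------------------------------------------
# modality: KDE modes + Hartigan dip


def _hull_deviation_core(xs, c_lo, c_hi):
    """Largest amount by which the staircase centers exceed the lower convex
    hull of (xs, c_lo); xs strictly increasing. Stack-based monotone chain
    followed by a single interpolation sweep, so it jit-compiles cleanly.
    """
    m = xs.shape[0]
    hull = np.empty(m, np.int64)
    hull[0] = 0
    hull[1] = 1
    top = 2
    for i in range(2, m):
        while top >= 2:
            j = hull[top - 2]
            k2 = hull[top - 1]
            # pop k2 if it lies on or above the chord j -> i
            if (c_lo[k2] - c_lo[j]) * (xs[i] - xs[j]) >= \
               (c_lo[i] - c_lo[j]) * (xs[k2] - xs[j]):
                top -= 1
            else:
                break
        hull[top] = i
        top += 1
    best = 0.0
    seg = 0
    for i in range(m):
        while seg < top - 2 and xs[hull[seg + 1]] < xs[i]:
            seg += 1
        j = hull[seg]
        k2 = hull[seg + 1]
        fit = c_lo[j] + (c_lo[k2] - c_lo[j]) * (xs[i] - xs[j]) \
            / (xs[k2] - xs[j])
        d = c_hi[i] - fit
        if d > best:
            best = d
    return best


try:  # optional compiled fast path; the pure-Python core is the fallback
    from numba import njit as _njit

    _hull_deviation_fast = _njit(cache=True)(_hull_deviation_core)
except ImportError:  # pragma: no cover
    _hull_deviation_fast = _hull_deviation_core


def _hull_deviation(xs: np.ndarray, c_lo: np.ndarray, c_hi: np.ndarray) -> float:
    m = xs.size
    if m == 0:
        return 0.0
    if m <= 2:
        return float(np.max(c_hi - c_lo))
    return float(_hull_deviation_fast(xs, c_lo, c_hi))


def _side_deviation(x: np.ndarray, c: np.ndarray, mirror: bool) -> float:
    """Deviation profile helper for one side of the candidate mode."""
    if x.size == 0:
        return 0.0
    if mirror:
        x = -x[::-1]
        c = -c[::-1]
    # collapse duplicated abscissae: hull anchored at the lowest center,
    # violation measured at the highest
    ux, first = np.unique(x, return_index=True)
    # c is increasing, so within a duplicate block the first is lowest
    last = np.concatenate([first[1:] - 1, [x.size - 1]])
    return _hull_deviation(ux, c[first], c[last])


def dip_statistic(samples) -> float:
    """Hartigan & Hartigan dip: min over unimodal cdfs G of sup |F_n - G|.

    For a candidate mode position, the best unimodal cdf must be convex to
    the left and concave to the right; on each side the minimal sup-deviation
    is ``1/(2n)`` plus half the largest violation of the jump midpoints with
    respect to their convex (resp. concave) hull. The left deviation grows
    and the right deviation shrinks as the mode moves right, so the optimal
    split is found by bisection.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        return 0.0
    c = (np.arange(n) + 0.5) / n  # jump midpoints of the empirical cdf

    def dev_left(j: int) -> float:
        return _side_deviation(x[:j + 1], c[:j + 1], mirror=False)

    def dev_right(j: int) -> float:
        return _side_deviation(x[j + 1:], c[j + 1:], mirror=True)

    lo, hi = -1, n - 1
    # find smallest j with dev_left(j) >= dev_right(j) (left grows, right shrinks)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if dev_left(mid) >= dev_right(mid):
            hi = mid
        else:
            lo = mid
    best = min(max(dev_left(j), dev_right(j)) for j in (lo, hi))
    return 1.0 / (2 * n) + 0.5 * best


#: Bootstrap null dips keyed by (sample size, draws); the null depends on
#: the sample size only, so repeated tests at the same n reuse the draws.
_DIP_NULL_CACHE: dict[tuple[int, int], np.ndarray] = {}


def dip_test(samples, *, n_boot: int = 200,
             rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Dip statistic plus bootstrap p-value against uniform samples.

    The uniform is the asymptotically least-favourable unimodal null, so the
    p-value is the fraction of ``n_boot`` uniform samples of the same size
    whose dip is at least as large as the observed one.
    """
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(samples, dtype=float)
    d = dip_statistic(x)
    n = x.size
    key = (n, n_boot)
    if key not in _DIP_NULL_CACHE:
        _DIP_NULL_CACHE[key] = np.array(
            [dip_statistic(rng.random(n)) for _ in range(n_boot)])
    boots = _DIP_NULL_CACHE[key]
    p = float((np.sum(boots >= d) + 1) / (n_boot + 1))
    return d, p


def lifespan_modality(lifespans, *, bandwidth=None, prominence: float = 0.05,
                      n_boot: int = 200, max_n: int = 2000,
                      rng: np.random.Generator | None = None) -> ModalityResult:
    """Mode count and dip test for a lifespan distribution.

    Modes are maxima of a Gaussian KDE (Silverman bandwidth by default) with
    prominence at least ``prominence`` times the density maximum. Infinite
    lifespans (never-dying sentinel) are excluded. Samples larger than
    ``max_n`` are subsampled for the dip bootstrap.
    """
    rng = np.random.default_rng() if rng is None else rng
    lifespans = np.asarray(lifespans, dtype=float)
    lifespans = lifespans[np.isfinite(lifespans)]
    if lifespans.size < 100:
        raise ValueError("need at least 100 finite lifespans")

    bw = "silverman" if bandwidth is None else bandwidth
    kde = stats.gaussian_kde(lifespans, bw_method=bw)
    h = kde.factor * lifespans.std(ddof=1)
    grid = np.linspace(lifespans.min() - 3 * h, lifespans.max() + 3 * h, 512)
    dens = kde(grid)
    peaks, _ = signal.find_peaks(dens, prominence=prominence * dens.max())
    mode_count = max(int(peaks.size), 1)

    sub = lifespans
    if sub.size > max_n:
        sub = rng.choice(sub, size=max_n, replace=False)
    d, p = dip_test(sub, n_boot=n_boot, rng=rng)
    return ModalityResult(mode_count=mode_count, dip=d, p_value=p)


# ---------------------------------------------------------------------------
# trait-tail truncation


def truncate_trait_tail(dist_or_sample, x_max: float):
    """Remove trait mass (or individuals) above ``x_max`` and renormalize.

    Accepts either a trait-distribution object (anything with ``grid`` and
    ``mass`` attributes; bins above ``x_max`` are emptied and the mass
    renormalized on the same grid) or a plain sample of traits.
    """
    if not 0 < x_max <= 1:
        raise ValueError("x_max must lie in (0, 1]")
    if hasattr(dist_or_sample, "grid") and hasattr(dist_or_sample, "mass"):
        dist = dist_or_sample
        keep = dist.grid <= x_max
        mass = np.where(keep, dist.mass, 0.0)
        total = mass.sum()
        if total <= 0:
            raise ValueError("truncation removed all mass")
        return type(dist)(grid=dist.grid.copy(), mass=mass / total)
    sample = np.asarray(dist_or_sample, dtype=float)
    out = sample[sample <= x_max]
    if out.size == 0:
        raise ValueError("truncation removed all individuals")
    return out
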