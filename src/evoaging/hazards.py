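"""Individual mortality laws for the two heterogeneity hypotheses.

Two Gompertz-type hazard families describe how a heritable resource-allocation
trait ``x`` in [0, 1] (investment in reproduction versus somatic maintenance)
shapes an individual's age-specific mortality:

* **HRM** (heterogeneity in aging *rate*): ``mu(x, t) = a * exp(b * x**k * t)``.
  All individuals share the initial mortality ``a`` but age at trait-dependent
  rates ``b * x**k``.
* **HTM** (heterogeneity in aging *timing*): ``mu(x, t) = a * x**k * exp(b * t)``.
  All individuals share the aging rate ``b``; a change in ``x`` shifts the
  log-mortality curve along the time axis by ``ln(x2**k / x1**k) / b``.

An age-independent extrinsic hazard ``ext`` may be added to either family.
Cumulative hazards have closed forms, so lifespans are sampled exactly by
inverse-transform sampling; with ``ext > 0`` the intrinsic and extrinsic
components are independent competing risks and the minimum of the two draws
is exact.

An HTM individual with ``x = 0`` (and ``ext = 0``) never dies; its lifespan is
the ``numpy.inf`` sentinel, which downstream code treats as "never dies within
any horizon".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "HazardFamily",
    "HazardParams",
    "hazard",
    "cumulative_hazard",
    "survival_probability",
    "death_time_from_uniform",
    "draw_death_time",
]

#: Rate products below this threshold are treated as the constant-hazard limit.
_RATE_EPS = 1e-12


class HazardFamily(str, enum.Enum):
    """Which aspect of aging the trait modulates."""

    HRM = "HRM"  # heterogeneity in aging rate
    HTM = "HTM"  # heterogeneity in aging timing


@dataclass(frozen=True)
class HazardParams:
    """Parameters of the individual mortality law, shared by a whole run.

    Parameters
    ----------
    family
        ``HazardFamily.HRM`` or ``HazardFamily.HTM``.
    a
        Initial mortality rate (per unit time, > 0).
    b
        Environment-biology interaction rate (per unit time, >= 0); the slope
        of the baseline exponential aging.
    k
        Trait exponent (dimensionless, > 0). ``k = 1`` gives linear dependence
        on the trait.
    ext
        Extrinsic, age- and trait-independent hazard (per unit time, >= 0).
    """

    family: HazardFamily
    a: float
    b: float
    k: float = 1.0
    ext: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", HazardFamily(self.family))
        if not self.a > 0:
            raise ValueError(f"initial mortality a must be > 0, got {self.a}")
        if self.b < 0:
            raise ValueError(f"aging rate b must be >= 0, got {self.b}")
        if not self.k > 0:
            raise ValueError(f"trait exponent k must be > 0, got {self.k}")
        if self.ext < 0:
            raise ValueError(f"extrinsic hazard ext must be >= 0, got {self.ext}")

    def with_b(self, b: float) -> "HazardParams":
        """Copy of the parameters with a different environment rate ``b``."""
        return replace(self, b=b)

    def rescaled(self, factor: float) -> "HazardParams":
        """Rescale the time unit: all rates multiplied by ``factor``.

        Lifespan distributions under the rescaled parameters are those of the
        original parameters with time divided by ``factor``; dimensionless
        combinations (``a/b``, ``b * t`` at corresponding ages) are preserved.
        """
        return replace(self, a=self.a * factor, b=self.b * factor,
                       ext=self.ext * factor)


def _check_domain(x, t) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("trait x must lie in [0, 1]")
    if np.any(t < 0):
        raise ValueError("age t must be >= 0")
    return x, t


def _intrinsic_hazard(family: HazardFamily, a: float, b: float, k: float,
                      x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Intrinsic hazard without domain validation (x may exceed 1, e.g. for
    frailty mixtures on an unbounded scale)."""
    xk = np.power(x, k)
    if family is HazardFamily.HRM:
        return a * np.exp(b * xk * t)
    return a * xk * np.exp(b * t)


def _intrinsic_cumulative(family: HazardFamily, a: float, b: float, k: float,
                          x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Closed-form integral of the intrinsic hazard over [0, t].

    HRM (rate r = b x^k): a * (exp(r t) - 1) / r, with limit a * t as r -> 0.
    HTM: a x^k * (exp(b t) - 1) / b, with limit a x^k t as b -> 0.
    """
    xk = np.power(x, k)
    with np.errstate(over="ignore", invalid="ignore"):
        if family is HazardFamily.HRM:
            r = b * xk
            r_safe = np.where(np.abs(r) < _RATE_EPS, 1.0, r)
            out = np.where(np.abs(r) < _RATE_EPS,
                           a * t,
                           a * np.expm1(r_safe * t) / r_safe)
        else:
            if b < _RATE_EPS:
                out = a * xk * t
            else:
                out = a * xk * np.expm1(b * t) / b
                # xk = 0 multiplied by an overflowing exponential: the
                # cumulative hazard is identically zero there
                out = np.where(xk == 0, 0.0, out)
    return out


def hazard(params: HazardParams, x, t):
    """Total hazard of death ``mu(x, t) + ext`` at age ``t`` for trait ``x``.

    Vectorized over ``x`` and ``t`` (broadcast). Raises ``ValueError`` for
    ``t < 0`` or ``x`` outside [0, 1].
    """
    x, t = _check_domain(x, t)
    out = _intrinsic_hazard(params.family, params.a, params.b, params.k, x, t)
    out = out + params.ext
    return out if out.ndim else float(out)


def cumulative_hazard(params: HazardParams, x, t):
    """Cumulative hazard ``H(x, t) = integral of mu over [0, t]`` (+ ext * t)."""
    x, t = _check_domain(x, t)
    out = _intrinsic_cumulative(params.family, params.a, params.b, params.k, x, t)
    out = out + params.ext * t
    return out if out.ndim else float(out)


def survival_probability(params: HazardParams, x, t):
    """Survival function ``S(x, t) = exp(-H(x, t))``."""
    h = cumulative_hazard(params, x, t)
    return np.exp(-np.asarray(h)) if np.ndim(h) else float(np.exp(-h))


def _invert_intrinsic(family: HazardFamily, a: float, b: float, k: float,
                      x: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Solve ``H_intrinsic(t) = e`` for t (e >= 0). Returns inf where the
    cumulative hazard is bounded below e (HTM with x = 0)."""
    xk = np.power(x, k)
    if family is HazardFamily.HRM:
        # H = a (exp(r t) - 1)/r  ->  t = log1p(r e / a) / r, limit e/a.
        r = b * xk
        small = np.abs(r) < _RATE_EPS
        r_safe = np.where(small, 1.0, r)
        t = np.where(small, e / a, np.log1p(r_safe * e / a) / r_safe)
        return t
    # HTM: H = a x^k (exp(b t) - 1)/b -> t = log1p(b e / (a x^k)) / b
    with np.errstate(divide="ignore"):
        scaled = np.where(xk > 0, e / (a * np.where(xk > 0, xk, 1.0)), np.inf)
    if b < _RATE_EPS:
        t = scaled
    else:
        t = np.where(np.isinf(scaled), np.inf, np.log1p(b * scaled) / b)
    t = np.where(e == 0, 0.0, t)
    return t


def death_time_from_uniform(params: HazardParams, x, u):
    """Deterministic inverse-transform map: the age ``t`` with ``S(x, t) = u``.

    This is the quantile-by-survival function used by :func:`draw_death_time`
    for the intrinsic component; exposed separately so the inversion identity
    can be exercised directly. ``ext`` is ignored here (the extrinsic
    component is an independent competing exponential in the sampler).
    """
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("trait x must lie in [0, 1]")
    if np.any(u <= 0) or np.any(u > 1):
        raise ValueError("u must lie in (0, 1]")
    e = -np.log(u)
    t = _invert_intrinsic(params.family, params.a, params.b, params.k, x, e)
    return t if t.ndim else float(t)


def draw_death_time(params: HazardParams, x, rng: np.random.Generator):
    """Sample exact lifespans for traits ``x`` by inverse-transform sampling.

    One draw per element of ``x``. With ``ext > 0``, returns the minimum of
    the intrinsic draw and an independent Exp(ext) draw (competing risks).
    HTM with ``x = 0`` and ``ext = 0`` yields ``inf``.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("trait x must lie in [0, 1]")
    e = rng.exponential(1.0, size=x.shape)
    t = _invert_intrinsic(params.family, params.a, params.b, params.k, x, e)
    if params.ext > 0:
        t_ext = rng.exponential(1.0 / params.ext, size=x.shape)
        t = np.minimum(t, t_ext)
    return float(t[0]) if scalar else t
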