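"""Closed-form growth laws for unperturbed and direct-current treated tumors.

The unperturbed model is the classical Gompertz solution

    V(t) = V0 * exp((alpha/beta) * (1 - exp(-beta*t)))

with intrinsic growth rate ``alpha`` (1/day) and growth-deceleration factor
``beta`` (1/day).  Electrochemical therapy (EChT, low-level direct current
delivered through needle electrodes) is modelled by replacing ``alpha`` with a
time-dependent modified rate

    alpha*(t) = [a1 * (1 - exp(-gamma*t)) + a2] * alpha,
    a1 = r * (2 - r),   a2 = 1 - r,   r = i / i0,

where ``i`` is the applied DC intensity (mA), ``i0`` the polarization current
induced in the tumor (mA) and ``gamma`` (1/day) the first-order decay rate of
the net treatment effect after current removal.  ``alpha*(t)`` is substituted
pointwise into the closed form above (the modified Gompertz equation, MGE);
no time-varying-rate ODE is re-integrated.

For ``i = 0`` the MGE reduces exactly to the unperturbed Gompertz law.  The
asymptotic volume is ``V0 * exp((1 + r - r^2) * alpha / beta)``; it crosses
``V0`` at the golden-ratio current ratio ``r = (1 + sqrt(5))/2``, above which
the model predicts net tumor regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GompertzParams",
    "EChTParams",
    "CurrentRatioTerms",
    "CRITICAL_RATIO",
    "DEFAULT_RATIO_THRESHOLD",
    "NEVER_DOUBLES",
    "gompertz_volume",
    "exponential_volume",
    "current_ratio_terms",
    "alpha_star",
    "mge_volume",
    "mge_asymptote",
    "analytic_doubling_time",
    "steel_doubling_time",
    "growth_fraction",
    "response_regime",
]

#: Current ratio at which the asymptotic MGE volume equals V0 (root of 1 + r - r^2).
CRITICAL_RATIO = (1.0 + math.sqrt(5.0)) / 2.0

#: Experimentally reported threshold ratio (i/i0)_u above which complete
#: response is hypothesized for this tumor histological variety.
DEFAULT_RATIO_THRESHOLD = 1.50

#: Sentinel returned when a trajectory's plateau never reaches twice V0.
NEVER_DOUBLES = math.inf


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class GompertzParams:
    """Unperturbed Gompertz parameters: initial volume (cm^3) and rates (1/day)."""

    v0: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("v0", "alpha", "beta"):
            val = getattr(self, name)
            _require(math.isfinite(val), f"{name} must be finite, got {val!r}")
        _require(self.v0 > 0, f"v0 must be > 0, got {self.v0}")
        _require(self.alpha > 0, f"alpha must be > 0, got {self.alpha}")
        _require(
            self.beta > 0,
            f"beta must be > 0, got {self.beta} (use exponential_volume for beta = 0)",
        )

    @property
    def plateau(self) -> float:
        """Asymptotic (carrying-capacity) volume V0 * exp(alpha/beta), cm^3."""
        return self.v0 * math.exp(self.alpha / self.beta)


@dataclass(frozen=True)
class EChTParams:
    """Treatment parameters: applied current i (mA), polarization current i0 (mA),
    and first-order decay rate gamma (1/day) of the net post-treatment effect."""

    i: float
    i0: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("i", "i0", "gamma"):
            val = getattr(self, name)
            _require(math.isfinite(val), f"{name} must be finite, got {val!r}")
        _require(self.i >= 0, f"applied current i must be >= 0, got {self.i}")
        _require(self.i0 > 0, f"polarization current i0 must be > 0, got {self.i0}")
        _require(self.gamma >= 0, f"gamma must be >= 0, got {self.gamma}")

    @property
    def ratio(self) -> float:
        """Dimensionless current ratio r = i/i0."""
        return self.i / self.i0


@dataclass(frozen=True)
class CurrentRatioTerms:
    """Dimensionless terms r = i/i0, a1 = r(2 - r), a2 = 1 - r."""

    r: float
    a1: float
    a2: float


def current_ratio_terms(i: float, i0: float) -> CurrentRatioTerms:
    """Compute (r, a1, a2) from applied and polarization currents (mA).

    Satisfies a1 + a2 = 1 + r - r^2 identically.  Ratios above 2 make a1
    negative; they are permitted but flagged, since fitted ratios for this
    tumor variety stay below ~1.5.
    """
    _require(i0 > 0, f"polarization current i0 must be > 0, got {i0}")
    _require(i >= 0, f"applied current i must be >= 0, got {i}")
    r = i / i0
    if r > 2.0:
        warnings.warn(
            f"current ratio i/i0 = {r:.3f} exceeds 2; a1 = r(2-r) is negative",
            stacklevel=2,
        )
    return CurrentRatioTerms(r=r, a1=r * (2.0 - r), a2=1.0 - r)


def gompertz_volume(t, p: GompertzParams):
    """Unperturbed Gompertz volume at time(s) ``t`` (days since window origin).

    Strictly increasing in t, bounded above by the plateau ``p.plateau``.
    """
    t = np.asarray(t, dtype=float)
    _require(bool(np.all(t >= 0)), "t must be >= 0")
    out = p.v0 * np.exp((p.alpha / p.beta) * (1.0 - np.exp(-p.beta * t)))
    return out if out.ndim else float(out)


def exponential_volume(t, v0: float, alpha: float):
    """Exponential-growth limit of the Gompertz law (beta -> 0): V0*exp(alpha*t)."""
    _require(v0 > 0, f"v0 must be > 0, got {v0}")
    _require(alpha > 0, f"alpha must be > 0, got {alpha}")
    t = np.asarray(t, dtype=float)
    _require(bool(np.all(t >= 0)), "t must be >= 0")
    out = v0 * np.exp(alpha * t)
    return out if out.ndim else float(out)


def alpha_star(t, alpha: float, e: EChTParams):
    """Modified growth rate alpha*(t) = [a1(1 - e^{-gamma t}) + a2] * alpha (1/day).

    At t = 0 this equals a2*alpha (negative when i > i0, i.e. transient
    regression); as t -> inf it approaches (1 + r - r^2)*alpha.
    """
    t = np.asarray(t, dtype=float)
    _require(bool(np.all(t >= 0)), "t must be >= 0")
    terms = current_ratio_terms(e.i, e.i0)
    out = (terms.a1 * (1.0 - np.exp(-e.gamma * t)) + terms.a2) * alpha
    return out if out.ndim else float(out)


def mge_volume(t, p: GompertzParams, e: EChTParams):
    """Modified Gompertz volume: alpha*(t) substituted pointwise into the closed form.

    V(0) = V0 for every parameter bundle; with i = 0 this is identical to
    :func:`gompertz_volume` for all t.
    """
    t = np.asarray(t, dtype=float)
    _require(bool(np.all(t >= 0)), "t must be >= 0")
    a_star = np.asarray(alpha_star(t, p.alpha, e), dtype=float)
    out = p.v0 * np.exp((a_star / p.beta) * (1.0 - np.exp(-p.beta * t)))
    return out if out.ndim else float(out)


def mge_asymptote(p: GompertzParams, e: EChTParams) -> float:
    """Asymptotic MGE volume V0 * exp((1 + r - r^2) * alpha / beta), cm^3."""
    terms = current_ratio_terms(e.i, e.i0)
    return p.v0 * math.exp((terms.a1 + terms.a2) * p.alpha / p.beta)


def analytic_doubling_time(p: GompertzParams) -> float:
    """Time (days) at which the unperturbed Gompertz volume reaches 2*V0.

    Closed-form inversion: -(1/beta) * ln(1 - beta*ln2/alpha).  Returns the
    :data:`NEVER_DOUBLES` sentinel (inf) when the plateau stays below 2*V0,
    i.e. alpha <= beta*ln 2.
    """
    x = p.beta * math.log(2.0) / p.alpha
    if x >= 1.0:
        return NEVER_DOUBLES
    return -math.log(1.0 - x) / p.beta


def steel_doubling_time(tc: float, phi: float, gf: float) -> float:
    """Steel relation DT = Tc*ln2 / [(1 - phi) * ln(1 + GF)] (days).

    ``tc`` is the cell-cycle time (days), ``phi`` the cell-loss factor and
    ``gf`` the growth fraction (both dimensionless fractions).
    """
    _require(tc > 0, f"cell cycle time must be > 0, got {tc}")
    _require(0.0 <= phi < 1.0, f"cell loss factor must be in [0, 1), got {phi}")
    _require(0.0 < gf <= 1.0, f"growth fraction must be in (0, 1], got {gf}")
    return tc * math.log(2.0) / ((1.0 - phi) * math.log(1.0 + gf))


def growth_fraction(n_cycling: float, n_noncycling: float) -> float:
    """Growth fraction GF = N_cc / (N_cc + N_n-cc) from cell counts."""
    _require(n_cycling > 0, "cycling cell count must be > 0")
    _require(n_noncycling >= 0, "non-cycling cell count must be >= 0")
    return n_cycling / (n_cycling + n_noncycling)


def response_regime(
    p: GompertzParams,
    e: EChTParams,
    threshold: float = DEFAULT_RATIO_THRESHOLD,
    rtol: float = 0.02,
) -> str:
    """Label the asymptotic behavior of an MGE trajectory.

    Returns ``"stationary"`` when r = i/i0 lies within ``rtol`` (relative) of
    the configured threshold ratio, ``"regression"`` when the asymptotic
    volume falls below V0 (r beyond the golden-ratio root of 1 + r - r^2),
    and ``"progression"`` otherwise.
    """
    _require(threshold > 0, f"threshold must be > 0, got {threshold}")
    r = e.ratio
    if abs(r - threshold) <= rtol * threshold:
        return "stationary"
    if 1.0 + r - r * r < 0.0:
        return "regression"
    return "progression"
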