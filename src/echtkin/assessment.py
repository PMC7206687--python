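"""Fit-quality statistics and curve-distance measures.

All statistics are defined on one fitted window of n1 observed volumes
V_j with model predictions Vhat_j and k = 2 free parameters per stage:

    SSE   = sum_j (Vhat_j - V_j)^2
    SE    = sqrt(SSE / (n1 - k))
    1-r^2 = SSE / (sum V^2 - (sum V)^2 / n1)
    r_a^2 = [(n1 - 1) r^2 - k + 1] / (n1 - k)        (satisfactory when > 0.98)
    PRESS = sum_{j=1}^{n1-1} [(Vhat_j)' - V_j]^2 / (n1 - k)
    MPRESS(m) = sum_{j=m+1}^{n1} [(Vhat_j)' - V_j]^2 / (n1 - m)

where (Vhat_j)' is the prediction for point j from a refit without it
(PRESS) or from a fit to the first m points only (MPRESS, reported for
m = 3 by default).  The printed PRESS limits (sum to n1 - 1, denominator
n1 - k) are implemented as stated; ``mode="standard"`` gives the
conventional unnormalised full-sum leave-one-out statistic instead.

Treated-vs-control group curves on a common interpolation grid of M days
are compared with Dmax = max|F_i - G_i| and RMSE = sqrt(sum (F_i-G_i)^2/M),
where F is the control reference and G the treated curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AssessmentReport",
    "sse",
    "se",
    "r2_ra2",
    "press",
    "mpress",
    "curve_distance",
    "assess_fit",
    "RA2_SATISFACTORY",
]

#: Adjusted-r^2 level above which a fit is considered satisfactory.
RA2_SATISFACTORY = 0.98


def _pair(observed, predicted):
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    return observed, predicted


def sse(observed, predicted) -> float:
    """Sum of squared errors (cm^6); zero iff the vectors coincide."""
    observed, predicted = _pair(observed, predicted)
    d = predicted - observed
    return float(d @ d)


def se(observed, predicted, k: int = 2) -> float:
    """Standard error of the estimate sqrt(SSE/(n1-k)) (cm^3)."""
    observed, predicted = _pair(observed, predicted)
    n1 = observed.size
    if n1 <= k:
        raise ValueError(f"need n1 > k, got n1 = {n1}, k = {k}")
    return math.sqrt(sse(observed, predicted) / (n1 - k))


def r2_ra2(observed, predicted, k: int = 2) -> tuple[float, float]:
    """Goodness of fit r^2 and its adjusted form r_a^2."""
    observed, predicted = _pair(observed, predicted)
    n1 = observed.size
    tss = float(np.sum(observed**2) - np.sum(observed) ** 2 / n1)
    if tss <= 0:
        raise ValueError("observed values have zero variance; r^2 is undefined")
    r2 = 1.0 - sse(observed, predicted) / tss
    ra2 = ((n1 - 1) * r2 - k + 1) / (n1 - k)
    return r2, ra2


def press(
    days,
    volumes,
    fit_predict,
    k: int = 2,
    mode: str = "printed",
) -> float:
    """Leave-one-out predicted residual statistic (cm^3 column convention).

    ``fit_predict(days, volumes, j)`` must refit the series without point j
    (keeping the window's initial condition anchored at the observed origin
    volume) and return the prediction at ``days[j]``.

    ``mode="printed"`` follows the stated formula: sum over the first
    n1 - 1 points, divided by n1 - k.  ``mode="standard"`` is the
    conventional full-sum, unnormalised PRESS.  A deletion whose refit
    fails is skipped with a warning.
    """
    days = np.asarray(days, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    n1 = days.size
    if mode not in ("printed", "standard"):
        raise ValueError(f"unknown PRESS mode {mode!r}")
    indices = range(n1 - 1) if mode == "printed" else range(n1)
    total = 0.0
    for j in indices:
        try:
            pred = fit_predict(days, volumes, j)
        except Exception as exc:  # refit failure: skip the deletion
            warnings.warn(f"leave-one-out refit failed for point {j}: {exc}",
                          stacklevel=2)
            continue
        total += (pred - volumes[j]) ** 2
    return total / (n1 - k) if mode == "printed" else total


def mpress(days, volumes, fit_forecast, m: int = 3) -> float:
    """Fit-first-m forecast statistic MPRESS(m).

    ``fit_forecast(days, volumes, m)`` must fit the first m points and
    return predictions for the remaining n1 - m days.
    """
    days = np.asarray(days, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    n1 = days.size
    if not 3 <= m < n1:
        raise ValueError(f"need 3 <= m < n1, got m = {m}, n1 = {n1}")
    preds = np.asarray(fit_forecast(days, volumes, m), dtype=float)
    if preds.size != n1 - m:
        raise ValueError("fit_forecast must return one prediction per held-out point")
    d = preds - volumes[m:]
    return float(d @ d) / (n1 - m)


def curve_distance(reference, compared) -> tuple[float, float]:
    """(Dmax, RMSE) between a control reference curve and a treated curve.

    Both inputs are value arrays on a common grid of M points (use
    :func:`echtkin.interpolation.group_mean_curve` outputs).
    """
    f = np.asarray(getattr(reference, "values", reference), dtype=float)
    g = np.asarray(getattr(compared, "values", compared), dtype=float)
    rgrid = getattr(reference, "grid", None)
    cgrid = getattr(compared, "grid", None)
    if rgrid is not None and cgrid is not None and not np.array_equal(rgrid, cgrid):
        raise ValueError("curves must share a common grid")
    if f.shape != g.shape:
        raise ValueError("curves must share a common grid")
    diff = np.abs(f - g)
    dmax = float(diff.max())
    rmse = float(math.sqrt(np.mean(diff**2)))
    return dmax, rmse


@dataclass
class AssessmentReport:
    """All per-fit statistics in the study's table layout."""

    sse: float
    se: float
    r2: float
    ra2: float
    rmse: float
    dmax: float
    press: float | None = None
    mpress: dict = field(default_factory=dict)  # m -> value
    n1: int = 0
    k: int = 2

    @property
    def satisfactory(self) -> bool:
        return self.ra2 > RA2_SATISFACTORY


def assess_fit(observed, predicted, k: int = 2) -> AssessmentReport:
    """Residual-based statistics for one fitted window (PRESS/MPRESS need
    refits and are attached separately by the caller)."""
    observed, predicted = _pair(observed, predicted)
    n1 = observed.size
    r2, ra2 = r2_ra2(observed, predicted, k)
    resid = np.abs(predicted - observed)
    return AssessmentReport(
        sse=sse(observed, predicted),
        se=se(observed, predicted, k),
        r2=r2,
        ra2=ra2,
        rmse=float(math.sqrt(np.mean(resid**2))),
        dmax=float(resid.max()),
        n1=n1,
        k=k,
    )
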