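"""Kinetic endpoints and response classification.

Per animal: the regression percent 100*|V_min - V0|/V0 reached after
treatment (reported as a magnitude when the tumor shrinks, 0 otherwise,
with the signed raw value retained), the doubling time (first day the
volume reaches twice the window's initial volume) and the response class
(PD/SD/PR/CR).  Per group: the growth delay (ratio of the treated arm's
mean doubling time to its control arm's) and the overall effectiveness
100*(PR + CR)/N.

The study cites but never defines numeric PD/SD/PR/CR criteria; the
defaults here are standard preclinical conventions (CR below a 0.01 cm^3
detection limit, PR at >= 50% regression, PD at final volume >= 2*V0
without >= 25% regression, SD otherwise) and are fully configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interpolation import InterpolatedCurve, hermite_interpolate

__all__ = [
    "ResponseThresholds",
    "RegressionResult",
    "RESPONSE_CLASSES",
    "regression_percent",
    "doubling_time_from_data",
    "growth_delay",
    "classify_response",
    "overall_effectiveness",
    "percent",
    "attrition_summary",
    "endpoint_tables",
]

RESPONSE_CLASSES = ("PD", "SD", "PR", "CR")

#: Doubling-time sentinel when the curve never reaches 2*V0 in follow-up.
NOT_REACHED = math.inf


@dataclass(frozen=True)
class ResponseThresholds:
    """Configurable response-class boundaries."""

    cr_volume: float = 0.01        # cm^3 detection limit for complete response
    pr_regression: float = 50.0    # % regression for partial response
    pd_growth_factor: float = 2.0  # final volume >= factor*V0 for progression
    pd_max_regression: float = 25.0  # % regression that rules out progression

    def __post_init__(self) -> None:
        if self.cr_volume < 0 or not 0 < self.pr_regression <= 100:
            raise ValueError("invalid response thresholds")
        if self.pd_growth_factor <= 1 or not 0 <= self.pd_max_regression < 100:
            raise ValueError("invalid progression thresholds")


@dataclass(frozen=True)
class RegressionResult:
    percent: float       # magnitude, 0 when the tumor never shrinks below V0
    raw_percent: float   # signed 100*(Vmin - V0)/V0
    vmin: float
    vmin_day: float
    regressed: bool


def _as_curve(days, volumes=None, interpolate: bool = True) -> InterpolatedCurve:
    if isinstance(days, InterpolatedCurve):
        return days
    days = np.asarray(days, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if interpolate and days.size >= 3:
        return hermite_interpolate(days, volumes)
    return InterpolatedCurve(grid=days, values=volumes)


def regression_percent(
    days, volumes=None, v0: float | None = None, interpolate: bool = True
) -> RegressionResult:
    """Tumor regression percent from the post-treatment curve.

    ``v0`` defaults to the curve's first value (the treatment-day volume).
    Vmin is the first occurrence of the minimum on the daily interpolated
    curve (default, damping single-measurement noise) or on the raw points
    when ``interpolate=False``.
    """
    curve = _as_curve(days, volumes, interpolate)
    if len(curve) == 0:
        raise ValueError("empty post-treatment window")
    v0 = float(curve.values[0]) if v0 is None else float(v0)
    if v0 <= 0:
        raise ValueError("V0 must be positive")
    idx = int(np.argmin(curve.values))
    vmin = float(curve.values[idx])
    raw = (vmin - v0) / v0 * 100.0
    regressed = vmin < v0
    return RegressionResult(
        percent=-raw if regressed else 0.0,
        raw_percent=raw,
        vmin=vmin,
        vmin_day=float(curve.grid[idx]),
        regressed=regressed,
    )


def doubling_time_from_data(
    days, volumes=None, v0: float | None = None, interpolate: bool = True
) -> float:
    """First time (days from the window origin) the volume reaches 2*V0.

    Grid search on the (interpolated) curve, refined by linear interpolation
    between the bracketing days; :data:`NOT_REACHED` (inf) if the curve
    stays below 2*V0 throughout follow-up.
    """
    curve = _as_curve(days, volumes, interpolate)
    v0 = float(curve.values[0]) if v0 is None else float(v0)
    if v0 <= 0:
        raise ValueError("V0 must be positive")
    target = 2.0 * v0
    above = curve.values >= target
    if not above.any():
        return NOT_REACHED
    i = int(np.argmax(above))
    t0 = float(curve.grid[0])
    if i == 0:
        return 0.0
    d0, d1 = curve.grid[i - 1], curve.grid[i]
    y0, y1 = curve.values[i - 1], curve.values[i]
    frac = (target - y0) / (y1 - y0) if y1 > y0 else 1.0
    return float(d0 + frac * (d1 - d0) - t0)


def growth_delay(treated_dts, control_dts) -> float:
    """Ratio of mean doubling times: treated / control (dimensionless).

    Sentinel (inf) doubling times are dropped; if a whole arm never doubles
    the ratio itself is the sentinel, with a warning.
    """
    treated = np.asarray([t for t in np.atleast_1d(treated_dts)], dtype=float)
    control = np.asarray([t for t in np.atleast_1d(control_dts)], dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("both arms must be non-empty")
    t_fin, c_fin = treated[np.isfinite(treated)], control[np.isfinite(control)]
    if c_fin.size == 0 or c_fin.mean() == 0:
        raise ValueError("control arm has no finite doubling time")
    if t_fin.size == 0:
        warnings.warn("treated arm never doubles; growth delay is unbounded",
                      stacklevel=2)
        return math.inf
    return float(t_fin.mean() / c_fin.mean())


def classify_response(
    days,
    volumes=None,
    v0: float | None = None,
    thresholds: ResponseThresholds = ResponseThresholds(),
) -> str:
    """Assign exactly one of PD/SD/PR/CR to a post-treatment series."""
    curve = _as_curve(days, volumes)
    v0 = float(curve.values[0]) if v0 is None else float(v0)
    reg = regression_percent(curve, v0=v0)
    final = float(curve.values[-1])
    if reg.vmin <= thresholds.cr_volume:
        return "CR"
    if reg.percent >= thresholds.pr_regression:
        return "PR"
    if final >= thresholds.pd_growth_factor * v0 and reg.percent < thresholds.pd_max_regression:
        return "PD"
    return "SD"


def overall_effectiveness(responses) -> float:
    """Overall treatment effectiveness 100*(PR + CR)/N, one decimal."""
    responses = list(responses)
    if not responses:
        raise ValueError("need at least one response")
    unknown = set(responses) - set(RESPONSE_CLASSES)
    if unknown:
        raise ValueError(f"unknown response classes: {sorted(unknown)}")
    hits = sum(1 for r in responses if r in ("PR", "CR"))
    return round(100.0 * hits / len(responses), 1)


def percent(part: float, whole: float, decimals: int = 2) -> float:
    """Cohort-accounting helper: 100*part/whole rounded to ``decimals``."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round(100.0 * part / whole, decimals)


def attrition_summary(
    n_initial: int,
    n_died_pre: int,
    n_died_post: int,
    n_at_risk_post: int | None = None,
    n_evaluable: int | None = None,
) -> dict:
    """Cohort attrition bookkeeping as percentages of the stated denominators.

    ``n_at_risk_post`` defaults to the animals alive at treatment and
    ``n_evaluable`` to those alive at follow-up end; both can be overridden
    when an external accounting convention fixes them.
    """
    if n_at_risk_post is None:
        n_at_risk_post = n_initial - n_died_pre
    if n_evaluable is None:
        n_evaluable = n_at_risk_post - n_died_post
    return {
        "n_initial": n_initial,
        "n_died_pre": n_died_pre,
        "n_died_post": n_died_post,
        "n_at_risk_post": n_at_risk_post,
        "n_evaluable": n_evaluable,
        "pre_treatment_death_pct": percent(n_died_pre, n_initial),
        "post_treatment_death_pct": percent(n_died_post, n_at_risk_post),
        "evaluable_pct": percent(n_evaluable, n_initial, decimals=3),
    }


def endpoint_tables(
    frame: pd.DataFrame,
    treatment_day: float = 31.0,
    first_day: float = 18.0,
    last_day: float = 49.0,
    thresholds: ResponseThresholds = ResponseThresholds(),
    min_points: int = 3,
    interpolate: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-animal endpoints plus group response and doubling-time tables.
    ``interpolate=False`` switches Vmin/doubling searches to raw points.

    Returns ``(per_animal, response_table, doubling_table)``.  Doubling times
    are computed on the interpolated pre-window (origin at ``first_day``) and
    post-window (origin at ``treatment_day``); the growth delay of each
    treated arm uses the control arm of the same gender with matching
    geometry where present (CG1 for C-I, CG2 otherwise).
    """
    rows = []
    for animal_id, sub in frame.groupby("animal_id", sort=False):
        sub = sub.sort_values("day")
        days = sub["day"].to_numpy(float)
        vols = sub["volume_cm3"].to_numpy(float)
        treated = float(sub["current_ma"].iloc[0]) > 0
        row = {
            "animal_id": animal_id,
            "group": sub["group"].iloc[0],
            "gender": sub["gender"].iloc[0],
            "treated": treated,
        }
        pre = (days >= first_day) & (days <= treatment_day)
        if pre.sum() >= min_points:
            row["doubling_time_pre"] = doubling_time_from_data(
                days[pre], vols[pre], interpolate=interpolate
            )
        post = (days >= treatment_day) & (days <= last_day)
        if post.sum() >= min_points:
            curve = _as_curve(days[post], vols[post], interpolate)
            reg = regression_percent(curve)
            row.update(
                doubling_time_post=doubling_time_from_data(curve),
                regression_pct=reg.percent,
                regression_raw_pct=reg.raw_percent,
                vmin=reg.vmin,
                response=classify_response(curve, thresholds=thresholds),
            )
        rows.append(row)
    per_animal = pd.DataFrame(rows)

    resp_rows = []
    treated_arms = per_animal[per_animal["treated"] & per_animal["response"].notna()] \
        if "response" in per_animal else per_animal.iloc[0:0]
    for (group, gender), sub in treated_arms.groupby(["group", "gender"]):
        counts = {cls: int((sub["response"] == cls).sum()) for cls in RESPONSE_CLASSES}
        n = len(sub)
        resp_rows.append(
            {
                "group": group, "gender": gender, "n": n, **counts,
                **{f"{cls}_pct": percent(counts[cls], n, 1) for cls in RESPONSE_CLASSES},
                "overall_effectiveness_pct": overall_effectiveness(sub["response"]),
                "regression_mean_pct": float(sub["regression_pct"].mean()),
            }
        )
    response_table = pd.DataFrame(resp_rows)

    dt_rows = []
    for (group, gender), sub in per_animal.groupby(["group", "gender"]):
        pre_dts = sub.get("doubling_time_pre", pd.Series(dtype=float)).dropna()
        post_dts = sub.get("doubling_time_post", pd.Series(dtype=float)).dropna()
        dt_rows.append(
            {
                "group": group, "gender": gender, "n": len(sub),
                "dt_pre_mean": _finite_mean(pre_dts),
                "dt_pre_sem": _finite_sem(pre_dts),
                "dt_post_mean": _finite_mean(post_dts),
                "dt_post_sem": _finite_sem(post_dts),
            }
        )
    doubling_table = pd.DataFrame(dt_rows)

    if not doubling_table.empty:
        doubling_table["growth_delay"] = [
            _growth_delay_row(row, doubling_table) for _, row in doubling_table.iterrows()
        ]
    return per_animal, response_table, doubling_table


_CONTROL_FOR = {"TG1": "CG1"}  # C-I treated arm vs the C-I control; others vs CG2


def _growth_delay_row(row, table) -> float:
    if str(row["group"]).startswith("CG"):
        return math.nan
    control = _CONTROL_FOR.get(row["group"], "CG2")
    ref = table[(table["group"] == control) & (table["gender"] == row["gender"])]
    if ref.empty or not math.isfinite(ref["dt_post_mean"].iloc[0]):
        return math.nan
    if not math.isfinite(row["dt_post_mean"]):
        return math.inf
    return float(row["dt_post_mean"] / ref["dt_post_mean"].iloc[0])


def _finite_mean(values) -> float:
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else math.nan


def _finite_sem(values) -> float:
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size <= 1:
        return 0.0
    return float(vals.std(ddof=1) / math.sqrt(vals.size))
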