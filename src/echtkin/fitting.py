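"""Two-stage per-animal fitting of tumor growth kinetics.

Stage 1 (pre-treatment window, days 18-31 re-zeroed to t = 0) fits the
unperturbed Gompertz law for (alpha, beta) with V0 fixed to the observed
origin-day volume.  Stage 2 (post-treatment window, days 31-49 re-zeroed)
freezes (alpha, beta) and fits the modified Gompertz equation for
(i0, gamma) given the applied current.  Both stages minimise the sum of
squared volume residuals with a Levenberg-Marquardt solver working on
log-transformed parameters (positivity without hard bounds), with a small
multi-start fallback on non-convergence.  Parameter standard errors come
from the Jacobian-based covariance scaled by the residual variance,
cov = s^2 (J^T J)^{-1} with s^2 = SSE/(n - k).

The fitters are scikit-learn style estimators (``fit``/``predict``,
``get_params``, trailing-underscore attributes); the ``fit_tgk1`` /
``fit_tgk2`` / ``fit_pipeline`` functions are thin wrappers over them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
from scipy.optimize import least_squares

from . import assessment
from .cohort import StudyDesign
from .growth_models import EChTParams, GompertzParams, gompertz_volume, mge_volume

__all__ = [
    "VolumeSeries",
    "FitResult",
    "GompertzCurveFit",
    "MGECurveFit",
    "rezero_time",
    "fit_tgk1",
    "fit_tgk2",
    "fit_pipeline",
    "PipelineResult",
    "group_parameter_summary",
    "press_for_result",
    "mpress_for_result",
]

_LSQ_KW = dict(method="lm", ftol=1e-15, xtol=1e-15, gtol=1e-15)
_MAX_NFEV = 500

# Soft parameter domains: log-transformed parameters keep the optimizer
# positive, and estimates are projected onto these boxes afterwards (the
# cost is flat beyond them: e.g. gamma above ~5/day is indistinguishable
# on a twice-weekly schedule).
_BOUNDS = {
    "alpha": (1e-6, 5.0),
    "beta": (1e-6, 5.0),
    "i0": (1e-3, 100.0),
    "gamma": (1e-3, 200.0),
}


def _clip(name: str, value: float) -> float:
    lo, hi = _BOUNDS[name]
    return float(min(max(value, lo), hi))


@dataclass(frozen=True)
class VolumeSeries:
    """One animal's (day, volume) observations with identifying metadata."""

    days: np.ndarray
    volumes: np.ndarray
    animal_id: str = ""
    group: str = ""
    gender: str = ""

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        order = np.argsort(days)
        object.__setattr__(self, "days", days[order])
        object.__setattr__(self, "volumes", volumes[order])
        if self.days.size != self.volumes.size:
            raise ValueError("days and volumes must have equal length")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be positive")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("observation days must be distinct")

    def __len__(self) -> int:
        return int(self.days.size)

    def window(self, start: float, stop: float) -> "VolumeSeries":
        """Observations with start <= day <= stop."""
        mask = (self.days >= start) & (self.days <= stop)
        return VolumeSeries(
            self.days[mask], self.volumes[mask],
            self.animal_id, self.group, self.gender,
        )


def rezero_time(series: VolumeSeries, origin_day: float) -> VolumeSeries:
    """Shift times so the window origin is t = 0 and V(0) is the observed
    origin-day volume (the stage's initial condition).

    Requires an observation at ``origin_day``; observations before it are
    dropped.
    """
    if origin_day > series.days[-1]:
        raise ValueError(
            f"origin day {origin_day} lies after the last observation {series.days[-1]}"
        )
    if not np.any(np.isclose(series.days, origin_day)):
        raise ValueError(f"no observation at origin day {origin_day}")
    mask = series.days >= origin_day - 1e-9
    return VolumeSeries(
        series.days[mask] - origin_day, series.volumes[mask],
        series.animal_id, series.group, series.gender,
    )


@dataclass
class FitResult:
    """Outcome of one stage fit: estimates, errors, residuals, diagnostics."""

    stage: str                      # "TGK1", "TGK2" or "full"
    params: dict                    # {"alpha":, "beta":} or {"i0":, "gamma":}
    errors: dict                    # matching standard errors
    covariance: np.ndarray
    v0: float
    days: np.ndarray                # re-zeroed times used in the fit
    volumes: np.ndarray
    predicted: np.ndarray
    residuals: np.ndarray           # predicted - observed
    sse: float
    n_points: int
    k: int
    converged: bool
    degenerate: bool = False
    n_iterations: int = 0
    frozen: dict = field(default_factory=dict)   # TGK2: alpha, beta, current
    animal_id: str = ""
    group: str = ""
    gender: str = ""

    @property
    def ratio(self) -> float | None:
        """Current ratio i/i0 for stage-2 fits, else None."""
        if "i0" in self.params and "current" in self.frozen:
            return self.frozen["current"] / self.params["i0"]
        return None

    def predict(self, days) -> np.ndarray:
        days = np.asarray(days, dtype=float)
        if "alpha" in self.params:
            p = GompertzParams(self.v0, self.params["alpha"], self.params["beta"])
            return gompertz_volume(days, p)
        p = GompertzParams(self.v0, self.frozen["alpha"], self.frozen["beta"])
        e = EChTParams(self.frozen["current"], self.params["i0"], self.params["gamma"])
        return mge_volume(days, p, e)


def _gompertz_model_jac(t, v0, alpha, beta):
    """Model values and Jacobian wrt (alpha, beta)."""
    with np.errstate(all="ignore"):
        ebt = np.exp(-beta * t)
        g = (1.0 - ebt) / beta
        v = v0 * np.exp(alpha * g)
        d_alpha = v * g
        d_beta = v * alpha * (t * ebt / beta - g / beta)
        return v, np.column_stack([d_alpha, d_beta])


def _mge_model_jac(t, v0, alpha, beta, i, i0, gamma):
    """Model values and Jacobian wrt (i0, gamma) with (alpha, beta) frozen."""
    with np.errstate(all="ignore"):
        return _mge_model_jac_inner(t, v0, alpha, beta, i, i0, gamma)


def _mge_model_jac_inner(t, v0, alpha, beta, i, i0, gamma):
    r = i / i0
    a1 = r * (2.0 - r)
    a2 = 1.0 - r
    egt = np.exp(-gamma * t)
    astar = (a1 * (1.0 - egt) + a2) * alpha
    ebt = np.exp(-beta * t)
    g = (1.0 - ebt) / beta
    v = v0 * np.exp(astar * g)
    # d astar / dr, chain through dr/di0 = -r/i0
    dastar_dr = ((2.0 - 2.0 * r) * (1.0 - egt) - 1.0) * alpha
    d_i0 = v * g * dastar_dr * (-r / i0)
    d_gamma = v * g * a1 * alpha * t * egt
    return v, np.column_stack([d_i0, d_gamma])


class _Solution:
    def __init__(self, x, cost, status, nfev):
        self.x, self.cost, self.status, self.nfev = x, cost, status, nfev


def _polish_gauss_newton(residual_jac, x, max_steps=25):
    """Drive the gradient to zero with undamped Gauss-Newton steps.

    Cost-based stopping leaves the estimate anywhere in a flat (alpha, beta)
    valley where the cost varies below machine precision; iterating to the
    stationary point of the normal equations makes the optimum a
    deterministic function of the data, independent of the start.
    """
    resid, jac = residual_jac(x)
    cost = float(resid @ resid)
    for _ in range(max_steps):
        try:
            step, *_ = np.linalg.lstsq(jac, -resid, rcond=None)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        scale = 1.0
        for _ in range(12):
            x_new = x + scale * step
            resid_new, jac_new = residual_jac(x_new)
            cost_new = float(resid_new @ resid_new)
            if np.isfinite(cost_new) and cost_new <= cost * (1.0 + 1e-12):
                break
            scale *= 0.5
        else:
            break
        x, resid, jac, cost = x_new, resid_new, jac_new, min(cost, cost_new)
        if np.linalg.norm(scale * step) < 1e-13:
            break
    return x, cost


def _run_lm(residual_jac, x0_list, max_nfev):
    """Log-space Levenberg-Marquardt from one or more starts, Gauss-Newton
    polished; the lowest-cost solution wins."""
    best = None
    for x0 in x0_list:
        try:
            res = least_squares(
                lambda th: residual_jac(th)[0],
                x0,
                jac=lambda th: residual_jac(th)[1],
                max_nfev=max_nfev,
                **_LSQ_KW,
            )
        except Exception:  # numerical failure on a bad start
            continue
        x, cost = _polish_gauss_newton(residual_jac, res.x)
        sol = _Solution(x, cost, res.status, res.nfev)
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def _covariance(jac_nat, residuals, n, k):
    """cov = s^2 (J^T J)^{-1} with s^2 = SSE/(n-k); pseudo-inverse for
    weakly identified directions."""
    sse = float(residuals @ residuals)
    s2 = sse / (n - k) if n > k else np.nan
    jtj = jac_nat.T @ jac_nat
    try:
        cov = s2 * np.linalg.pinv(jtj)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    return cov


class GompertzCurveFit(RegressorMixin, BaseEstimator):
    """Unperturbed Gompertz growth-curve regressor (stage-1 / control fits).

    Fits (alpha, beta) of V(t) = v0*exp((alpha/beta)(1 - e^{-beta t})) by
    damped least squares on log-parameters, with V0 fixed to the observation
    at t = 0 (or given explicitly).

    Parameters
    ----------
    v0 : float or None
        Initial volume (cm^3).  None fixes it to the observed volume at
        the smallest time, which must then be t = 0.
    alpha0, beta0 : float or None
        Starting values (1/day).  alpha0 = None uses the log-volume slope
        over the first three points.
    n_restarts : int
        Jittered restarts attempted when the first solve fails to converge.

    Attributes
    ----------
    alpha_, beta_ : float
        Estimated rates (1/day).
    stderr_alpha_, stderr_beta_ : float
    covariance_ : ndarray of shape (2, 2)
    residuals_, sse_, converged_, degenerate_, n_iter_, v0_
    """

    def __init__(self, v0=None, alpha0=None, beta0=0.02,
                 max_nfev=_MAX_NFEV, n_restarts=5, random_state=0):
        self.v0 = v0
        self.alpha0 = alpha0
        self.beta0 = beta0
        self.max_nfev = max_nfev
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _initial_alpha(self, t, y):
        if self.alpha0 is not None:
            return float(self.alpha0)
        m = min(3, t.size)
        span = t[m - 1] - t[0]
        slope = (math.log(y[m - 1]) - math.log(y[0])) / span if span > 0 else 0.1
        return float(np.clip(slope, 1e-3, 5.0))

    def fit(self, X, y):
        t, y = _check_times_volumes(X, y)
        if self.v0 is None:
            if not np.isclose(t[0], 0.0):
                raise ValueError("v0=None requires an observation at t = 0")
            v0 = float(y[0])
        else:
            v0 = float(self.v0)
            if v0 <= 0:
                raise ValueError("v0 must be positive")
        self.v0_ = v0
        self.n_features_in_ = 1

        if np.ptp(y) <= 1e-12 * max(1.0, float(np.max(y))):
            # Flat series: alpha -> 0, nothing identifiable.
            self.alpha_, self.beta_ = 0.0, float(self.beta0)
            self.stderr_alpha_ = self.stderr_beta_ = math.nan
            self.covariance_ = np.full((2, 2), np.nan)
            self.residuals_ = v0 - y
            self.sse_ = float(self.residuals_ @ self.residuals_)
            self.converged_, self.degenerate_, self.n_iter_ = False, True, 0
            return self

        def residual_jac(theta):
            with np.errstate(over="ignore", invalid="ignore"):
                alpha, beta = np.exp(theta)
                v, jac_nat = _gompertz_model_jac(t, v0, alpha, beta)
                return v - y, jac_nat * np.array([alpha, beta])

        x0 = np.log([self._initial_alpha(t, y), float(self.beta0)])
        res = _run_lm(residual_jac, [x0], self.max_nfev)
        if res is None or res.status <= 0:
            rng = np.random.default_rng(self.random_state)
            jitters = [x0 + rng.normal(0, 0.5, size=2) for _ in range(self.n_restarts)]
            res2 = _run_lm(residual_jac, jitters, self.max_nfev)
            if res2 is not None and (res is None or res2.cost < res.cost):
                res = res2
        if res is None:
            raise RuntimeError("Gompertz fit failed from every start")

        self.alpha_ = _clip("alpha", float(np.exp(res.x[0])))
        self.beta_ = _clip("beta", float(np.exp(res.x[1])))
        v, jac_nat = _gompertz_model_jac(t, v0, self.alpha_, self.beta_)
        self.residuals_ = v - y
        self.sse_ = float(self.residuals_ @ self.residuals_)
        self.covariance_ = _covariance(jac_nat, self.residuals_, t.size, 2)
        self.stderr_alpha_, self.stderr_beta_ = (
            float(math.sqrt(max(c, 0.0))) for c in np.diag(self.covariance_)
        )
        self.converged_ = bool(res.status > 0)
        self.degenerate_ = False
        self.n_iter_ = int(res.nfev)
        return self

    def predict(self, X):
        check_is_fitted(self, "alpha_")
        t = _check_times(X)
        if self.degenerate_:
            return np.full(t.shape, self.v0_)
        p = GompertzParams(self.v0_, self.alpha_, self.beta_)
        return np.asarray(gompertz_volume(t, p), dtype=float)


class MGECurveFit(RegressorMixin, BaseEstimator):
    """Modified-Gompertz regressor for the post-treatment window (stage 2).

    Fits (i0, gamma) with (alpha, beta) frozen to the same animal's stage-1
    estimates and the applied current given; V0 is fixed to the observed
    treatment-day volume.  Parameters are log-transformed so i0, gamma > 0.

    Attributes include ``i0_``, ``gamma_``, their standard errors, and
    ``ratio_`` = current/i0_.
    """

    def __init__(self, current=None, alpha=None, beta=None, v0=None,
                 i0_init=None, gamma0=10.0,
                 max_nfev=_MAX_NFEV, n_restarts=5, random_state=0):
        self.current = current
        self.alpha = alpha
        self.beta = beta
        self.v0 = v0
        self.i0_init = i0_init
        self.gamma0 = gamma0
        self.max_nfev = max_nfev
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y):
        if self.current is None or self.alpha is None or self.beta is None:
            raise ValueError("current, alpha and beta must be set before fitting")
        if self.current <= 0:
            raise ValueError(
                "stage-2 fits require a positive applied current "
                "(control animals are not stage-2 fitted)"
            )
        t, y = _check_times_volumes(X, y)
        if self.v0 is None:
            if not np.isclose(t[0], 0.0):
                raise ValueError("v0=None requires an observation at t = 0")
            v0 = float(y[0])
        else:
            v0 = float(self.v0)
        self.v0_ = v0
        self.n_features_in_ = 1
        i, alpha, beta = float(self.current), float(self.alpha), float(self.beta)

        def residual_jac(theta):
            with np.errstate(over="ignore", invalid="ignore"):
                i0, gamma = np.exp(theta)
                v, jac_nat = _mge_model_jac(t, v0, alpha, beta, i, i0, gamma)
                return v - y, jac_nat * np.array([i0, gamma])

        # (i0, gamma) sit on an identifiability ridge: gamma -> inf with
        # ratio r and gamma -> 0 with ratio 1 - (1 + r - r^2) produce the
        # same constant effective rate.  Profile i0 first with gamma frozen
        # at its initial guess; the joint refinement then starts on the
        # branch where the treatment effect saturates, and the flatness of
        # the gamma direction shows up honestly in its standard error.
        gamma0 = float(self.gamma0)
        # Observed ratios cluster near 1.3-1.5, so i/1.3 is a sensible start.
        i0_init = float(self.i0_init) if self.i0_init is not None else i / 1.3

        def residual_jac_i0(theta1):
            resid, jac = residual_jac(np.array([theta1[0], math.log(gamma0)]))
            return resid, jac[:, :1]

        prof = _run_lm(residual_jac_i0, [np.array([math.log(i0_init)])], self.max_nfev)
        if prof is not None:
            i0_init = float(np.exp(prof.x[0]))
        x0 = np.log([i0_init, gamma0])
        res = _run_lm(residual_jac, [x0], self.max_nfev)
        if res is None or res.status <= 0:
            rng = np.random.default_rng(self.random_state)
            jitters = [x0 + rng.normal(0, 0.5, size=2) for _ in range(self.n_restarts)]
            res2 = _run_lm(residual_jac, jitters, self.max_nfev)
            if res2 is not None and (res is None or res2.cost < res.cost):
                res = res2
        if res is None:
            raise RuntimeError("MGE fit failed from every start")

        self.i0_ = _clip("i0", float(np.exp(res.x[0])))
        self.gamma_ = _clip("gamma", float(np.exp(res.x[1])))
        self.ratio_ = i / self.i0_
        v, jac_nat = _mge_model_jac(t, v0, alpha, beta, i, self.i0_, self.gamma_)
        self.residuals_ = v - y
        self.sse_ = float(self.residuals_ @ self.residuals_)
        self.covariance_ = _covariance(jac_nat, self.residuals_, t.size, 2)
        self.stderr_i0_, self.stderr_gamma_ = (
            float(math.sqrt(max(c, 0.0))) for c in np.diag(self.covariance_)
        )
        self.converged_ = bool(res.status > 0)
        self.degenerate_ = False
        self.n_iter_ = int(res.nfev)
        return self

    def predict(self, X):
        check_is_fitted(self, "i0_")
        t = _check_times(X)
        p = GompertzParams(self.v0_, float(self.alpha), float(self.beta))
        e = EChTParams(float(self.current), self.i0_, self.gamma_)
        return np.asarray(mge_volume(t, p, e), dtype=float)


def _check_times(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("X must have a single time column")
        X = X[:, 0]
    if np.any(X < 0):
        raise ValueError("times must be >= 0 (re-zero the window first)")
    return X


def _check_times_volumes(X, y):
    t = _check_times(X)
    y = np.asarray(y, dtype=float)
    if t.size != y.size:
        raise ValueError("X and y must have equal length")
    if t.size < 3:
        raise ValueError(f"need >= 3 observations per fit, got {t.size}")
    if np.any(y <= 0):
        raise ValueError("volumes must be positive")
    order = np.argsort(t)
    return t[order], y[order]


def _result_from_estimator(est, stage, series: VolumeSeries, params, errors,
                           frozen=None) -> FitResult:
    predicted = est.predict(series.days.reshape(-1, 1))
    return FitResult(
        stage=stage,
        params=params,
        errors=errors,
        covariance=est.covariance_,
        v0=est.v0_,
        days=series.days,
        volumes=series.volumes,
        predicted=predicted,
        residuals=est.residuals_,
        sse=assessment.sse(series.volumes, predicted),
        n_points=len(series),
        k=2,
        converged=est.converged_,
        degenerate=est.degenerate_,
        n_iterations=est.n_iter_,
        frozen=frozen or {},
        animal_id=series.animal_id,
        group=series.group,
        gender=series.gender,
    )


def fit_tgk1(series: VolumeSeries, *, stage: str = "TGK1", min_points: int = 4,
             **estimator_kw) -> FitResult:
    """Stage-1 fit of the re-zeroed pre-treatment window (V0 = origin volume)."""
    if len(series) < min_points:
        raise ValueError(f"need >= {min_points} observations, got {len(series)}")
    est = GompertzCurveFit(**estimator_kw).fit(series.days.reshape(-1, 1), series.volumes)
    return _result_from_estimator(
        est, stage, series,
        params={"alpha": est.alpha_, "beta": est.beta_},
        errors={"alpha": est.stderr_alpha_, "beta": est.stderr_beta_},
    )


def fit_tgk2(series: VolumeSeries, alpha: float, beta: float, current: float,
             *, min_points: int = 4, **estimator_kw) -> FitResult:
    """Stage-2 fit with (alpha, beta) frozen from stage 1 and the current given."""
    if len(series) < min_points:
        raise ValueError(f"need >= {min_points} observations, got {len(series)}")
    est = MGECurveFit(current=current, alpha=alpha, beta=beta, **estimator_kw)
    est.fit(series.days.reshape(-1, 1), series.volumes)
    return _result_from_estimator(
        est, "TGK2", series,
        params={"i0": est.i0_, "gamma": est.gamma_},
        errors={"i0": est.stderr_i0_, "gamma": est.stderr_gamma_},
        frozen={"alpha": alpha, "beta": beta, "current": current},
    )


@dataclass
class PipelineResult:
    """Per-animal fits plus the eligibility bookkeeping of a cohort run."""

    tgk1: dict            # animal_id -> FitResult
    tgk2: dict
    full: dict
    excluded: dict        # animal_id -> reason
    frame: pd.DataFrame   # per-animal parameter table

    def stage_results(self, stage: str) -> list[FitResult]:
        return list({"TGK1": self.tgk1, "TGK2": self.tgk2, "full": self.full}[stage].values())


def _series_for_window(sub: pd.DataFrame, start, stop, volume_limit):
    mask = (sub["day"] >= start) & (sub["day"] <= stop) & (sub["volume_cm3"] < volume_limit)
    win = sub[mask]
    if win.empty:
        return None
    return VolumeSeries(
        win["day"].to_numpy(float), win["volume_cm3"].to_numpy(float),
        animal_id=str(sub["animal_id"].iloc[0]),
        group=str(sub["group"].iloc[0]),
        gender=str(sub["gender"].iloc[0]),
    )


def fit_pipeline(
    frame: pd.DataFrame,
    design: StudyDesign | None = None,
    *,
    tgk1_window: tuple[float, float] = (18.0, 31.0),
    tgk2_window: tuple[float, float] = (31.0, 49.0),
    volume_limit: float = 2.0,
    min_points: int = 4,
    cap_per_arm: int | None = None,
    fit_full_controls: bool = True,
    fit_on_interpolated: bool = False,
    rng: np.random.Generator | int | None = None,
) -> PipelineResult:
    """Run the two-stage protocol over a long-format cohort table.

    Eligibility mirrors the study: observations at or above ``volume_limit``
    (2 cm^3, the ethics limit) are excluded, each stage needs at least
    ``min_points`` remaining observations including the window origin, and
    stage 2 additionally needs a converged stage 1 and a positive current.
    ``cap_per_arm`` optionally subsamples eligible animals per group-gender
    arm (the study fitted 5 per gender).  Control animals additionally get a
    full-range Gompertz fit (origin at the first window day).

    By default each stage fits the raw observations; with
    ``fit_on_interpolated=True`` the objective instead uses the window's
    daily shape-preserving interpolation (useful when raw points are too
    few for the decay term).

    Emits per-animal results and a flat parameter table; group summaries come
    from :func:`group_parameter_summary`.
    """
    required = {"animal_id", "group", "gender", "day", "volume_cm3", "current_ma"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    if rng is not None and not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    tgk1: dict[str, FitResult] = {}
    tgk2: dict[str, FitResult] = {}
    full: dict[str, FitResult] = {}
    excluded: dict[str, str] = {}

    animal_ids = list(dict.fromkeys(frame["animal_id"]))
    if cap_per_arm is not None:
        animal_ids = _subsample_arms(frame, animal_ids, cap_per_arm, rng)

    def _maybe_interpolate(series: VolumeSeries) -> VolumeSeries:
        if not fit_on_interpolated or len(series) < 3:
            return series
        from .interpolation import hermite_interpolate

        curve = hermite_interpolate(series.days, series.volumes)
        return VolumeSeries(curve.grid, curve.values,
                            series.animal_id, series.group, series.gender)

    for animal_id in animal_ids:
        sub = frame[frame["animal_id"] == animal_id]
        current = float(sub["current_ma"].iloc[0])

        s1 = _series_for_window(sub, *tgk1_window, volume_limit)
        if s1 is None or len(s1) < min_points:
            excluded[animal_id] = "too few pre-treatment observations below the limit"
            continue
        try:
            s1z = _maybe_interpolate(rezero_time(s1, tgk1_window[0]))
        except ValueError:
            excluded[animal_id] = "no observation at the pre-treatment origin day"
            continue
        r1 = fit_tgk1(s1z, min_points=min_points)
        r1.animal_id, r1.group, r1.gender = s1.animal_id, s1.group, s1.gender
        tgk1[animal_id] = r1

        if current > 0:
            s2 = _series_for_window(sub, *tgk2_window, volume_limit)
            if s2 is not None and len(s2) >= min_points and r1.converged:
                try:
                    s2z = rezero_time(s2, tgk2_window[0])
                except ValueError:
                    s2z = None
                if s2z is not None:
                    r2 = fit_tgk2(
                        _maybe_interpolate(s2z),
                        r1.params["alpha"], r1.params["beta"], current,
                        min_points=min_points,
                    )
                    tgk2[animal_id] = r2
        elif fit_full_controls:
            sf = _series_for_window(sub, tgk1_window[0], tgk2_window[1], volume_limit)
            if sf is not None and len(sf) >= min_points:
                try:
                    sfz = rezero_time(sf, tgk1_window[0])
                except ValueError:
                    sfz = None
                if sfz is not None:
                    full[animal_id] = fit_tgk1(sfz, stage="full", min_points=min_points)

    if not tgk1:
        warnings.warn("no animals were eligible for fitting", stacklevel=2)
    return PipelineResult(
        tgk1=tgk1, tgk2=tgk2, full=full, excluded=excluded,
        frame=_results_frame(tgk1, tgk2, full),
    )


def _subsample_arms(frame, animal_ids, cap, rng):
    arms: dict[tuple, list[str]] = {}
    meta = frame.drop_duplicates("animal_id").set_index("animal_id")
    for animal_id in animal_ids:
        key = (meta.loc[animal_id, "group"], meta.loc[animal_id, "gender"])
        arms.setdefault(key, []).append(animal_id)
    kept = []
    for ids in arms.values():
        if len(ids) <= cap:
            kept.extend(ids)
        elif rng is None:
            kept.extend(ids[:cap])
        else:
            kept.extend(rng.choice(ids, size=cap, replace=False))
    return [a for a in animal_ids if a in set(kept)]


def _results_frame(tgk1, tgk2, full) -> pd.DataFrame:
    rows = []
    for stage, results in (("TGK1", tgk1), ("TGK2", tgk2), ("full", full)):
        for animal_id, r in results.items():
            row = {
                "animal_id": animal_id, "group": r.group, "gender": r.gender,
                "stage": stage, "n_points": r.n_points, "sse": r.sse,
                "converged": r.converged,
            }
            for name, val in r.params.items():
                row[name] = val
                row[f"e_{name}"] = r.errors[name]
            if r.ratio is not None:
                row["ratio"] = r.ratio
            rows.append(row)
    return pd.DataFrame(rows)


def group_parameter_summary(
    results: list[FitResult],
    ratio_mode: str = "ratio-of-means",
) -> pd.DataFrame:
    """Mean +/- SEM of fitted parameters per group-gender arm.

    ``ratio_mode`` selects how the group current ratio is aggregated:
    ``"ratio-of-means"`` (i divided by the mean i0, the study's table
    convention) or ``"mean-of-ratios"``.
    """
    if ratio_mode not in ("ratio-of-means", "mean-of-ratios"):
        raise ValueError(f"unknown ratio_mode {ratio_mode!r}")
    by_arm: dict[tuple, list[FitResult]] = {}
    for r in results:
        by_arm.setdefault((r.group, r.gender), []).append(r)
    rows = []
    for (group, gender), fits in sorted(by_arm.items()):
        row = {"group": group, "gender": gender, "n": len(fits)}
        names = list(fits[0].params)
        for name in names:
            vals = np.array([f.params[name] for f in fits])
            errs = np.array([f.errors[name] for f in fits])
            row[f"{name}_mean"] = vals.mean()
            row[f"{name}_sem"] = _sem(vals)
            row[f"e_{name}_mean"] = np.nanmean(errs)
            row[f"e_{name}_sem"] = _sem(errs[~np.isnan(errs)])
        if "i0" in names:
            current = fits[0].frozen["current"]
            if ratio_mode == "ratio-of-means":
                row["ratio"] = current / np.mean([f.params["i0"] for f in fits])
            else:
                row["ratio"] = float(np.mean([f.ratio for f in fits]))
        sses = np.array([f.sse for f in fits])
        row["sse_mean"], row["sse_sem"] = sses.mean(), _sem(sses)
        rows.append(row)
    return pd.DataFrame(rows)


def _refit_estimator(result: FitResult, warm_start: bool):
    """Fresh estimator configured like the stage fit behind ``result``.

    Warm starts reuse the converged estimates as initial values; this
    stabilises leave-one-out refits without moving converged optima.
    """
    if "alpha" in result.params:
        if warm_start:
            return GompertzCurveFit(
                v0=result.v0,
                alpha0=result.params["alpha"], beta0=result.params["beta"],
            )
        return GompertzCurveFit(v0=result.v0)
    kw = dict(
        current=result.frozen["current"],
        alpha=result.frozen["alpha"], beta=result.frozen["beta"],
        v0=result.v0,
    )
    if warm_start:
        kw.update(i0_init=result.params["i0"], gamma0=result.params["gamma"])
    return MGECurveFit(**kw)


def press_for_result(result: FitResult, mode: str = "printed",
                     warm_start: bool = False) -> float:
    """PRESS for a stage fit: refit the stage with each point deleted.

    The window's initial condition stays anchored at the observed origin
    volume even when the origin point itself is deleted.  Refits default to
    the cold-start protocol: on noisy windows the cost surface can hold
    adjacent shallow optima, and a deterministic start makes the statistic a
    reproducible function of the data alone.
    """

    def fit_predict(days, volumes, j):
        keep = np.ones(days.size, dtype=bool)
        keep[j] = False
        est = _refit_estimator(result, warm_start)
        est.fit(days[keep].reshape(-1, 1), volumes[keep])
        return float(est.predict(np.array([[days[j]]]))[0])

    return assessment.press(result.days, result.volumes, fit_predict,
                            k=result.k, mode=mode)


def mpress_for_result(result: FitResult, m: int = 3,
                      warm_start: bool = False) -> float:
    """MPRESS(m) for a stage fit: fit the first m points, forecast the rest."""

    def fit_forecast(days, volumes, m):
        est = _refit_estimator(result, warm_start)
        est.fit(days[:m].reshape(-1, 1), volumes[:m])
        return est.predict(days[m:].reshape(-1, 1))

    return assessment.mpress(result.days, result.volumes, fit_forecast, m=m)


def _sem(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size <= 1:
        return 0.0
    return float(values.std(ddof=1) / math.sqrt(values.size))
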