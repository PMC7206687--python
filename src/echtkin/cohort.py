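"""Synthetic preclinical cohorts of DC-treated tumors.

The assay's raw animal data are confidential, so this module generates
per-animal longitudinal caliper series with the study's design: 8 groups
(2 controls, 6 treated) x 2 genders x 10 mice = 160 animals, tumor cells
inoculated at day 0, palpable tumor after a gender/group-specific latency,
twice-weekly caliper measurements from day 18, treatment at day 31 when the
tumor is near 0.5 cm^3, follow-up to day 49 (n1 = 11 scheduled points per
animal), multiplicative lognormal measurement noise, pre/post-treatment
death hazards and ethics censoring at 2 cm^3.

Per-animal true trajectories are Gompertz before treatment (anchored so the
true volume at the treatment day hits the drawn treatment-size target) and
modified-Gompertz afterwards, re-anchored at the treatment-day volume.
Caliper diameters (major a, minor b, in mm) are back-solved from each noisy
volume through V = pi*a*b^2/6 with a random aspect ratio a/b in [1, 2], so
recorded volumes and diameters are exactly consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .growth_models import EChTParams, GompertzParams, gompertz_volume, mge_volume

__all__ = [
    "GroupSpec",
    "StudyDesign",
    "PopulationHyper",
    "MouseRecord",
    "default_groups",
    "default_design",
    "default_hyper",
    "diameters_to_volume",
    "volume_to_diameters",
    "sample_animal_params",
    "simulate_mouse",
    "simulate_cohort",
    "cohort_to_frame",
    "design_to_frame",
]

MEASUREMENT_DAYS = (18, 21, 25, 28, 31, 32, 35, 38, 42, 45, 49)

FATE_COMPLETED = "completed"
FATE_DIED_PRE = "died_pre_treatment"
FATE_DIED_POST = "died_post_treatment"
FATE_CENSORED = "censored_large_tumor"


@dataclass(frozen=True)
class GroupSpec:
    """One experimental arm: label, gender, electrode geometry tag and DC dose."""

    label: str
    gender: str  # "F" or "M"
    geometry: str  # "C-I", "C-II", "C-III" or "none"
    current_ma: float
    exposure_min: float
    n_animals: int
    control: bool

    def __post_init__(self) -> None:
        if self.gender not in ("F", "M"):
            raise ValueError(f"gender must be 'F' or 'M', got {self.gender!r}")
        if self.control and self.current_ma != 0:
            raise ValueError(f"control group {self.label} must have zero current")
        if not self.control and self.current_ma <= 0:
            raise ValueError(f"treated group {self.label} must have positive current")
        if self.n_animals <= 0:
            raise ValueError("n_animals must be positive")

    @property
    def full_label(self) -> str:
        return f"{self.label}-{self.gender}"


# (label, geometry, current mA, exposure min, control?) — study arms.
_GROUP_TABLE = (
    ("CG1", "C-I", 0.0, 0.0, True),
    ("CG2", "C-II", 0.0, 0.0, True),
    ("TG1", "C-I", 2.0, 10.0, False),
    ("TG2", "C-II", 6.0, 20.0, False),
    ("TG3", "C-III", 2.0, 10.0, False),
    ("TG4", "C-II", 2.0, 10.0, False),
    ("TG5", "C-II", 6.0, 10.0, False),
    ("TG6", "C-II", 10.0, 10.0, False),
)


def default_groups(n_per_gender: int = 10) -> list[GroupSpec]:
    """The study's 8 arms x 2 genders (default 10 animals each: 160 total)."""
    groups = []
    for label, geom, i, t_exp, control in _GROUP_TABLE:
        for gender in ("F", "M"):
            groups.append(
                GroupSpec(
                    label=label,
                    gender=gender,
                    geometry=geom,
                    current_ma=i,
                    exposure_min=t_exp,
                    n_animals=n_per_gender,
                    control=control,
                )
            )
    return groups


@dataclass(frozen=True)
class StudyDesign:
    """Scheduling skeleton: inoculation at day 0, treatment day, follow-up end,
    twice-weekly measurement days."""

    groups: tuple[GroupSpec, ...]
    treatment_day: int = 31
    last_day: int = 49
    measurement_days: tuple[int, ...] = MEASUREMENT_DAYS

    def __post_init__(self) -> None:
        days = tuple(sorted(self.measurement_days))
        object.__setattr__(self, "measurement_days", days)
        if self.treatment_day not in days:
            raise ValueError("treatment_day must be a measurement day")
        if days[-1] != self.last_day:
            raise ValueError("last measurement day must equal last_day")
        labels = [g.full_label for g in self.groups]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate group labels in design")

    @property
    def n_animals(self) -> int:
        return sum(g.n_animals for g in self.groups)


def default_design(n_per_gender: int = 10) -> StudyDesign:
    return StudyDesign(groups=tuple(default_groups(n_per_gender)))


# Gender-specific latency means (days post-inoculation to palpable tumor),
# per group, as printed for this study.
_LATENCY_MEAN = {
    ("CG1", "F"): 15.4, ("CG2", "F"): 13.2, ("TG1", "F"): 12.0, ("TG2", "F"): 11.6,
    ("TG3", "F"): 13.2, ("TG4", "F"): 12.6, ("TG5", "F"): 14.0, ("TG6", "F"): 15.0,
    ("CG1", "M"): 11.8, ("CG2", "M"): 12.3, ("TG1", "M"): 11.0, ("TG2", "M"): 12.0,
    ("TG3", "M"): 11.5, ("TG4", "M"): 12.8, ("TG5", "M"): 12.2, ("TG6", "M"): 11.0,
}

# Treated-group polarization current i0 (mA) and decay rate gamma (1/day)
# population means, per gender, at the scale of the study's fitted values.
_I0_MEAN = {
    ("TG1", "F"): 1.561, ("TG2", "F"): 4.061, ("TG3", "F"): 1.413,
    ("TG4", "F"): 1.569, ("TG5", "F"): 4.415, ("TG6", "F"): 6.942,
    ("TG1", "M"): 1.842, ("TG2", "M"): 4.147, ("TG3", "M"): 1.495,
    ("TG4", "M"): 1.516, ("TG5", "M"): 4.333, ("TG6", "M"): 7.119,
}
_GAMMA_MEAN = {
    ("TG1", "F"): 17.742, ("TG2", "F"): 12.890, ("TG3", "F"): 26.291,
    ("TG4", "F"): 36.567, ("TG5", "F"): 49.672, ("TG6", "F"): 13.672,
    ("TG1", "M"): 13.197, ("TG2", "M"): 4.536, ("TG3", "M"): 7.526,
    ("TG4", "M"): 12.742, ("TG5", "M"): 27.890, ("TG6", "M"): 10.291,
}


@dataclass(frozen=True)
class PopulationHyper:
    """Population-level means and dispersions for per-animal parameter draws.

    Defaults reproduce the study's conditions: gender-specific intrinsic
    growth rates (females faster), deceleration factor in the 0.01-0.08/day
    band, group-specific latency, treatment at ~0.5 cm^3, 5% multiplicative
    caliper noise, and death hazards calibrated so that on average ~24.4% of
    animals die before treatment and ~13.5% of survivors afterwards.
    """

    alpha_mean: dict = field(
        default_factory=lambda: {"F": 0.490, "M": 0.422}
    )
    alpha_sd: float = 0.05
    beta_mean: float = 0.045
    beta_sd: float = 0.015
    latency_mean: dict = field(default_factory=lambda: dict(_LATENCY_MEAN))
    latency_sd: float = 2.0
    latency_floor: float = 5.0
    latency_ceil: float = 17.0
    treat_volume_mean: float = 0.5  # cm^3 at the treatment day
    treat_volume_cv: float = 0.10
    i0_mean: dict = field(default_factory=lambda: dict(_I0_MEAN))
    i0_cv: float = 0.08
    gamma_mean: dict = field(default_factory=lambda: dict(_GAMMA_MEAN))
    gamma_cv: float = 0.20
    noise_cv: float = 0.05
    hazard_pre: float = 0.00902   # 1/day; 1 - e^{-31 h} ~ 0.244
    hazard_post: float = 0.00804  # 1/day over days 31-49; 1 - e^{-18 h} ~ 0.135
    aspect_low: float = 1.0
    aspect_high: float = 2.0
    censor_volume: float = 2.0    # cm^3 ethics limit

    def __post_init__(self) -> None:
        for name in ("alpha_sd", "beta_sd", "latency_sd", "treat_volume_cv",
                     "i0_cv", "gamma_cv", "noise_cv", "hazard_pre", "hazard_post"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (1.0 <= self.aspect_low <= self.aspect_high):
            raise ValueError("aspect ratio bounds must satisfy 1 <= low <= high")
        if self.censor_volume <= 0:
            raise ValueError("censor_volume must be positive")


def default_hyper(**overrides) -> PopulationHyper:
    return replace(PopulationHyper(), **overrides) if overrides else PopulationHyper()


@dataclass
class MouseRecord:
    """One simulated animal: identity, true generating parameters and the
    observed (day, major mm, minor mm, volume cm^3) caliper series."""

    animal_id: str
    group: str
    gender: str
    geometry: str
    current_ma: float
    exposure_min: float
    latency: float
    growth: GompertzParams            # anchored at the first measurement day
    echt: EChTParams | None           # None for controls
    first_day: int
    treatment_day: int
    observations: list[tuple[int, float, float, float]]
    fate: str
    fate_day: float

    def true_volume(self, day) -> np.ndarray:
        """Noise-free generating trajectory at absolute day(s) post-inoculation.

        Controls follow one continuous Gompertz curve anchored at the first
        measurement day.  Treated animals follow the same curve up to the
        treatment day, then the modified Gompertz law re-anchored there with
        the time (and deceleration) clock re-zeroed — exactly the model
        family the two-stage protocol fits, so noiseless fits recover the
        generating parameters.
        """
        day = np.atleast_1d(np.asarray(day, dtype=float))
        out = np.full(day.shape, np.nan)
        upto = self.treatment_day if self.echt is not None else math.inf
        pre = (day >= self.first_day) & (day <= upto)
        out[pre] = gompertz_volume(day[pre] - self.first_day, self.growth)
        if self.echt is not None:
            post = day > self.treatment_day
            if post.any():
                v_treat = float(
                    gompertz_volume(self.treatment_day - self.first_day, self.growth)
                )
                p2 = GompertzParams(
                    v0=v_treat, alpha=self.growth.alpha, beta=self.growth.beta
                )
                out[post] = mge_volume(day[post] - self.treatment_day, p2, self.echt)
        return out if out.size > 1 else float(out[0])


def diameters_to_volume(a_mm: float, b_mm: float):
    """Ellipsoid caliper volume V = pi*a*b^2/6 (cm^3) from diameters in mm.

    ``a`` is the major and ``b`` the minor diameter; a >= b > 0 is enforced
    (swapped calipers are an input error, not a convention).
    """
    a = np.asarray(a_mm, dtype=float)
    b = np.asarray(b_mm, dtype=float)
    if np.any(b <= 0):
        raise ValueError("minor diameter must be > 0")
    if np.any(a < b):
        raise ValueError("major diameter a must be >= minor diameter b")
    out = math.pi * (a / 10.0) * (b / 10.0) ** 2 / 6.0
    return out if out.ndim else float(out)


def volume_to_diameters(volume_cm3: float, aspect: float) -> tuple[float, float]:
    """Back-solve (a, b) in mm from a volume and an aspect ratio a/b >= 1."""
    if volume_cm3 <= 0:
        raise ValueError("volume must be positive")
    if aspect < 1.0:
        raise ValueError("aspect ratio a/b must be >= 1")
    b_cm = (6.0 * volume_cm3 / (math.pi * aspect)) ** (1.0 / 3.0)
    return aspect * b_cm * 10.0, b_cm * 10.0


def _trunc_normal(rng, mean, sd, low, high=np.inf):
    """Draw from N(mean, sd) truncated to (low, high) by redrawing; sd=0 -> mean."""
    if sd == 0:
        return float(min(max(mean, low), high))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low < x < high:
            return float(x)
    return float(min(max(mean, low), high))


def _lognormal_factor(rng, cv: float) -> float:
    """Unit-mean multiplicative lognormal factor with coefficient of variation cv."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def sample_animal_params(
    group: GroupSpec,
    hyper: PopulationHyper,
    rng: np.random.Generator,
    treatment_day: int = 31,
    first_day: int = 18,
) -> tuple[float, GompertzParams, EChTParams | None]:
    """Draw one animal's latency, growth and (for treated arms) EChT parameters.

    All draws come from truncated-positive distributions around the
    gender/group-specific population means; with zero dispersions every
    animal receives the group mean exactly.  The drawn ``alpha`` is the
    intrinsic rate at the first measurement day (the fitting windows'
    origin); V0 is anchored there so that the true volume at the treatment
    day equals the drawn treatment-size target (~0.5 cm^3).  Latency is
    recorded as palpability metadata.
    """
    key = (group.label, group.gender)
    alpha = _trunc_normal(rng, hyper.alpha_mean[group.gender], hyper.alpha_sd, 1e-3)
    beta = _trunc_normal(rng, hyper.beta_mean, hyper.beta_sd, 1e-3)
    latency = _trunc_normal(
        rng, hyper.latency_mean.get(key, 13.0), hyper.latency_sd,
        hyper.latency_floor, hyper.latency_ceil,
    )
    v_treat = hyper.treat_volume_mean * _lognormal_factor(rng, hyper.treat_volume_cv)
    span = treatment_day - first_day
    v0 = v_treat / math.exp((alpha / beta) * (1.0 - math.exp(-beta * span)))
    growth = GompertzParams(v0=v0, alpha=alpha, beta=beta)
    if group.control:
        return latency, growth, None
    i0 = hyper.i0_mean[key] * _lognormal_factor(rng, hyper.i0_cv)
    gamma = hyper.gamma_mean[key] * _lognormal_factor(rng, hyper.gamma_cv)
    echt = EChTParams(i=group.current_ma, i0=i0, gamma=gamma)
    return latency, growth, echt


def simulate_mouse(
    animal_id: str,
    group: GroupSpec,
    design: StudyDesign,
    hyper: PopulationHyper,
    rng: np.random.Generator,
) -> MouseRecord:
    """Simulate one animal's observed caliper series and fate.

    Observed volume at each scheduled day is the true trajectory times a
    unit-mean lognormal factor (CV ``hyper.noise_cv``).  Death days are drawn
    from two constant hazards (before/after treatment); the first scheduled
    observation at or above the ethics limit (2 cm^3) is recorded and ends
    the series (``censored_large_tumor``).
    """
    first_day = design.measurement_days[0]
    latency, growth, echt = sample_animal_params(
        group, hyper, rng,
        treatment_day=design.treatment_day, first_day=first_day,
    )
    record = MouseRecord(
        animal_id=animal_id,
        group=group.label,
        gender=group.gender,
        geometry=group.geometry,
        current_ma=group.current_ma,
        exposure_min=group.exposure_min,
        latency=latency,
        growth=growth,
        echt=echt,
        first_day=first_day,
        treatment_day=design.treatment_day,
        observations=[],
        fate=FATE_COMPLETED,
        fate_day=float(design.last_day),
    )

    # Death day from piecewise-constant hazards (exponential waiting times).
    death_day = math.inf
    if hyper.hazard_pre > 0:
        d = rng.exponential(1.0 / hyper.hazard_pre)
        if d < design.treatment_day:
            death_day = d
    if math.isinf(death_day) and hyper.hazard_post > 0:
        d = design.treatment_day + rng.exponential(1.0 / hyper.hazard_post)
        if d <= design.last_day:
            death_day = d
    if death_day < design.treatment_day:
        record.fate = FATE_DIED_PRE
        record.fate_day = death_day
    elif math.isfinite(death_day):
        record.fate = FATE_DIED_POST
        record.fate_day = death_day

    for day in design.measurement_days:
        if day > record.fate_day:
            break
        if day < latency:
            continue  # tumor not yet palpable
        true_v = record.true_volume(day)
        obs_v = true_v * _lognormal_factor(rng, hyper.noise_cv)
        aspect = rng.uniform(hyper.aspect_low, hyper.aspect_high)
        a_mm, b_mm = volume_to_diameters(obs_v, aspect)
        obs_v = diameters_to_volume(a_mm, b_mm)  # exact round trip by construction
        record.observations.append((day, a_mm, b_mm, obs_v))
        if obs_v >= hyper.censor_volume:
            record.fate = FATE_CENSORED
            record.fate_day = float(day)
            break
    return record


def simulate_cohort(
    design: StudyDesign | None = None,
    hyper: PopulationHyper | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[MouseRecord], pd.DataFrame]:
    """Simulate a full cohort; returns per-animal records and the long table.

    Deterministic given the seed: the same seed yields byte-identical CSVs.
    """
    design = design or default_design()
    hyper = hyper or default_hyper()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records: list[MouseRecord] = []
    seen: set[str] = set()
    for group in design.groups:
        for j in range(group.n_animals):
            animal_id = f"{group.full_label}-{j + 1:02d}"
            if animal_id in seen:
                raise ValueError(f"duplicate animal id {animal_id}")
            seen.add(animal_id)
            records.append(simulate_mouse(animal_id, group, design, hyper, rng))
    return records, cohort_to_frame(records)


def cohort_to_frame(records: list[MouseRecord]) -> pd.DataFrame:
    """Long-format observation table (one row per animal-day)."""
    rows = []
    for rec in records:
        for day, a_mm, b_mm, vol in rec.observations:
            rows.append(
                {
                    "animal_id": rec.animal_id,
                    "group": rec.group,
                    "gender": rec.gender,
                    "geometry": rec.geometry,
                    "current_ma": rec.current_ma,
                    "exposure_min": rec.exposure_min,
                    "day": day,
                    "a_mm": a_mm,
                    "b_mm": b_mm,
                    "volume_cm3": vol,
                    "fate": rec.fate,
                }
            )
    columns = [
        "animal_id", "group", "gender", "geometry", "current_ma",
        "exposure_min", "day", "a_mm", "b_mm", "volume_cm3", "fate",
    ]
    return pd.DataFrame(rows, columns=columns)


def design_to_frame(design: StudyDesign) -> pd.DataFrame:
    """Group design table (one row per group x gender arm)."""
    return pd.DataFrame(
        [
            {
                "group": g.label,
                "gender": g.gender,
                "geometry": g.geometry,
                "current_ma": g.current_ma,
                "exposure_min": g.exposure_min,
                "n_animals": g.n_animals,
                "control": g.control,
            }
            for g in design.groups
        ]
    )
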