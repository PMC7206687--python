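"""Shape-preserving interpolation of sparse caliper series onto a daily grid.

Volume series are measured twice weekly; rate parameters are per day, so
curve comparisons and endpoint searches work on a 1-day grid.  "Hermite
interpolation" here is monotone piecewise-cubic Hermite (PCHIP,
Fritsch-Carlson derivative estimates): it passes through every observation,
never overshoots between monotone neighbours and therefore can never
produce negative volumes from positive data.  No extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = ["InterpolatedCurve", "hermite_interpolate", "group_mean_curve"]


@dataclass(frozen=True)
class InterpolatedCurve:
    """A volume curve on a strictly increasing (normally daily) grid."""

    grid: np.ndarray
    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)
        if grid.ndim != 1 or grid.size != values.size:
            raise ValueError("grid and values must be 1-D and equally long")
        if grid.size >= 2 and not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")

    def __len__(self) -> int:
        return int(self.grid.size)


def hermite_interpolate(days, volumes, grid=None, source: str = "") -> InterpolatedCurve:
    """Interpolate one animal's (day, volume) observations onto a daily grid.

    Parameters
    ----------
    days, volumes
        Observation days and volumes (cm^3); at least 3 points.
    grid
        Target grid; defaults to integer days spanning the observations.
        Requests outside the observation span raise (no extrapolation).
    """
    days = np.asarray(days, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    order = np.argsort(days)
    days, volumes = days[order], volumes[order]
    if days.size < 3:
        raise ValueError(f"need >= 3 observations to interpolate, got {days.size}")
    if np.any(np.diff(days) <= 0):
        raise ValueError("observation days must be distinct")
    if grid is None:
        grid = np.arange(int(np.ceil(days[0])), int(np.floor(days[-1])) + 1, dtype=float)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.min() < days[0] or grid.max() > days[-1]:
            raise ValueError(
                f"grid [{grid.min()}, {grid.max()}] extends beyond the observation "
                f"span [{days[0]}, {days[-1]}]; extrapolation is not supported"
            )
    values = PchipInterpolator(days, volumes)(grid)
    return InterpolatedCurve(grid=grid, values=values, source=source)


def group_mean_curve(
    curves: list[InterpolatedCurve], source: str = ""
) -> tuple[InterpolatedCurve, np.ndarray]:
    """Pointwise mean curve and per-day SEM = sd/sqrt(N) over a common grid.

    With a single curve the mean is that curve and the SEM is zero by
    convention (N = 1 leaves the standard deviation undefined).
    """
    if not curves:
        raise ValueError("need at least one curve")
    grid = curves[0].grid
    for c in curves[1:]:
        if c.grid.shape != grid.shape or not np.array_equal(c.grid, grid):
            raise ValueError("curves must share a common grid")
    stack = np.vstack([c.values for c in curves])
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    sem = np.zeros_like(mean) if n == 1 else stack.std(axis=0, ddof=1) / np.sqrt(n)
    return InterpolatedCurve(grid=grid, values=mean, source=source), sem
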