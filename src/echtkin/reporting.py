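"""Pipeline orchestration: simulate -> interpolate -> fit -> assess -> endpoints.

One seeded run writes a cohort CSV, the design table, per-animal fit and
assessment CSVs, group summary tables in the study's publication layout,
endpoint tables, a resolved-config snapshot and a run log.  Identical seeds
give identical report bundles.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assessment, endpoints, fitting
from .cohort import default_design, default_hyper, design_to_frame, simulate_cohort
from .interpolation import group_mean_curve, hermite_interpolate

__all__ = ["RunConfig", "run_pipeline", "format_group_table", "load_config"]

log = logging.getLogger("echtkin")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, with the seed mandatory."""

    seed: int
    outdir: str = "echtkin_run"
    n_per_gender: int = 10
    noise_cv: float = 0.05
    hazard_pre: float = 0.00902
    hazard_post: float = 0.00804
    volume_limit: float = 2.0
    min_points: int = 4
    cap_per_arm: int | None = 5
    press_mode: str = "printed"        # or "standard"
    ratio_mode: str = "ratio-of-means"  # or "mean-of-ratios"
    mpress_m: int = 3
    compute_press: bool = True
    thresholds: dict = field(default_factory=dict)  # response-class overrides

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("config must set a seed")
    return RunConfig(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns the in-memory report bundle and writes
    every table under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        bundle = _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()
    return bundle


def _run(config: RunConfig, outdir: Path) -> dict:
    log.info("resolved config: %s", config.resolved())
    with open(outdir / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config.resolved(), fh, sort_keys=False)

    rng = np.random.default_rng(config.seed)
    design = default_design(config.n_per_gender)
    hyper = default_hyper(
        noise_cv=config.noise_cv,
        hazard_pre=config.hazard_pre,
        hazard_post=config.hazard_post,
    )
    records, frame = simulate_cohort(design, hyper, rng)
    frame.to_csv(outdir / "cohort.csv", index=False)
    design_to_frame(design).to_csv(outdir / "design.csv", index=False)
    log.info("simulated %d animals, %d observations", len(records), len(frame))

    result = fitting.fit_pipeline(
        frame,
        volume_limit=config.volume_limit,
        min_points=config.min_points,
        cap_per_arm=config.cap_per_arm,
        rng=rng,
    )
    result.frame.to_csv(outdir / "fits_per_animal.csv", index=False)
    log.info(
        "fits: %d TGK1, %d TGK2, %d full-control; %d animals excluded",
        len(result.tgk1), len(result.tgk2), len(result.full), len(result.excluded),
    )

    assess_rows = []
    for stage in ("TGK1", "TGK2", "full"):
        for r in result.stage_results(stage):
            rep = assessment.assess_fit(r.volumes, r.predicted, k=r.k)
            row = {
                "animal_id": r.animal_id, "group": r.group, "gender": r.gender,
                "stage": stage, "n1": rep.n1, "sse": rep.sse, "se": rep.se,
                "r2": rep.r2, "ra2": rep.ra2, "rmse": rep.rmse, "dmax": rep.dmax,
            }
            if config.compute_press:
                row["press"] = fitting.press_for_result(r, mode=config.press_mode)
                if r.n_points > config.mpress_m:
                    row[f"mpress_m{config.mpress_m}"] = fitting.mpress_for_result(
                        r, m=config.mpress_m
                    )
            assess_rows.append(row)
    assess_frame = pd.DataFrame(assess_rows)
    assess_frame.to_csv(outdir / "assessment_per_animal.csv", index=False)

    summaries = {}
    for stage, template in (("TGK1", "tab45"), ("TGK2", "tab67")):
        results = result.stage_results(stage)
        if results:
            summary = fitting.group_parameter_summary(results, config.ratio_mode)
            summaries[stage] = summary
            summary.to_csv(outdir / f"group_summary_{stage.lower()}.csv", index=False)
            format_group_table(summary).to_csv(
                outdir / f"group_table_{stage.lower()}.csv", index=False
            )
        else:
            log.warning("no %s fits; group table skipped", stage)

    thresholds = endpoints.ResponseThresholds(**config.thresholds)
    log.info("response thresholds: %s", thresholds)
    per_animal, response_table, doubling_table = endpoints.endpoint_tables(
        frame, thresholds=thresholds
    )
    per_animal.to_csv(outdir / "endpoints_per_animal.csv", index=False)
    response_table.to_csv(outdir / "response_table.csv", index=False)
    doubling_table.to_csv(outdir / "doubling_table.csv", index=False)

    curve_rows = _group_curve_distances(frame)
    curve_frame = pd.DataFrame(curve_rows)
    curve_frame.to_csv(outdir / "curve_distances.csv", index=False)

    log.info("pipeline complete; outputs in %s", outdir)
    return {
        "records": records,
        "cohort": frame,
        "fits": result,
        "assessment": assess_frame,
        "summaries": summaries,
        "endpoints": (per_animal, response_table, doubling_table),
        "curve_distances": curve_frame,
    }


def _group_curve_distances(frame: pd.DataFrame) -> list[dict]:
    """Dmax/RMSE between each treated arm's mean curve and its control arm."""
    grid = np.arange(18.0, 50.0)
    mean_curves = {}
    for (group, gender), sub in frame.groupby(["group", "gender"]):
        curves = []
        for _, animal in sub.groupby("animal_id"):
            animal = animal.sort_values("day")
            days = animal["day"].to_numpy(float)
            if days.size < 3 or days[0] > grid[0] or days[-1] < grid[0]:
                continue
            sub_grid = grid[(grid >= days[0]) & (grid <= days[-1])]
            if sub_grid.size < 3:
                continue
            curve = hermite_interpolate(days, animal["volume_cm3"].to_numpy(float),
                                        grid=sub_grid)
            # pad to the full grid with NaN so arms average day-by-day
            values = np.full(grid.size, np.nan)
            idx = np.searchsorted(grid, curve.grid)
            values[idx] = curve.values
            curves.append(values)
        if curves:
            stack = np.vstack(curves)
            counts = np.isfinite(stack).sum(axis=0)
            sums = np.nansum(np.where(np.isfinite(stack), stack, 0.0), axis=0)
            mean_curves[(group, gender)] = np.where(
                counts > 0, sums / np.maximum(counts, 1), np.nan
            )
    rows = []
    for (group, gender), treated_curve in mean_curves.items():
        if group.startswith("CG"):
            continue
        control = endpoints._CONTROL_FOR.get(group, "CG2")
        ref = mean_curves.get((control, gender))
        if ref is None:
            continue
        ok = np.isfinite(treated_curve) & np.isfinite(ref)
        if not ok.any():
            continue
        dmax, rmse = assessment.curve_distance(ref[ok], treated_curve[ok])
        rows.append(
            {"group": group, "gender": gender, "control": control,
             "m_days": int(ok.sum()), "dmax": dmax, "rmse": rmse}
        )
    return rows


def format_group_table(summary: pd.DataFrame, precision: int = 3) -> pd.DataFrame:
    """Publication-style table: 'mean +/- SEM' strings, ratios to 3 dp.

    Round-trips exactly through CSV (strings in, strings out); single-animal
    arms show a blank SEM flag.
    """
    out = {"group": summary["group"], "gender": summary["gender"], "n": summary["n"]}
    for col in summary.columns:
        if col.endswith("_mean"):
            base = col[: -len("_mean")]
            sem_col = f"{base}_sem"
            cells = []
            for _, row in summary.iterrows():
                mean = row[col]
                if not math.isfinite(mean):
                    cells.append("NA")
                    continue
                if row["n"] <= 1 or sem_col not in summary.columns:
                    cells.append(f"{mean:.{precision}f} ± -")
                else:
                    cells.append(f"{mean:.{precision}f} ± {row[sem_col]:.{precision}f}")
            out[base] = cells
    if "ratio" in summary.columns:
        out["i_over_i0"] = [f"{r:.3f}" for r in summary["ratio"]]
    return pd.DataFrame(out)
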