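"""Stage-oriented pipeline runner.

Stages form the chain simulate -> align -> piv -> fttc -> roi -> report;
each stage reads the previous stage's files from the output directory and
writes its own, so any contiguous run of stages can be (re)executed.  Every
output is regenerable from the configuration plus the seed; ``log.json``
records the config digest, seed and per-stage record counts.

The default simulated experiment is paired: for each replicate one movie
with a contracting patch ("syncytial" ROI) and one traction-free movie with
an identical ROI ("mononucleated" control), so the report stage can compare
the two groups exactly the way the microscopy analysis does.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io
from .config import PipelineConfig
from .fttc import traction_timeseries
from .piv import align_to_reference, iterative_piv, validate_and_fill
from .stress_roi import (
    RegionOfInterest,
    aggregate_window,
    compare_regions,
    decompose_timeseries,
    dilate_roi,
)
from .synthetic import BeadImageSpec, ContractionScenario, make_contraction_movie

logger = logging.getLogger("trophomech")

STAGE_ORDER = ("simulate", "align", "piv", "fttc", "roi", "report")

__all__ = ["STAGE_ORDER", "run_pipeline", "run_patch_control_experiment"]


def run_patch_control_experiment(
    n_pairs: int = 7,
    seed: int = 0,
    times: np.ndarray | None = None,
    cfg: PipelineConfig | None = None,
):
    """In-memory replicate experiment: contracting-patch movies vs.
    traction-free control movies, each scored by its aggregated 12-48 h mean
    radial stress, compared by an independent t-test.

    This is the synthetic counterpart of the syncytial-vs-mononucleated
    region comparison: n_pairs ROIs per group, identical geometry, the only
    difference being whether a contractile patch develops.  Returns the
    RegionComparison plus the per-ROI aggregates.
    """
    from .fttc import invert_traction
    from .piv import iterative_piv, validate_and_fill
    from .stress_roi import decompose_timeseries

    cfg = cfg or PipelineConfig()
    sc = cfg.scenario
    if times is None:
        times = np.arange(0.0, 48.1, 2.0)
    sr: dict[str, list[float]] = {"patch": [], "control": []}
    st: dict[str, list[float]] = {"patch": [], "control": []}
    for i in range(n_pairs):
        for cond in ("patch", "control"):
            mseed = seed * 1000 + 2 * i + (0 if cond == "patch" else 1)
            scenario = ContractionScenario(
                patch_center=sc.patch_center_um,
                patch_radius=sc.patch_radius_um,
                peak_traction=sc.peak_traction_pa if cond == "patch" else 0.0,
                onset_time=sc.onset_time_h,
                field_extent=sc.field_extent_px,
                seed=mseed,
            )
            spec = BeadImageSpec(
                bead_density=sc.bead_density_per_um2,
                noise_sd=sc.noise_sd,
                image_size=sc.field_extent_px,
                pixel_size=cfg.substrate.pixel_size,
                seed=mseed,
            )
            movie = make_contraction_movie(
                scenario, cfg.substrate, times, spec, cfg.piv
            )
            fields = []
            for k, t in enumerate(times):
                f = validate_and_fill(
                    iterative_piv(movie.frames[0], movie.frames[k], cfg.piv), cfg.piv
                )
                f.time = float(t)
                fields.append(f)
            tractions = [invert_traction(f, cfg.substrate, cfg.fttc) for f in fields]
            roi = _pipeline_roi(
                cfg,
                {
                    "patch_center_um": sc.patch_center_um,
                    "patch_radius_um": sc.patch_radius_um,
                    "field_extent_px": sc.field_extent_px,
                },
                cond if cond == "patch" else "control",
            )
            series = decompose_timeseries(tractions, roi)
            a_sr, a_st = aggregate_window(
                series, cfg.roi.window_start_h, cfg.roi.window_end_h
            )
            sr[cond].append(a_sr)
            st[cond].append(a_st)
    comparison = compare_regions(sr["patch"], sr["control"])
    return {
        "radial": comparison,
        "tangential": compare_regions(st["patch"], st["control"]),
        "mean_radial_pa": sr,
        "mean_abs_tangential_pa": st,
    }


def _movie_ids(cfg: PipelineConfig) -> list[tuple[str, int]]:
    return [
        (cond, i)
        for i in range(cfg.scenario.n_replicates)
        for cond in ("patch", "control")
    ]


def _movie_times(cfg: PipelineConfig) -> np.ndarray:
    sc = cfg.scenario
    return np.arange(0.0, sc.duration_h + 1e-9, sc.time_step_h)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs missing upstream artifact: {path}"
        )
    return path


def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> int:
    sc = cfg.scenario
    times = _movie_times(cfg)
    n = 0
    for cond, i in _movie_ids(cfg):
        seed = cfg.seed * 1000 + 2 * i + (0 if cond == "patch" else 1)
        scenario = ContractionScenario(
            patch_center=sc.patch_center_um,
            patch_radius=sc.patch_radius_um,
            peak_traction=sc.peak_traction_pa if cond == "patch" else 0.0,
            onset_time=sc.onset_time_h,
            field_extent=sc.field_extent_px,
            seed=seed,
        )
        spec = BeadImageSpec(
            bead_density=sc.bead_density_per_um2,
            noise_sd=sc.noise_sd,
            image_size=sc.field_extent_px,
            pixel_size=cfg.substrate.pixel_size,
            seed=seed,
        )
        movie = make_contraction_movie(scenario, cfg.substrate, times, spec, cfg.piv)
        io.write_image_stack(outdir / f"beads_{cond}_{i}.tif", movie.frames)
        io.write_traction_csv(
            outdir / f"truth_traction_{cond}_{i}.csv", movie.truth_tractions
        )
        n += movie.frames.shape[0]
    io.write_json(
        outdir / "scenario.json",
        {
            "times_h": list(map(float, times)),
            "movies": [f"{c}_{i}" for c, i in _movie_ids(cfg)],
            "patch_center_um": list(sc.patch_center_um),
            "patch_radius_um": sc.patch_radius_um,
            "field_extent_px": list(sc.field_extent_px),
        },
    )
    return n


def _stage_align(cfg: PipelineConfig, outdir: Path) -> int:
    n = 0
    for cond, i in _movie_ids(cfg):
        stack = io.read_image_stack(
            _require(outdir / f"beads_{cond}_{i}.tif", "align")
        )
        aligned, shifts = align_to_reference(stack.astype(float), 0)
        io.write_image_stack(outdir / f"aligned_{cond}_{i}.tif", aligned)
        np.savetxt(
            outdir / f"shifts_{cond}_{i}.csv",
            shifts,
            delimiter=",",
            header="dy_px,dx_px",
            comments="",
        )
        n += shifts.shape[0]
    return n


def _stage_piv(cfg: PipelineConfig, outdir: Path) -> int:
    meta = io.read_json(_require(outdir / "scenario.json", "piv"))
    times = meta["times_h"]
    n = 0
    for cond, i in _movie_ids(cfg):
        aligned = outdir / f"aligned_{cond}_{i}.tif"
        src = aligned if aligned.exists() else outdir / f"beads_{cond}_{i}.tif"
        stack = io.read_image_stack(_require(src, "piv")).astype(float)
        fields = []
        for t_idx, t in enumerate(times):
            f = iterative_piv(stack[0], stack[t_idx], cfg.piv)
            f = validate_and_fill(f, cfg.piv)
            f.time = float(t)
            fields.append(f)
            n += 1
        io.write_displacement_csv(outdir / f"displacement_{cond}_{i}.csv", fields)
    return n


def _stage_fttc(cfg: PipelineConfig, outdir: Path) -> int:
    n = 0
    for cond, i in _movie_ids(cfg):
        fields = io.read_displacement_csv(
            _require(outdir / f"displacement_{cond}_{i}.csv", "fttc"),
            cfg.substrate.pixel_size,
        )
        tractions = traction_timeseries(fields, cfg.substrate, cfg.fttc)
        io.write_traction_csv(outdir / f"traction_{cond}_{i}.csv", tractions)
        n += len(tractions)
    return n


def _pipeline_roi(cfg: PipelineConfig, meta: dict, cond: str) -> RegionOfInterest:
    px = cfg.substrate.pixel_size
    cx, cy = (c / px for c in meta["patch_center_um"])
    label = "syncytial" if cond == "patch" else "mononucleated"
    roi = RegionOfInterest.from_disk(
        shape=tuple(meta["field_extent_px"]),
        center=(cx, cy),
        radius_px=meta["patch_radius_um"] / px,
        label=label,
        fused_fraction=0.77 if cond == "patch" else 0.27,
    )
    return dilate_roi(roi, cfg.roi.dilation_px)


def _stage_roi(cfg: PipelineConfig, outdir: Path) -> int:
    import pandas as pd

    meta = io.read_json(_require(outdir / "scenario.json", "roi"))
    rows = []
    aggregates = []
    for cond, i in _movie_ids(cfg):
        tractions = io.read_traction_csv(
            _require(outdir / f"traction_{cond}_{i}.csv", "roi"),
            cfg.substrate.pixel_size,
        )
        roi = _pipeline_roi(cfg, meta, cond)
        roi.roi_id = f"{cond}_{i}"
        series = decompose_timeseries(tractions, roi)
        rows.append(series.to_dataframe())
        sr, st = aggregate_window(
            series, cfg.roi.window_start_h, min(cfg.roi.window_end_h, max(meta["times_h"]))
        )
        aggregates.append(
            {
                "roi_id": roi.roi_id,
                "label": roi.label,
                "mean_radial_pa": sr,
                "mean_abs_tangential_pa": st,
            }
        )
    df = pd.concat(rows, ignore_index=True)
    df.to_csv(outdir / "roi_timeseries.csv", index=False)
    pd.DataFrame(aggregates).to_csv(outdir / "roi_aggregate.csv", index=False)
    return len(df)


def _stage_report(cfg: PipelineConfig, outdir: Path) -> int:
    import pandas as pd

    agg = pd.read_csv(_require(outdir / "roi_aggregate.csv", "report"))
    syn = agg[agg.label == "syncytial"]
    mono = agg[agg.label == "mononucleated"]
    out = {}
    for col in ("mean_radial_pa", "mean_abs_tangential_pa"):
        cmp = compare_regions(syn[col].to_numpy(), mono[col].to_numpy())
        out[col] = {
            "t_statistic": cmp.t_statistic,
            "p_value": cmp.p_value,
            "mean_syncytial": cmp.mean_syncytial,
            "mean_mononucleated": cmp.mean_mononucleated,
            "n_syncytial": cmp.n_syncytial,
            "n_mononucleated": cmp.n_mononucleated,
        }
    io.write_json(outdir / "comparison.json", out)
    return len(out)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "align": _stage_align,
    "piv": _stage_piv,
    "fttc": _stage_fttc,
    "roi": _stage_roi,
    "report": _stage_report,
}


def run_pipeline(
    cfg: PipelineConfig, stages: Sequence[str], outdir: str | Path
) -> dict:
    """Run a contiguous chain of pipeline stages and write a run log.

    ``stages`` must appear in pipeline order with no gaps (the optional
    ``align`` stage may be skipped); each stage validates that its upstream
    artifacts exist in ``outdir``.
    """
    stages = list(stages)
    if not stages:
        raise ValueError("no stages requested")
    order = [s for s in STAGE_ORDER if s in stages]
    if order != stages:
        raise ValueError(f"stages must follow the order {STAGE_ORDER}, got {stages}")
    core = [s for s in stages if s != "align"]
    core_order = [s for s in STAGE_ORDER if s != "align"]
    idx = [core_order.index(s) for s in core]
    if idx and idx != list(range(idx[0], idx[0] + len(idx))):
        raise ValueError(f"stages must be contiguous in {core_order}, got {stages}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = {}
    for stage in stages:
        logger.info("running stage %s", stage)
        counts[stage] = _STAGE_FN[stage](cfg, outdir)
        logger.info("stage %s wrote %d records", stage, counts[stage])
    log = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "stages": stages,
        "record_counts": counts,
        "numpy_version": np.__version__,
    }
    io.write_json(outdir / "log.json", log)
    return log
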