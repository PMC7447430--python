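"""Readers, writers, and config-driven pipeline runs.

All tabular artifacts are UTF-8 comma-separated CSV with a mandatory header
and '.' decimals.  Image stacks are multi-page TIFFs (pages interleaved
frame-major, channel order per the JSON metadata sidecar).  Every pipeline
run writes its fully-resolved configuration and a machine-readable report
(package version, config hash, input hashes, headline outputs) next to its
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .bead_quant import aggregate_beads, quantify_bead
from .cc_trace import TracedPath, path_statistics, summarize_paths
from .guv_quant import (
    GuvQuantConfig,
    RecruitmentTrajectory,
    TimelapseStack,
    TrajectoryAggregate,
    build_trajectories,
)
from .hdx_diff import (
    UPTAKE_COLUMNS,
    UNEXCHANGED_LABEL,
    class_regions,
    classify_peptides,
    condition_stats,
    differential_exchange,
    percent_deuteration_table,
)
from .synthetic_data import (
    FilamentSimSpec,
    GuvSimSpec,
    HdxSimSpec,
    simulate_bead_image,
    simulate_filament,
    simulate_guv_timelapse,
    simulate_hdx_experiment,
)

logger = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = ["vesicle_id", "frame", "time_min", "value", "n_pixels"]
AGGREGATE_COLUMNS = ["time_min", "mean", "sd", "n"]
PATH_COLUMNS = ["path_id", "point_index", "row_px", "col_px"]

__all__ = [
    "write_timelapse",
    "read_timelapse",
    "write_trajectories",
    "write_aggregate",
    "write_uptake_table",
    "read_uptake_table",
    "write_paths",
    "read_paths",
    "RunConfig",
    "run_pipeline",
]


# --------------------------------------------------------------------------
# TIFF time-lapse
# --------------------------------------------------------------------------

def write_timelapse(stack: TimelapseStack, tiff_path, metadata_path) -> None:
    """Write a stack as a frame-major interleaved multi-page TIFF + sidecar."""
    pages = np.stack(
        [ch for t in range(stack.n_frames) for ch in (stack.membrane[t], stack.protein[t])]
    )
    tifffile.imwrite(tiff_path, pages.astype(np.float32), photometric="minisblack")
    meta = {
        "channel_order": ["membrane", "protein"],
        "pixel_size_um": stack.pixel_size_um,
        "frame_times_min": [float(t) for t in stack.frame_times_min],
    }
    Path(metadata_path).write_text(json.dumps(meta, indent=2))


def read_timelapse(tiff_path, metadata_path) -> TimelapseStack:
    """Read a two-channel stack written by :func:`write_timelapse`."""
    meta = json.loads(Path(metadata_path).read_text())
    for field in ("channel_order", "pixel_size_um", "frame_times_min"):
        if field not in meta:
            raise ValueError(f"metadata missing required field {field!r}")
    channel_order = meta["channel_order"]
    n_channels = len(channel_order)
    pages = tifffile.imread(tiff_path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] % n_channels != 0:
        raise ValueError(
            f"page count {pages.shape[0]} not divisible by channel count {n_channels}"
        )
    n_frames = pages.shape[0] // n_channels
    by_channel = {
        name: pages[i::n_channels].astype(float)
        for i, name in enumerate(channel_order)
    }
    times = np.asarray(meta["frame_times_min"], dtype=float)
    if times.shape[0] != n_frames:
        raise ValueError(
            f"metadata lists {times.shape[0]} frame times for {n_frames} frames"
        )
    return TimelapseStack(
        by_channel["membrane"], by_channel["protein"], meta["pixel_size_um"], times
    )


# --------------------------------------------------------------------------
# CSV tables
# --------------------------------------------------------------------------

def write_trajectories(trajectories: list[RecruitmentTrajectory], path) -> None:
    rows = []
    for tr in trajectories:
        for frame, (t, v, n) in enumerate(zip(tr.times_min, tr.values, tr.n_pixels)):
            rows.append(
                {
                    "vesicle_id": tr.vesicle_id,
                    "frame": frame,
                    "time_min": t,
                    "value": v,
                    "n_pixels": n,
                }
            )
    pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).to_csv(path, index=False)


def write_aggregate(agg: TrajectoryAggregate, path) -> None:
    pd.DataFrame(
        {
            "time_min": agg.times_min,
            "mean": agg.mean,
            "sd": agg.sd,
            "n": agg.n_vesicles,
        }
    ).to_csv(path, index=False)


def write_uptake_table(records: pd.DataFrame, path) -> None:
    records[UPTAKE_COLUMNS].to_csv(path, index=False)


def read_uptake_table(
    path, *, maxlabel_timepoint_s: float = 60000.0
) -> pd.DataFrame:
    """Read and validate a long-format uptake CSV.

    Checks the schema, basic row invariants, uniqueness of
    (condition, timepoint, replicate) keys per peptide, and the presence of
    the unexchanged and maximally-labeled control rows for every peptide;
    offending peptides are listed in the error.
    """
    df = pd.read_csv(path)
    missing = [c for c in UPTAKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"uptake table missing columns: {missing}")
    if (df["start"] > df["end"]).any():
        raise ValueError("peptide spans must satisfy start <= end")
    if (df["centroid_mass_da"] <= 0).any():
        raise ValueError("centroid masses must be positive")
    dup = df.duplicated(
        subset=["protein", "start", "end", "condition", "timepoint_s", "replicate"]
    )
    if dup.any():
        raise ValueError("duplicate (peptide, condition, timepoint, replicate) rows")
    peptides = df[["protein", "start", "end"]].drop_duplicates()
    key = pd.MultiIndex.from_frame(peptides)
    has_un = pd.MultiIndex.from_frame(
        df.loc[df["condition"] == UNEXCHANGED_LABEL, ["protein", "start", "end"]]
        .drop_duplicates()
    )
    has_max = pd.MultiIndex.from_frame(
        df.loc[
            (df["condition"] != UNEXCHANGED_LABEL)
            & (df["timepoint_s"] == maxlabel_timepoint_s),
            ["protein", "start", "end"],
        ].drop_duplicates()
    )
    missing_un = key.difference(has_un)
    missing_max = key.difference(has_max)
    problems = []
    if len(missing_un):
        problems.append(f"missing unexchanged control rows: {sorted(missing_un.tolist())}")
    if len(missing_max):
        problems.append(
            f"missing maximally-labeled control rows ({maxlabel_timepoint_s} s): "
            f"{sorted(missing_max.tolist())}"
        )
    if problems:
        raise ValueError("; ".join(problems))
    return df


def write_paths(paths: list[TracedPath], path) -> None:
    rows = []
    for p in paths:
        for i, (r, c) in enumerate(p.coordinates):
            rows.append(
                {"path_id": p.path_id, "point_index": i, "row_px": r, "col_px": c}
            )
    pd.DataFrame(rows, columns=PATH_COLUMNS).to_csv(path, index=False)


def read_paths(path, pixel_size_nm: float) -> list[TracedPath]:
    df = pd.read_csv(path)
    missing = [c for c in PATH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"paths table missing columns: {missing}")
    out = []
    for pid, group in df.groupby("path_id", sort=False):
        group = group.sort_values("point_index")
        coords = group[["row_px", "col_px"]].to_numpy(dtype=float)
        out.append(TracedPath(str(pid), coords, pixel_size_nm))
    return out


# --------------------------------------------------------------------------
# Config-driven runs
# --------------------------------------------------------------------------

class RunConfig(BaseModel):
    """One reproducible pipeline run: stage, parameters, seed, output dir."""

    model_config = ConfigDict(extra="forbid")

    stage: Literal[
        "simulate-guv",
        "simulate-bead",
        "simulate-hdx",
        "simulate-filament",
        "quantify-guv",
        "hdx-diff",
        "trace-stats",
        "guv-pipeline",
        "hdx-pipeline",
    ]
    params: dict[str, Any] = Field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"


def _sha256_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _stage_simulate_guv(config: RunConfig, out: Path) -> dict[str, Any]:
    spec = GuvSimSpec(**{**config.params, "seed": config.seed})
    result = simulate_guv_timelapse(spec)
    write_timelapse(result.stack, out / "stack.tif", out / "stack_meta.json")
    result.truth.to_csv(out / "ground_truth.csv", index=False)
    tifffile.imwrite(out / "ring_labels.tif", result.ring_labels)
    return {"n_vesicles": len(spec.vesicles), "n_frames": result.stack.n_frames}


def _stage_quantify_guv(config: RunConfig, out: Path) -> dict[str, Any]:
    params = dict(config.params)
    tiff = params.pop("tiff")
    meta = params.pop("metadata")
    quant = GuvQuantConfig(**params.pop("config", {}))
    if params:
        raise ValueError(f"unknown quantify-guv parameters: {sorted(params)}")
    stack = read_timelapse(tiff, meta)
    trajectories, agg = build_trajectories(stack, quant)
    write_trajectories(trajectories, out / "trajectories.csv")
    write_aggregate(agg, out / "aggregate.csv")
    final = float(agg.mean[-1]) if len(trajectories) else float("nan")
    return {
        "inputs": {"tiff": _sha256_file(tiff), "metadata": _sha256_file(meta)},
        "n_trajectories": len(trajectories),
        "final_mean": final,
    }


def _stage_simulate_hdx(config: RunConfig, out: Path) -> dict[str, Any]:
    spec = HdxSimSpec(**{**config.params, "seed": config.seed})
    result = simulate_hdx_experiment(spec)
    write_uptake_table(result.records, out / "uptake.csv")
    result.truth.to_csv(out / "ground_truth.csv", index=False)
    return {"n_peptides": len(spec.peptides), "conditions": sorted(spec.site_rates)}


def _stage_hdx_diff(config: RunConfig, out: Path) -> dict[str, Any]:
    params = dict(config.params)
    uptake = params.pop("uptake")
    condition = params.pop("condition")
    reference = params.pop("reference")
    timepoint = float(params.pop("timepoint_s", 60.0))
    threshold = float(params.pop("threshold", 10.0))
    maxlabel = float(params.pop("maxlabel_timepoint_s", 60000.0))
    if params:
        raise ValueError(f"unknown hdx-diff parameters: {sorted(params)}")
    records = read_uptake_table(uptake, maxlabel_timepoint_s=maxlabel)
    pct = percent_deuteration_table(records, maxlabel_timepoint_s=maxlabel)
    stats = condition_stats(pct)
    diff = differential_exchange(stats, condition, reference)
    classified = classify_peptides(diff, threshold=threshold, timepoint_s=timepoint)
    classified.to_csv(out / "differences.csv", index=False)
    region_rows = []
    for protein in classified["protein"].unique():
        for cls in ("protected", "deprotected"):
            for start, end in class_regions(classified, protein, cls):
                region_rows.append(
                    {"protein": protein, "classification": cls, "start": start, "end": end}
                )
    pd.DataFrame(
        region_rows, columns=["protein", "classification", "start", "end"]
    ).to_csv(out / "regions.csv", index=False)
    counts = classified["classification"].value_counts().to_dict()
    return {"inputs": {"uptake": _sha256_file(uptake)}, "classification_counts": counts}


def _stage_simulate_bead(config: RunConfig, out: Path) -> dict[str, Any]:
    from .synthetic_data import disc_outlines

    params = dict(config.params)
    centers = [tuple(c) for c in params.pop("centers")]
    radius = float(params.pop("radius_px"))
    shape = tuple(params.pop("image_shape"))
    inside = float(params.pop("inside_value"))
    outside = float(params.pop("outside_value"))
    noise = float(params.pop("noise_sigma", 0.0))
    if params:
        raise ValueError(f"unknown simulate-bead parameters: {sorted(params)}")
    outlines = disc_outlines(centers, radius, shape)
    sim = simulate_bead_image(
        inside, outside, outlines, shape, noise_sigma=noise, seed=config.seed
    )
    tifffile.imwrite(out / "beads.tif", sim.image.astype(np.float32))
    labels = np.zeros(shape, dtype=np.int32)
    for o in outlines:
        labels[o.mask] = o.bead_id
    tifffile.imwrite(out / "bead_labels.tif", labels)
    measurements = [
        quantify_bead(sim.image, o, other_beads=(labels > 0) & ~o.mask)
        for o in outlines
    ]
    pd.DataFrame(
        [
            {"bead_id": m.bead_id, "value": m.value, "degenerate": m.degenerate}
            for m in measurements
        ]
    ).to_csv(out / "beads.csv", index=False)
    mean, sd = aggregate_beads([m.value for m in measurements])
    pd.DataFrame([{"mean": mean, "sd": sd, "n": len(measurements)}]).to_csv(
        out / "beads_aggregate.csv", index=False
    )
    return {"n_beads": len(outlines), "mean": mean, "sd": sd}


def _stage_simulate_filament(config: RunConfig, out: Path) -> dict[str, Any]:
    spec = FilamentSimSpec(**{**config.params, "seed": config.seed})
    result = simulate_filament(spec)
    tifffile.imwrite(out / "filament.tif", result.image.astype(np.float32))
    write_paths(
        [TracedPath("truth", result.centerline_px, spec.pixel_size_nm)],
        out / "true_centerline.csv",
    )
    json.dump(
        {
            "arc_length_nm": result.arc_length_nm,
            "end_to_end_nm": result.end_to_end_nm,
        },
        (out / "ground_truth.json").open("w"),
        indent=2,
    )
    return {"arc_length_nm": result.arc_length_nm}


def _stage_trace_stats(config: RunConfig, out: Path) -> dict[str, Any]:
    params = dict(config.params)
    paths_csv = params.pop("paths")
    pixel_size = float(params.pop("pixel_size_nm"))
    bin_width = float(params.pop("bin_width_nm", 10.0))
    if params:
        raise ValueError(f"unknown trace-stats parameters: {sorted(params)}")
    paths = read_paths(paths_csv, pixel_size)
    summaries = [path_statistics(p) for p in paths]
    pd.DataFrame(
        [
            {
                "path_id": s.path_id,
                "contour_length_nm": s.contour_length_nm,
                "end_to_end_nm": s.end_to_end_nm,
            }
            for s in summaries
        ]
    ).to_csv(out / "path_summaries.csv", index=False)
    ens = summarize_paths(summaries, bin_width_nm=bin_width)
    pd.DataFrame(
        {
            "bin_left_nm": ens.bin_edges_nm[:-1],
            "bin_right_nm": ens.bin_edges_nm[1:],
            "contour_count": ens.contour_hist_counts,
            "end_to_end_count": ens.end_to_end_hist_counts,
        }
    ).to_csv(out / "histograms.csv", index=False)
    return {
        "inputs": {"paths": _sha256_file(paths_csv)},
        "n_paths": ens.n_paths,
        "contour_mean_nm": ens.contour_mean_nm,
        "end_to_end_mean_nm": ens.end_to_end_mean_nm,
    }


def _stage_guv_pipeline(config: RunConfig, out: Path) -> dict[str, Any]:
    params = dict(config.params)
    quant = params.pop("quant", {})
    sim_report = _stage_simulate_guv(
        RunConfig(stage="simulate-guv", params=params, seed=config.seed, out_dir=str(out)),
        out,
    )
    quant_report = _stage_quantify_guv(
        RunConfig(
            stage="quantify-guv",
            params={
                "tiff": str(out / "stack.tif"),
                "metadata": str(out / "stack_meta.json"),
                "config": quant,
            },
            seed=config.seed,
            out_dir=str(out),
        ),
        out,
    )
    return {**sim_report, **quant_report}


def _stage_hdx_pipeline(config: RunConfig, out: Path) -> dict[str, Any]:
    params = dict(config.params)
    condition = params.pop("condition")
    reference = params.pop("reference")
    timepoint = params.pop("timepoint_s", 60.0)
    threshold = params.pop("threshold", 10.0)
    sim_report = _stage_simulate_hdx(
        RunConfig(stage="simulate-hdx", params=params, seed=config.seed, out_dir=str(out)),
        out,
    )
    diff_report = _stage_hdx_diff(
        RunConfig(
            stage="hdx-diff",
            params={
                "uptake": str(out / "uptake.csv"),
                "condition": condition,
                "reference": reference,
                "timepoint_s": timepoint,
                "threshold": threshold,
                "maxlabel_timepoint_s": params.get("maxlabel_timepoint_s", 60000.0),
            },
            seed=config.seed,
            out_dir=str(out),
        ),
        out,
    )
    return {**sim_report, **diff_report}


_STAGES = {
    "simulate-guv": _stage_simulate_guv,
    "simulate-bead": _stage_simulate_bead,
    "simulate-hdx": _stage_simulate_hdx,
    "simulate-filament": _stage_simulate_filament,
    "quantify-guv": _stage_quantify_guv,
    "hdx-diff": _stage_hdx_diff,
    "trace-stats": _stage_trace_stats,
    "guv-pipeline": _stage_guv_pipeline,
    "hdx-pipeline": _stage_hdx_pipeline,
}


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute one configured stage; write artifacts, resolved config, report."""
    logging.basicConfig(level=config.log_level.upper())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.json").write_text(
        json.dumps(config.model_dump(), indent=2, default=str)
    )
    headline = _STAGES[config.stage](config, out)
    report = {
        "recruitkit_version": __version__,
        "stage": config.stage,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "outputs": headline,
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
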