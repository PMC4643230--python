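"""End-to-end orchestration: segmentation -> traces -> events -> population.

Each stage writes a self-describing CSV so later stages can be re-run
from saved outputs; a run manifest records the resolved configuration,
the files produced and the per-filter counts. Given the same input and
configuration the CSV outputs are byte-identical between runs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import caflux
from caflux.movie_io import MovieStack, RunConfig, log_stage, write_stack
from caflux.segmentation import CellRecord, segment_movie
from caflux.synthetic import SceneConfig, GroundTruth, generate_movie, write_ground_truth
from caflux.traces import RawTrace, extract_trace, smooth_trace, normalize_trace
from caflux.events import EventAnnotation, annotate_cell, align_trace
from caflux.population import summarize, resolution_scan, event_figures, max_projection_figure

__all__ = ["RunManifest", "run_full", "run_synthetic", "run_traces_only", "analyze_stack"]


@dataclass
class RunManifest:
    """What a run consumed and produced."""

    inputs: dict
    config: dict
    outputs: list[str] = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


@dataclass
class AnalysisResult:
    """All intermediate products of a full analysis."""

    records: list[CellRecord]
    raw_traces: list[RawTrace]
    smoothed_traces: list[RawTrace]
    normalized_traces: list
    aligned_traces: list
    annotations: list[EventAnnotation]
    landings: dict[int, float]


def analyze_stack(stack: MovieStack, config: RunConfig | None = None) -> AnalysisResult:
    """Library-level full analysis of a movie.

    Runs segmentation, landing detection and filtering, then trace
    extraction, smoothing, normalization and event classification for
    every included cell.
    """
    config = config or RunConfig()
    records = segment_movie(stack, config)
    raws: list[RawTrace] = []
    smoothed: list[RawTrace] = []
    normalized = []
    aligned = []
    annotations: list[EventAnnotation] = []
    landings: dict[int, float] = {}
    for rec in records:
        if not rec.included:
            continue
        raw = extract_trace(stack, rec)
        if len(raw.intensities) < config.smoothing_window_frames:
            continue
        sm = smooth_trace(raw, config.smoothing_window_frames, config.smoothing_poly_order)
        t_land = stack.frame_time(rec.landing_frame)
        ntr = normalize_trace(sm, baseline_window=config.baseline_window_frames, t_landing=t_land)
        ann = annotate_cell(ntr, t_land, config)
        raws.append(raw)
        smoothed.append(sm)
        normalized.append(ntr)
        aligned.append(align_trace(ntr, t_land, config))
        annotations.append(ann)
        landings[rec.cell_id] = t_land
    log_stage("events", n_included=len(annotations),
              n_responders=sum(a.is_responder for a in annotations))
    return AnalysisResult(records, raws, smoothed, normalized, aligned, annotations, landings)


def _cells_frame(records: list[CellRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        ref_frame = rec.landing_frame if rec.landing_frame is not None else rec.last_seen_frame
        r, c = rec.trajectory.get(ref_frame, (np.nan, np.nan))
        rows.append(
            {
                "cell_id": rec.cell_id,
                "first_seen_frame": rec.first_seen_frame,
                "landing_frame": -1 if rec.landing_frame is None else rec.landing_frame,
                "centroid_row": round(float(r), 3),
                "centroid_col": round(float(c), 3),
                "diameter_px": round(rec.diameter_px, 3),
                "included": int(rec.included),
                "exclusion_reason": rec.exclusion_reason,
            }
        )
    return pd.DataFrame(rows)


def _events_frame(annotations: list[EventAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append(
            {
                "cell_id": a.cell_id,
                "t_landing_s": a.t_landing,
                "t_triggering_s": np.nan if a.t_triggering is None else a.t_triggering,
                "T_s": np.nan if (a.T is None or not a.is_responder) else a.T,
                "is_responder": int(a.is_responder),
                "peak_response": a.peak_response,
                "I0": a.I0,
                "Imax": a.Imax,
                "dI": a.dI,
            }
        )
    return pd.DataFrame(rows)


def _summary_payload(summary, config: RunConfig) -> dict:
    return {
        "n_total": summary.n_total,
        "n_responders": summary.n_responders,
        "fraction": summary.fraction,
        "fraction_sdm": summary.fraction_sdm,
        "T_mean_s": summary.T_mean,
        "T_sdm_s": summary.T_sdm,
        "config": dataclasses.asdict(config),
        "version": caflux.__version__,
    }


def _write_outputs(
    stack: MovieStack,
    config: RunConfig,
    result: AnalysisResult,
    out_dir: Path,
    manifest: RunManifest,
    resolution_intervals: list[float] | None,
    make_figures: bool,
) -> None:
    cells_csv = out_dir / "cells.csv"
    _cells_frame(result.records).to_csv(cells_csv, index=False)
    manifest.outputs.append(str(cells_csv))

    trace_rows = []
    for raw, sm, ntr in zip(result.raw_traces, result.smoothed_traces, result.normalized_traces):
        t_land = result.landings[sm.cell_id]
        k0 = int(round((raw.times[0] - stack.origin_time) / stack.frame_interval))
        for j, t in enumerate(sm.times):
            trace_rows.append(
                {
                    "cell_id": sm.cell_id,
                    "frame": k0 + j,
                    "time_s": t,
                    "intensity_raw": raw.intensities[j],
                    "intensity_smoothed": sm.intensities[j],
                    "R": ntr.R[j],
                    "n_pixels": raw.n_pixels[j],
                    "t_landing_s": t_land,
                }
            )
    traces_csv = out_dir / "traces.csv"
    pd.DataFrame(
        trace_rows,
        columns=["cell_id", "frame", "time_s", "intensity_raw", "intensity_smoothed",
                 "R", "n_pixels", "t_landing_s"],
    ).to_csv(traces_csv, index=False)
    manifest.outputs.append(str(traces_csv))

    events_csv = out_dir / "events.csv"
    _events_frame(result.annotations).to_csv(events_csv, index=False)
    manifest.outputs.append(str(events_csv))

    manifest.counts = {
        "n_tracks": len(result.records),
        "n_included": len(result.annotations),
        "n_responders": int(sum(a.is_responder for a in result.annotations)),
        "exclusions": {
            reason: int(sum(r.exclusion_reason == reason for r in result.records))
            for reason in ("no_landing", "overlap", "late_landing", "edge")
        },
    }

    summary_json = out_dir / "summary.json"
    if result.annotations:
        summary = summarize(result.annotations, result.aligned_traces)
        summary_json.write_text(json.dumps(_summary_payload(summary, config), indent=2))
        manifest.outputs.append(str(summary_json))
        if make_figures:
            manifest.outputs += [str(p) for p in event_figures(summary, result.annotations, out_dir)]
            proj_png = out_dir / "max_projection.png"
            max_projection_figure(stack, proj_png)
            manifest.outputs.append(str(proj_png))
        if resolution_intervals:
            scan = resolution_scan(result.smoothed_traces, result.landings,
                                   resolution_intervals, config)
            scan_csv = out_dir / "resolution_scan.csv"
            scan.to_csv(scan_csv, index=False)
            manifest.outputs.append(str(scan_csv))
    else:
        summary_json.write_text(
            json.dumps({"n_total": 0, "n_responders": 0, "fraction": None,
                        "config": dataclasses.asdict(config),
                        "version": caflux.__version__}, indent=2)
        )
        manifest.outputs.append(str(summary_json))
        log_stage("population", notice="zero included cells; figures skipped")


def run_full(
    stack: MovieStack,
    config: RunConfig | None = None,
    out_dir: str | Path = ".",
    resolution_intervals: list[float] | None = None,
    make_figures: bool = True,
) -> RunManifest:
    """Run the whole pipeline on a movie and write all outputs.

    Writes cells.csv, traces.csv, events.csv, summary.json,
    summary_curves.csv, figures and manifest.json under ``out_dir``.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        inputs={"n_frames": stack.n_frames, "shape": list(stack.shape),
                "frame_interval_s": stack.frame_interval},
        config=dataclasses.asdict(config),
        started=time.time(),
    )
    result = analyze_stack(stack, config)
    _write_outputs(stack, config, result, out_dir, manifest,
                   resolution_intervals, make_figures)
    manifest.finished = time.time()
    manifest.write(out_dir / "manifest.json")
    return manifest


def match_to_ground_truth(
    records: list[CellRecord],
    annotations: list[EventAnnotation],
    gt: GroundTruth,
    stack: MovieStack,
) -> pd.DataFrame:
    """Match detected cells to ground-truth cells by resting position.

    Greedy nearest-neighbour on the post-landing centroid within one
    cell radius; reports per-cell landing error (frames), trigger-onset
    error (s) and responder agreement.
    """
    ann_by_id = {a.cell_id: a for a in annotations}
    det = [(r, r.trajectory[r.last_seen_frame]) for r in records]
    rows = []
    used: set[int] = set()
    dt = stack.frame_interval
    for cell in gt.cells:
        true_pos = cell.trajectory[-1]
        best, best_d = None, np.inf
        for r, pos in det:
            if r.cell_id in used:
                continue
            d = float(np.hypot(*(pos - true_pos)))
            if d < best_d:
                best, best_d = r, d
        row = {
            "true_cell_id": cell.cell_id,
            "true_landing_frame": cell.true_landing_frame,
            "true_is_responder": cell.is_responder,
            "true_trigger_frame": -1 if cell.true_trigger_frame is None else cell.true_trigger_frame,
        }
        if best is not None and best_d <= max(3.0, cell.radius_px):
            used.add(best.cell_id)
            ann = ann_by_id.get(best.cell_id)
            row.update(
                {
                    "matched": True,
                    "detected_cell_id": best.cell_id,
                    "match_distance_px": round(best_d, 3),
                    "included": best.included,
                    "detected_landing_frame": -1 if best.landing_frame is None else best.landing_frame,
                    "landing_error_frames": (
                        np.nan if best.landing_frame is None
                        else best.landing_frame - cell.true_landing_frame
                    ),
                    "detected_is_responder": bool(ann.is_responder) if ann else False,
                    "trigger_error_s": (
                        ann.t_triggering - cell.true_trigger_frame * dt - stack.origin_time
                        if ann is not None and ann.t_triggering is not None
                        and cell.true_trigger_frame is not None
                        else np.nan
                    ),
                }
            )
        else:
            row.update({"matched": False, "detected_cell_id": -1,
                        "match_distance_px": np.nan, "included": False,
                        "detected_landing_frame": -1, "landing_error_frames": np.nan,
                        "detected_is_responder": False, "trigger_error_s": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)


def run_synthetic(
    scene_config: SceneConfig,
    out_dir: str | Path,
    config: RunConfig | None = None,
    write_movie: bool = False,
    resolution_intervals: list[float] | None = None,
    make_figures: bool = True,
) -> RunManifest:
    """Generate a synthetic movie, analyze it, and report parameter recovery.

    Writes the ground-truth CSV, all ``run_full`` outputs, a per-cell
    recovery table (recovery.csv) and a recovery summary
    (recovery.json). The rendered movie is written as TIFF only on
    request — it is reproducible from the scene config and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    stack, gt = generate_movie(scene_config)
    if len(gt):
        write_ground_truth(gt, out_dir / "ground_truth.csv")
    if write_movie:
        write_stack(stack, out_dir / "movie.tif")

    manifest = RunManifest(
        inputs={"scene_config": dataclasses.asdict(scene_config)},
        config=dataclasses.asdict(config),
        started=time.time(),
    )
    manifest.seeds["scene_seed"] = scene_config.seed
    result = analyze_stack(stack, config)
    _write_outputs(stack, config, result, out_dir, manifest,
                   resolution_intervals, make_figures)

    matched = match_to_ground_truth(result.records, result.annotations, gt, stack)
    matched.to_csv(out_dir / "recovery.csv", index=False)
    manifest.outputs.append(str(out_dir / "recovery.csv"))

    landed = matched[matched["matched"] & matched["included"]
                     & (matched["detected_landing_frame"] >= 0)]
    anns = result.annotations
    recovery = {
        "n_true_cells": len(gt),
        "n_matched": int(matched["matched"].sum()),
        "true_responder_fraction": gt.n_responders / len(gt) if len(gt) else float("nan"),
        "detected_responder_fraction": (
            sum(a.is_responder for a in anns) / len(anns) if anns else float("nan")
        ),
        "landing_within_1_frame": (
            float(np.mean(np.abs(landed["landing_error_frames"]) <= 1))
            if len(landed) else float("nan")
        ),
        "mean_abs_trigger_error_s": (
            float(matched["trigger_error_s"].abs().mean())
            if matched["trigger_error_s"].notna().any() else float("nan")
        ),
    }
    (out_dir / "recovery.json").write_text(json.dumps(recovery, indent=2))
    manifest.outputs.append(str(out_dir / "recovery.json"))
    manifest.finished = time.time()
    manifest.write(out_dir / "manifest.json")
    return manifest


def run_traces_only(
    traces_csv: str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path = ".",
) -> RunManifest:
    """Events + population stages from a saved traces table.

    The CSV must follow the traces.csv schema (cell_id, frame, time_s,
    intensity_raw, intensity_smoothed, R, n_pixels) plus a
    ``t_landing_s`` column supplying each cell's landing time.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(traces_csv)
    if df.empty:
        raise ValueError(f"{traces_csv}: no data rows")
    if "t_landing_s" not in df.columns:
        raise ValueError("traces table must carry a t_landing_s column")
    manifest = RunManifest(
        inputs={"traces_csv": str(traces_csv)},
        config=dataclasses.asdict(config),
        started=time.time(),
    )
    annotations = []
    aligned = []
    for cell_id, sub in df.groupby("cell_id"):
        sub = sub.sort_values("time_s")
        col = "intensity_smoothed" if "intensity_smoothed" in sub else "intensity_raw"
        tr = RawTrace(
            cell_id=int(cell_id),
            times=sub["time_s"].to_numpy(float),
            intensities=sub[col].to_numpy(float),
            n_pixels=sub["n_pixels"].to_numpy() if "n_pixels" in sub else np.ones(len(sub), int),
        )
        t_land = float(sub["t_landing_s"].iloc[0])
        ntr = normalize_trace(tr, baseline_window=config.baseline_window_frames, t_landing=t_land)
        annotations.append(annotate_cell(ntr, t_land, config))
        aligned.append(align_trace(ntr, t_land, config))
    events_csv = out_dir / "events.csv"
    _events_frame(annotations).to_csv(events_csv, index=False)
    manifest.outputs.append(str(events_csv))
    summary = summarize(annotations, aligned)
    summary_json = out_dir / "summary.json"
    summary_json.write_text(json.dumps(_summary_payload(summary, config), indent=2))
    manifest.outputs.append(str(summary_json))
    manifest.outputs += [str(p) for p in event_figures(summary, annotations, out_dir)]
    manifest.counts = {"n_included": summary.n_total, "n_responders": summary.n_responders}
    manifest.finished = time.time()
    manifest.write(out_dir / "manifest.json")
    return manifest
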