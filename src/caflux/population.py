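"""Population-level aggregation: responder fractions, mean response
curves, triggering-time statistics, robustness analyses and figures.

Error bars follow the s.d.m. convention (standard deviation of the
mean, SD/sqrt(n)); the responder fraction carries a binomial s.d.m.
sqrt(p(1-p)/n). The mean response curve is computed over responders on
the aligned time grid (t = 0 at 2 s after landing), using at each time
point only the cells observed there and dropping points covered by
fewer than two cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from caflux.movie_io import MovieStack, RunConfig, log_stage
from caflux.segmentation import CellRecord
from caflux.traces import RawTrace, NormalizedTrace, normalize_trace, resample_trace
from caflux.events import EventAnnotation, annotate_cell

__all__ = [
    "PopulationSummary",
    "summarize",
    "resolution_scan",
    "dye_loading_report",
    "pixel_subsample_report",
    "max_projection_figure",
    "event_figures",
]


@dataclass
class PopulationSummary:
    """Ensemble outputs over the included cells."""

    n_total: int
    n_responders: int
    fraction: float
    fraction_sdm: float
    mean_R_times: np.ndarray = field(default_factory=lambda: np.array([]))
    mean_R: np.ndarray = field(default_factory=lambda: np.array([]))
    mean_R_sdm: np.ndarray = field(default_factory=lambda: np.array([]))
    mean_R_n: np.ndarray = field(default_factory=lambda: np.array([]))
    T_values: np.ndarray = field(default_factory=lambda: np.array([]))
    T_mean: float = float("nan")
    T_sdm: float = float("nan")

    def curves_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "aligned_time_s": self.mean_R_times,
                "mean_R": self.mean_R,
                "sdm_R": self.mean_R_sdm,
                "n_cells": self.mean_R_n,
            }
        )


def summarize(
    annotations: list[EventAnnotation],
    aligned_traces: list[NormalizedTrace] | None = None,
    responders_only: bool = True,
    sdm: bool = True,
) -> PopulationSummary:
    """Aggregate per-cell annotations into population statistics.

    fraction = n_responders / n_total with binomial s.d.m.; the mean
    aligned response curve is pointwise over responders (or all cells
    with ``responders_only=False``), with per-point SD/sqrt(n) (plain SD
    with ``sdm=False``); T statistics are over responders.
    """
    if len(annotations) == 0:
        raise ValueError("no included cells to summarize")
    n_total = len(annotations)
    responders = [a for a in annotations if a.is_responder]
    n_resp = len(responders)
    p = n_resp / n_total
    summary = PopulationSummary(
        n_total=n_total,
        n_responders=n_resp,
        fraction=p,
        fraction_sdm=float(np.sqrt(p * (1.0 - p) / n_total)),
    )
    t_vals = np.array([a.T for a in responders], dtype=float)
    summary.T_values = t_vals
    if len(t_vals):
        summary.T_mean = float(np.mean(t_vals))
        sd = float(np.std(t_vals, ddof=1)) if len(t_vals) > 1 else 0.0
        summary.T_sdm = sd / np.sqrt(len(t_vals)) if sdm else sd

    if aligned_traces:
        resp_ids = {a.cell_id for a in responders}
        use = aligned_traces if not responders_only else [
            tr for tr in aligned_traces if tr.cell_id in resp_ids
        ]
        if use:
            dt = use[0].interval
            frames_r = []
            for tr in use:
                grid = np.rint(tr.times / dt).astype(int)
                frames_r.append(pd.DataFrame({"k": grid, "R": tr.R}))
            long = pd.concat(frames_r)
            grp = long.groupby("k")["R"]
            stats = grp.agg(["mean", "std", "count"])
            stats = stats[stats["count"] >= 2]
            denom = np.sqrt(stats["count"].to_numpy()) if sdm else 1.0
            summary.mean_R_times = stats.index.to_numpy() * dt
            summary.mean_R = stats["mean"].to_numpy()
            summary.mean_R_sdm = stats["std"].to_numpy() / denom
            summary.mean_R_n = stats["count"].to_numpy()
    return summary


def resolution_scan(
    smoothed_traces: list[RawTrace],
    landings: dict[int, float],
    intervals: list[float],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Detected responder fraction as a function of acquisition interval.

    Mimics slower acquisition by decimating each (already smoothed)
    included trace to every interval in ``intervals``, then re-running
    normalization, event detection and classification. The native
    interval reproduces the standard analysis exactly. Cells whose
    trace becomes too short at a coarse interval are dropped from that
    interval's denominator.
    """
    config = config or RunConfig()
    rows = []
    for interval in intervals:
        n_total = 0
        n_resp = 0
        for tr in smoothed_traces:
            t_land = landings[tr.cell_id]
            try:
                res = resample_trace(tr, interval)
                baseline = max(2, int(round(config.baseline_window_frames
                                             * tr.interval / res.interval)))
                ntr = normalize_trace(res, baseline_window=baseline, t_landing=t_land)
                ann = annotate_cell(ntr, t_land, config)
            except ValueError:
                continue
            n_total += 1
            n_resp += bool(ann.is_responder)
        frac = n_resp / n_total if n_total else float("nan")
        rows.append({"interval_s": interval, "fraction": frac, "n_cells": n_total})
    return pd.DataFrame(rows)


def dye_loading_report(annotations: list[EventAnnotation]) -> tuple[pd.DataFrame, dict]:
    """Per-cell dI/I0 (dye-loading / background robustness metric).

    Cells with a non-positive baseline are flagged and excluded from the
    ratio statistics.
    """
    rows = []
    for a in annotations:
        ok = a.I0 > 0
        rows.append(
            {
                "cell_id": a.cell_id,
                "I0": a.I0,
                "Imax": a.Imax,
                "dI": a.dI,
                "dI_over_I0": a.dI / a.I0 if ok else np.nan,
                "flagged": not ok,
            }
        )
    table = pd.DataFrame(rows)
    valid = table.loc[~table["flagged"], "dI_over_I0"]
    stats = {
        "n": int(valid.size),
        "mean": float(valid.mean()) if valid.size else float("nan"),
        "sd": float(valid.std(ddof=1)) if valid.size > 1 else float("nan"),
        "n_flagged": int(table["flagged"].sum()),
    }
    return table, stats


def pixel_subsample_report(
    stack: MovieStack,
    records: list[CellRecord],
    pixel_counts: list[int],
    seed: int = 0,
) -> pd.DataFrame:
    """RMS deviation of R(t) when only a random pixel subset is collected.

    For each included, landed cell the post-landing mask (at the landing
    frame) defines the full pixel set; for each requested count a seeded
    random subset is drawn, the mean-intensity trace over post-landing
    frames recomputed and renormalized, and the RMS deviation from the
    full-mask R(t) reported. Checks that the readout is insensitive to
    the number of camera pixels per cell (e.g. 2500 down to 20).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rec in records:
        if not rec.included or rec.landing_frame is None:
            continue
        rows_px, cols_px = rec.masks[rec.landing_frame]
        n_full = len(rows_px)
        span = [f for f in rec.frames if f >= rec.landing_frame]
        full_trace = np.array([np.mean(stack.frames[f][rows_px, cols_px]) for f in span])
        full_R = full_trace / full_trace.max()
        for count in pixel_counts:
            if count > n_full:
                raise ValueError(
                    f"cell {rec.cell_id}: requested {count} pixels but mask has {n_full}"
                )
            if count == n_full:
                sel = np.arange(n_full)
            else:
                sel = rng.choice(n_full, size=count, replace=False)
            sub = np.array([np.mean(stack.frames[f][rows_px[sel], cols_px[sel]]) for f in span])
            sub_R = sub / sub.max()
            rms = float(np.sqrt(np.mean((sub_R - full_R) ** 2)))
            rows.append({"cell_id": rec.cell_id, "n_pixels": count, "rms_deviation": rms})
    return pd.DataFrame(rows)


def max_projection_figure(
    stack: MovieStack,
    path: str | Path | None = None,
) -> np.ndarray:
    """Per-pixel maximum over frames, rendered blue (low) to red (high).

    A cell that moved and then triggered appears as a red dot with a
    blue tail. Returns the projection array; saves a figure when a path
    is given.
    """
    projection = np.max(stack.frames, axis=0)
    if path is not None:
        fig, ax = plt.subplots(figsize=(6, 6))
        im = ax.imshow(projection, cmap="jet")
        fig.colorbar(im, ax=ax, label="max intensity (counts)")
        ax.set_title("Maximum intensity projection")
        ax.set_axis_off()
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return projection


def event_figures(
    summary: PopulationSummary,
    annotations: list[EventAnnotation],
    out_dir: str | Path,
) -> list[Path]:
    """Render the standard population figures and their source CSVs.

    Mean aligned R(t) with error band, triggering-time histogram and
    boxplot, responder-fraction bar. All plotted numbers are also
    written to CSV so figures are reproducible from text.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    curves = summary.curves_frame()
    curves_csv = out_dir / "summary_curves.csv"
    curves.to_csv(curves_csv, index=False)
    written.append(curves_csv)
    if len(curves):
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(curves["aligned_time_s"], curves["mean_R"], color="m", label="mean R(t)")
        if (curves["n_cells"] >= 2).any():
            ax.fill_between(
                curves["aligned_time_s"],
                curves["mean_R"] - curves["sdm_R"],
                curves["mean_R"] + curves["sdm_R"],
                alpha=0.3, color="m", label="± s.d.m.",
            )
        ax.set_xlabel("time after landing + offset (s)")
        ax.set_ylabel("R(t)")
        ax.legend()
        p = out_dir / "mean_response.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    t_csv = out_dir / "triggering_times.csv"
    pd.DataFrame({"T_s": summary.T_values}).to_csv(t_csv, index=False)
    written.append(t_csv)
    if len(summary.T_values) == 0:
        log_stage("figures", notice="no responders; T histogram and boxplot skipped")
    else:
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.hist(summary.T_values, bins="auto", color="tab:blue")
        ax1.set_xlabel("triggering interval T (s)")
        ax1.set_ylabel("cells")
        ax2.boxplot(summary.T_values, tick_labels=["all responders"])
        ax2.set_ylabel("T (s)")
        p = out_dir / "triggering_time.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    fig, ax = plt.subplots(figsize=(3, 4))
    ax.bar([0], [summary.fraction], yerr=[summary.fraction_sdm], color="tab:green")
    ax.set_xticks([0])
    ax.set_xticklabels(["responders"])
    ax.set_ylabel("fraction")
    ax.set_ylim(0, 1)
    p = out_dir / "fraction.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(p)
    return written
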