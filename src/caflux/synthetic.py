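"""Ground-truth synthetic movies of indicator-loaded cells landing on a surface.

Emulates the acquisition regime of a spinning-disk time-lapse of
Fluo-4-loaded lymphocytes in suspension: cells drift randomly above the
glass, land (instant cessation of movement plus a small intensity step
as they reach the focal plane), and a subset then fires a single global
calcium transient — a sharp rise over a few seconds followed by a slow
exponential decay, with amplitudes of several-fold up to ~100-fold over
baseline.

Every generated movie carries a :class:`GroundTruth` table (landing
frame, responder flag, trigger frame, amplitude, trajectory, mask) so
downstream stages can be validated by parameter recovery.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from caflux.movie_io import MovieStack

__all__ = [
    "SceneConfig",
    "CellTruth",
    "GroundTruth",
    "generate_movie",
    "write_ground_truth",
    "read_ground_truth",
    "transient_shape",
]

# distribution specs: {"kind": "uniform", "low": a, "high": b},
# {"kind": "fixed", "value": v}, {"kind": "exponential", "scale": s},
# {"kind": "normal", "mean": m, "sd": s} (truncated at 0)
def _sample_dist(rng: np.random.Generator, spec: dict, size: int) -> np.ndarray:
    kind = spec["kind"]
    if kind == "uniform":
        return rng.uniform(spec["low"], spec["high"], size)
    if kind == "fixed":
        return np.full(size, float(spec["value"]))
    if kind == "exponential":
        return rng.exponential(spec["scale"], size)
    if kind == "normal":
        return np.clip(rng.normal(spec["mean"], spec["sd"], size), 0.0, None)
    raise ValueError(f"unknown distribution kind {kind!r}")


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic landing-and-triggering scene.

    Defaults emulate the standard acquisition: a 512x512 field imaged at
    2 Hz for 600 frames (300 s), ~200 cells of radius ~8 px, 60% of
    which respond with amplitudes dI/I0 between 5.5 and 20. Landing
    times are uniform over the first minute; trigger delays uniform on
    50-200 s after landing. Pre-landing cells are dimmed by
    ``landing_step_factor`` (they are slightly out of focus) and move as
    a fixed-step random walk.
    """

    image_size: tuple[int, int] = (512, 512)
    n_frames: int = 600
    frame_interval: float = 0.5
    n_cells: int = 200
    cell_radius_px: tuple[float, float] = (6.0, 0.8)  # mean, sd
    min_separation_diameters: float = 2.0
    responder_fraction: float = 0.6
    landing_time_dist: dict = field(default_factory=lambda: {"kind": "uniform", "low": 5.0, "high": 60.0})
    trigger_delay_dist: dict = field(default_factory=lambda: {"kind": "uniform", "low": 50.0, "high": 200.0})
    baseline_intensity: float = 100.0
    landing_step_factor: float = 1.3
    amplitude_ratio_dist: dict = field(default_factory=lambda: {"kind": "uniform", "low": 5.5, "high": 20.0})
    rise_time: float = 3.0
    decay_time: float = 40.0
    diffusion_step_px: float = 1.0
    noise_gaussian_sd: float = 2.0
    noise_poisson: bool = False
    edge_blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        if not (self.decay_time > self.rise_time > 0):
            raise ValueError("require decay_time > rise_time > 0")
        if self.n_frames < 2 or self.n_cells < 0:
            raise ValueError("need n_frames >= 2 and n_cells >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.landing_step_factor < 1.0:
            raise ValueError("landing_step_factor must be >= 1")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be > 0")


def transient_shape(t: np.ndarray, rise_time: float, decay_time: float) -> np.ndarray:
    """Unit-peak calcium transient g(t): saturating-exponential rise times
    exponential decay, normalized so max g = 1; zero for t < 0.

    g(t) = (1 - exp(-t/rise)) * exp(-t/decay) / g_peak, with the peak at
    t* = rise * ln(1 + decay/rise).
    """
    t = np.asarray(t, dtype=float)
    a, b = float(rise_time), float(decay_time)
    t_peak = a * np.log1p(b / a)
    peak = (1.0 - np.exp(-t_peak / a)) * np.exp(-t_peak / b)
    g = np.where(t >= 0.0, (1.0 - np.exp(-np.maximum(t, 0.0) / a)) * np.exp(-np.maximum(t, 0.0) / b), 0.0)
    return g / peak


@dataclass
class CellTruth:
    """Ground truth for one synthetic cell."""

    cell_id: int
    true_landing_frame: int
    is_responder: bool
    true_trigger_frame: int | None
    true_amplitude_ratio: float
    radius_px: float
    trajectory: np.ndarray  # (n_frames, 2) float (row, col)


@dataclass
class GroundTruth:
    """Per-cell ground truth for a generated movie."""

    cells: list[CellTruth]
    config: SceneConfig

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def n_responders(self) -> int:
        return sum(c.true_trigger_frame is not None for c in self.cells)

    def mask(self, cell_id: int, frame: int) -> np.ndarray:
        """Boolean mask of the cell's rendered pixels at ``frame``."""
        cell = self.cells[cell_id]
        h, w = self.config.image_size
        return _disk_mask(cell.trajectory[frame], cell.radius_px, (h, w))

    def true_mean_trace(self, cell_id: int) -> np.ndarray:
        """Noise-free mean intensity of the cell per frame (the analytic
        transient actually rendered)."""
        cfg = self.config
        cell = self.cells[cell_id]
        return _cell_intensity_trace(cell, cfg)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": c.cell_id,
                "true_landing_frame": c.true_landing_frame,
                "is_responder": c.is_responder,
                "true_trigger_frame": -1 if c.true_trigger_frame is None else c.true_trigger_frame,
                "true_amplitude_ratio": c.true_amplitude_ratio,
            }
            for c in self.cells
        ]
        return pd.DataFrame(rows)


def _disk_mask(center: np.ndarray, radius: float, shape: tuple[int, int]) -> np.ndarray:
    """Pixels within ``radius`` of the integer-rounded centre."""
    r0, c0 = int(round(center[0])), int(round(center[1]))
    rr = int(np.ceil(radius))
    rows = np.arange(max(0, r0 - rr), min(shape[0], r0 + rr + 1))
    cols = np.arange(max(0, c0 - rr), min(shape[1], c0 + rr + 1))
    mask = np.zeros(shape, dtype=bool)
    if rows.size == 0 or cols.size == 0:
        return mask
    dr = rows[:, None] - r0
    dc = cols[None, :] - c0
    mask[np.ix_(rows, cols)] = dr * dr + dc * dc <= radius * radius
    return mask


def _cell_intensity_trace(cell: CellTruth, cfg: SceneConfig) -> np.ndarray:
    """Per-frame uniform disk intensity (camera counts, noise-free)."""
    n = cfg.n_frames
    dt = cfg.frame_interval
    i0 = cfg.baseline_intensity
    trace = np.full(n, i0 / cfg.landing_step_factor)
    land = cell.true_landing_frame
    trace[land:] = i0
    if cell.true_trigger_frame is not None:
        k = cell.true_trigger_frame
        t_rel = (np.arange(n) - k) * dt
        di = cell.true_amplitude_ratio * i0
        trace = trace + np.where(
            np.arange(n) >= k,
            di * transient_shape(t_rel, cfg.rise_time, cfg.decay_time),
            0.0,
        )
    return trace


def _place_cells(
    rng: np.random.Generator,
    cfg: SceneConfig,
    radii: np.ndarray,
    max_attempts_per_cell: int = 2000,
) -> np.ndarray:
    """Rejection-sample initial centres with >= 1 cell-diameter separation.

    Keeps boundary-overlap events rare, mirroring a suitably chosen cell
    density in the real experiment. Raises when the requested density is
    infeasible for the field of view.
    """
    h, w = cfg.image_size
    mean_d = 2.0 * float(np.mean(radii)) if len(radii) else 0.0
    sep = cfg.min_separation_diameters * mean_d
    margin = mean_d + float(np.max(radii, initial=0.0))
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ValueError(f"image {cfg.image_size} too small for cells of diameter {mean_d:.1f}")
    centers: list[np.ndarray] = []
    for i in range(cfg.n_cells):
        for _ in range(max_attempts_per_cell):
            cand = np.array([rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)])
            if all(np.hypot(*(cand - c)) >= sep for c in centers):
                centers.append(cand)
                break
        else:
            raise ValueError(
                f"could not place {cfg.n_cells} cells with {sep:.1f} px separation "
                f"in a {h}x{w} field (placed {i})"
            )
    return np.array(centers).reshape(cfg.n_cells, 2)


def generate_movie(config: SceneConfig) -> tuple[MovieStack, GroundTruth]:
    """Render a synthetic landing-and-triggering movie with ground truth.

    Cells random-walk with fixed-magnitude steps (``diffusion_step_px``
    per frame, uniform random direction) before their landing frame and
    are strictly stationary after it. Per-cell mean intensity follows
    the baseline I0 (dimmed by ``landing_step_factor`` pre-landing) and,
    for responders, a transient I0 + dI * g(t - t_trigger) with
    unit-peak shape g (see :func:`transient_shape`). Cells are rendered
    as uniform-intensity disks at the integer-rounded centroid, so with
    noise disabled each cell's rendered mean trace equals its analytic
    transient exactly. Identical configs (including seed) produce
    bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    n = cfg.n_frames
    dt = cfg.frame_interval

    radii = np.clip(
        rng.normal(cfg.cell_radius_px[0], cfg.cell_radius_px[1], cfg.n_cells),
        max(2.0, cfg.cell_radius_px[0] / 2), None,
    )
    centers = _place_cells(rng, cfg, radii)
    landing_times = _sample_dist(rng, cfg.landing_time_dist, cfg.n_cells)
    landing_frames = np.clip(np.rint(landing_times / dt).astype(int), 0, n - 1)
    is_responder = rng.random(cfg.n_cells) < cfg.responder_fraction
    delays = _sample_dist(rng, cfg.trigger_delay_dist, cfg.n_cells)
    amplitudes = _sample_dist(rng, cfg.amplitude_ratio_dist, cfg.n_cells)

    cells: list[CellTruth] = []
    for i in range(cfg.n_cells):
        land = int(landing_frames[i])
        # pre-landing random walk ending at the landing position
        traj = np.empty((n, 2))
        steps = np.zeros((n, 2))
        if land > 0:
            theta = rng.uniform(0, 2 * np.pi, land)
            steps[:land, 0] = cfg.diffusion_step_px * np.sin(theta)
            steps[:land, 1] = cfg.diffusion_step_px * np.cos(theta)
        pos = centers[i].copy()
        lim = radii[i] + 1.0
        for k in range(n):
            traj[k] = pos
            if k < land:
                pos = pos + steps[k]
                # reflect at the field border so cells never stall on it
                for ax, hi in ((0, h - 1 - lim), (1, w - 1 - lim)):
                    if pos[ax] < lim:
                        pos[ax] = 2 * lim - pos[ax]
                    elif pos[ax] > hi:
                        pos[ax] = 2 * hi - pos[ax]
        trigger: int | None = None
        if is_responder[i]:
            trigger = land + int(np.rint(delays[i] / dt))
            if trigger >= n:
                trigger = None  # fires after acquisition ends: unobservable
        cells.append(
            CellTruth(
                cell_id=i,
                true_landing_frame=land,
                is_responder=bool(is_responder[i] and trigger is not None),
                true_trigger_frame=trigger,
                true_amplitude_ratio=float(amplitudes[i]),
                radius_px=float(radii[i]),
                trajectory=traj,
            )
        )

    gt = GroundTruth(cells=cells, config=cfg)

    frames = np.zeros((n, h, w), dtype=np.float64)
    traces = [_cell_intensity_trace(c, cfg) for c in cells]
    for i, cell in enumerate(cells):
        rr = int(np.ceil(cell.radius_px))
        r2 = cell.radius_px ** 2
        for k in range(n):
            r0 = int(round(cell.trajectory[k, 0]))
            c0 = int(round(cell.trajectory[k, 1]))
            rs = slice(max(0, r0 - rr), min(h, r0 + rr + 1))
            cs = slice(max(0, c0 - rr), min(w, c0 + rr + 1))
            dr = np.arange(rs.start, rs.stop)[:, None] - r0
            dc = np.arange(cs.start, cs.stop)[None, :] - c0
            disk = dr * dr + dc * dc <= r2
            patch = frames[k, rs, cs]
            patch[disk] = np.maximum(patch[disk], traces[i][k])

    if cfg.edge_blur_sigma > 0:
        for k in range(n):
            frames[k] = ndimage.gaussian_filter(frames[k], cfg.edge_blur_sigma)

    if cfg.noise_poisson:
        frames = rng.poisson(np.maximum(frames, 0.0)).astype(np.float64)
    if cfg.noise_gaussian_sd > 0:
        frames = frames + rng.normal(0.0, cfg.noise_gaussian_sd, frames.shape)

    frames = np.clip(np.rint(frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    stack = MovieStack(frames=frames, frame_interval=dt)
    return stack, gt


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Write the ground-truth table to CSV (0-based frame indices).

    Non-responders carry an empty ``true_trigger_frame`` field.
    """
    if len(gt) == 0:
        raise ValueError("refusing to write an empty ground truth table")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["cell_id", "true_landing_frame", "is_responder", "true_trigger_frame", "true_amplitude_ratio"]
        )
        for c in gt.cells:
            writer.writerow(
                [
                    c.cell_id,
                    c.true_landing_frame,
                    int(c.is_responder),
                    "" if c.true_trigger_frame is None else c.true_trigger_frame,
                    repr(c.true_amplitude_ratio),
                ]
            )


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    """Read a ground-truth CSV back as a DataFrame (round-trip of
    :func:`write_ground_truth`)."""
    df = pd.read_csv(path)
    df["is_responder"] = df["is_responder"].astype(bool)
    df["true_trigger_frame"] = df["true_trigger_frame"].astype("Int64")
    return df
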