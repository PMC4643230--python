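"""Image-stack I/O, acquisition metadata and run configuration.

Conventions used throughout the package: frame indices are 0-based,
times are seconds (float), pixel coordinates are (row, col) 0-based.
Frame ``k`` of a movie maps to time ``origin_time + k * frame_interval``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml

logger = logging.getLogger("caflux")

_U16_MAX = np.iinfo(np.uint16).max


@dataclass(frozen=True)
class MovieStack:
    """A single-channel time-lapse movie with time/space calibration.

    Parameters
    ----------
    frames
        3-D array (frame, row, col) of camera counts.
    frame_interval
        Time between consecutive frames, seconds.
    pixel_size
        Pixel edge length in micrometres, if known.
    origin_time
        Acquisition time of frame 0, seconds.
    """

    frames: np.ndarray
    frame_interval: float
    pixel_size: float | None = None
    origin_time: float = 0.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (frame, row, col); got ndim={frames.ndim}")
        if frames.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames")
        if not self.frame_interval > 0:
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (rows, cols)."""
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame, seconds."""
        return self.origin_time + np.arange(self.n_frames) * self.frame_interval

    @property
    def duration(self) -> float:
        """Time span from first to last frame, seconds."""
        return (self.n_frames - 1) * self.frame_interval

    def frame_time(self, k: int) -> float:
        return self.origin_time + k * self.frame_interval


@dataclass(frozen=True)
class RunConfig:
    """Analysis parameters for a full pipeline run.

    The defaults encode the standard analysis regime: responders must
    show a >500% intensity increase over background (``response_threshold``
    = 5.0, a fold-change the user may override), only cells landing
    within the first 300 s are analysed, aligned time axes place t = 0
    at 2 s after landing, and cells closer than one cell diameter to the
    field edge are excluded.
    """

    response_threshold: float = 5.0
    landing_window: float = 300.0
    align_offset: float = 2.0
    edge_margin_diameters: float = 1.0
    smoothing_window_frames: int = 7
    smoothing_poly_order: int = 2
    motion_stop_threshold: float = 0.5   # px/frame
    motion_stop_frames: int = 5
    peak_min_prominence: float | None = None  # None -> adaptive (3x robust SD of pre-landing dR/dt)
    decrease_fraction: float = 0.2
    baseline_window_frames: int = 9
    # responder amplitude criterion: "fold_over_background" tests dI/I0 > threshold,
    # "ratio" tests Imax/I0 > threshold
    amplitude_criterion: str = "fold_over_background"
    # feature detection
    min_area_px: int = 20
    max_area_px: int = 5000
    detect_threshold: str = "background"  # "background" or "otsu"
    detect_sigma: float = 1.0
    track_gate_diameters: float = 1.0

    def __post_init__(self) -> None:
        if not self.response_threshold > 0:
            raise ValueError("response_threshold must be > 0")
        if self.smoothing_window_frames % 2 != 1:
            raise ValueError("smoothing_window_frames must be odd")
        if self.smoothing_window_frames <= self.smoothing_poly_order:
            raise ValueError("smoothing_window_frames must exceed smoothing_poly_order")
        if self.landing_window <= 0:
            raise ValueError("landing_window must be > 0")
        if self.amplitude_criterion not in ("fold_over_background", "ratio"):
            raise ValueError(f"unknown amplitude_criterion {self.amplitude_criterion!r}")
        if self.detect_threshold not in ("background", "otsu"):
            raise ValueError(f"unknown detect_threshold {self.detect_threshold!r}")

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def defaults() -> RunConfig:
    """Default run configuration."""
    return RunConfig()


def load_config(path: str | Path | None) -> RunConfig:
    """Load a :class:`RunConfig` from a flat YAML mapping.

    Unknown keys are rejected so that typos do not silently fall back to
    defaults. An empty or missing-content file yields the defaults.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def read_stack(
    path: str | Path,
    frame_interval: float,
    pixel_size: float | None = None,
    origin_time: float = 0.0,
) -> MovieStack:
    """Read a multi-page grayscale TIFF as a :class:`MovieStack`.

    Pages are taken in file order as acquisition order. Integer pixel
    data is preserved losslessly; 8-bit input is accepted as-is (it fits
    the 16-bit interchange range).
    """
    frames = tifffile.imread(str(path))
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise ValueError(f"{path}: single-frame stack; a movie needs at least 2 frames")
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected a single-channel multi-page TIFF, got shape {frames.shape}")
    return MovieStack(frames=frames, frame_interval=frame_interval,
                      pixel_size=pixel_size, origin_time=origin_time)


def write_stack(stack: MovieStack, path: str | Path) -> None:
    """Write a :class:`MovieStack` to a multi-page 16-bit grayscale TIFF.

    Page ``k`` holds frame ``k``. Values outside the unsigned 16-bit
    range are an error (no silent clipping).
    """
    frames = stack.frames
    if np.issubdtype(frames.dtype, np.floating):
        if not np.all(np.isfinite(frames)):
            raise ValueError("cannot write non-finite intensities")
        rounded = np.rint(frames)
        if rounded.min() < 0 or rounded.max() > _U16_MAX:
            raise ValueError(
                f"intensities [{frames.min()}, {frames.max()}] outside unsigned 16-bit range"
            )
        frames = rounded.astype(np.uint16)
    else:
        if frames.min() < 0 or frames.max() > _U16_MAX:
            raise ValueError(
                f"intensities [{frames.min()}, {frames.max()}] outside unsigned 16-bit range"
            )
        frames = frames.astype(np.uint16)
    tifffile.imwrite(str(path), frames, photometric="minisblack")


def log_stage(stage: str, **counts) -> None:
    """Structured per-stage log record (counts in/out of each filter)."""
    payload = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("[%s] %s", stage, payload)
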