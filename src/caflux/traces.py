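"""Per-cell intensity traces: extraction, smoothing, resampling, normalization.

The response of a cell is summarized by its relative fluorescence
R(t) = I(t) / Imax, where I(t) is the mean camera count over the cell's
segmented pixels at frame t and Imax the maximum of the (smoothed)
intensity curve. The baseline I0 is the median intensity immediately
after landing (before any triggering candidate) and dI = Imax - I0 is
the absolute response amplitude; dI/I0 is the fold-increase over
background used for responder classification and for dye-loading
robustness checks.

Processing order is fixed: extract -> smooth -> (optional resample) ->
normalize.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from caflux.movie_io import MovieStack, log_stage
from caflux.segmentation import CellRecord

__all__ = [
    "RawTrace",
    "NormalizedTrace",
    "extract_trace",
    "smooth_trace",
    "resample_trace",
    "normalize_trace",
]


@dataclass(frozen=True)
class RawTrace:
    """Mean intensity of one cell versus time (camera counts)."""

    cell_id: int
    times: np.ndarray
    intensities: np.ndarray
    n_pixels: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        n = np.asarray(self.n_pixels)
        if not (len(t) == len(i) == len(n)):
            raise ValueError("times, intensities, n_pixels must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(i < 0):
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", i)
        object.__setattr__(self, "n_pixels", n)

    @property
    def interval(self) -> float:
        return float(np.median(np.diff(self.times)))


@dataclass(frozen=True)
class NormalizedTrace:
    """Relative fluorescence R(t) = I(t)/Imax with baseline bookkeeping."""

    cell_id: int
    times: np.ndarray
    R: np.ndarray
    I0: float
    Imax: float

    @property
    def dI(self) -> float:
        return self.Imax - self.I0

    @property
    def fold_increase(self) -> float:
        """dI/I0, the fold-increase over background."""
        return self.dI / self.I0 if self.I0 > 0 else float("inf")

    @property
    def interval(self) -> float:
        return float(np.median(np.diff(self.times)))


def extract_trace(stack: MovieStack, record: CellRecord) -> RawTrace:
    """Mean stack intensity over the cell's mask, per frame.

    Frames inside the track span where segmentation dropped the cell are
    filled by linear interpolation of I(t) and flagged in the log; their
    n_pixels is recorded as 0.
    """
    frames = record.frames
    if len(frames) == 0:
        raise ValueError(f"cell {record.cell_id}: no frames")
    span = np.arange(frames[0], frames[-1] + 1)
    intensities = np.full(len(span), np.nan)
    npix = np.zeros(len(span), dtype=int)
    for f in frames:
        rows, cols = record.masks[f]
        if len(rows) == 0:
            raise ValueError(f"cell {record.cell_id}: empty mask at frame {f}")
        vals = stack.frames[f][rows, cols]
        intensities[f - span[0]] = float(np.mean(vals))
        npix[f - span[0]] = len(rows)
    missing = np.isnan(intensities)
    if missing.any():
        log_stage("extract", cell_id=record.cell_id, interpolated_frames=int(missing.sum()))
        good = ~missing
        intensities[missing] = np.interp(span[missing], span[good], intensities[good])
    times = stack.origin_time + span * stack.frame_interval
    return RawTrace(cell_id=record.cell_id, times=times, intensities=intensities, n_pixels=npix)


def smooth_trace(trace: RawTrace, window_frames: int = 7, poly_order: int = 2) -> RawTrace:
    """Savitzky-Golay smoothing.

    Each sample is replaced by the value at its position of the
    least-squares polynomial of degree ``poly_order`` fitted over the
    centred window; at the edges the boundary window's polynomial is
    evaluated (extrapolation), so polynomials of degree <= poly_order
    pass through unchanged.
    """
    if window_frames % 2 != 1:
        raise ValueError("window_frames must be odd")
    if window_frames <= poly_order:
        raise ValueError("window_frames must exceed poly_order")
    if len(trace.intensities) < window_frames:
        raise ValueError(
            f"trace of {len(trace.intensities)} samples shorter than window {window_frames}"
        )
    smoothed = savgol_filter(trace.intensities, window_frames, poly_order, mode="interp")
    return replace(trace, intensities=np.maximum(smoothed, 0.0))


def resample_trace(trace: RawTrace, target_interval: float) -> RawTrace:
    """Resample to a coarser (or equal) sampling interval.

    For an integer multiple of the native interval this decimates,
    keeping every k-th sample from sample 0 — simulating a slower
    acquisition. Non-integer ratios fall back to linear interpolation on
    the uniform target grid spanning the original range.
    """
    if target_interval <= 0:
        raise ValueError("target_interval must be > 0")
    native = trace.interval
    ratio = target_interval / native
    k = int(round(ratio))
    if abs(ratio - k) < 1e-9 and k >= 1:
        times = trace.times[::k]
        intens = trace.intensities[::k]
        npix = trace.n_pixels[::k]
    else:
        times = np.arange(trace.times[0], trace.times[-1] + 1e-9, target_interval)
        intens = np.interp(times, trace.times, trace.intensities)
        npix = np.interp(times, trace.times, trace.n_pixels).astype(int)
    if len(times) < 4:
        raise ValueError(
            f"resampling to {target_interval} s leaves {len(times)} samples (< 4)"
        )
    return RawTrace(cell_id=trace.cell_id, times=times, intensities=intens, n_pixels=npix)


def normalize_trace(
    trace: RawTrace,
    baseline_window: int = 9,
    t_landing: float | None = None,
) -> NormalizedTrace:
    """Normalize to R(t) = I(t)/Imax and estimate the baseline I0.

    I0 is the median of I over ``baseline_window`` samples starting at
    the first sample at or after ``t_landing`` (the post-landing,
    pre-trigger plateau); if no landing time is given the first
    ``baseline_window`` samples are used. Imax is the maximum of the
    trace, so max(R) = 1 exactly at that sample.
    """
    if len(trace.intensities) == 0:
        raise ValueError("empty trace")
    imax = float(np.max(trace.intensities))
    if imax <= 0:
        raise ValueError("Imax is zero; cannot normalize")
    if t_landing is None:
        start = 0
    else:
        start = int(np.searchsorted(trace.times, t_landing - 1e-9))
        start = min(start, max(len(trace.intensities) - 1, 0))
    stop = min(start + baseline_window, len(trace.intensities))
    i0 = float(np.median(trace.intensities[start:stop]))
    return NormalizedTrace(
        cell_id=trace.cell_id,
        times=trace.times.copy(),
        R=trace.intensities / imax,
        I0=i0,
        Imax=imax,
    )
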