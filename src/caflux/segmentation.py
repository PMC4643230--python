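"""Cell detection, tracking, landing detection and inclusion filtering.

Cells are detected per frame (background-robust threshold + connected
components with an area gate), optionally refined by DRLSE, linked into
trajectories by nearest-centroid association with a step gate, and then
screened by the standard inclusion rules: the cell must land (stop
moving) within the landing window, sit at least one cell diameter from
the field edge, and never overlap another cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters

from caflux.movie_io import MovieStack, RunConfig, log_stage

__all__ = [
    "Feature",
    "CellRecord",
    "detect_features",
    "track_cells",
    "detect_landing",
    "filter_cells",
    "segment_movie",
]


@dataclass
class Feature:
    """One connected bright region in a single frame."""

    centroid: np.ndarray          # (row, col)
    area: int
    mean_intensity: float
    pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols) int arrays

    @property
    def equivalent_diameter(self) -> float:
        return 2.0 * np.sqrt(self.area / np.pi)


@dataclass
class CellRecord:
    """One tracked cell across the movie.

    ``trajectory``/``masks``/``intensities``/``n_pixels`` are keyed by
    frame index over the frames where the cell was detected. Frames
    missed by detection inside the track are filled during trace
    extraction, not here.
    """

    cell_id: int
    trajectory: dict[int, np.ndarray] = field(default_factory=dict)
    masks: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    intensities: dict[int, float] = field(default_factory=dict)
    n_pixels: dict[int, int] = field(default_factory=dict)
    first_seen_frame: int = 0
    last_seen_frame: int = 0
    landing_frame: int | None = None
    diameter_px: float = 0.0
    overlap: bool = False
    included: bool = False
    exclusion_reason: str = "none"   # edge | late_landing | overlap | no_landing | none

    @property
    def frames(self) -> np.ndarray:
        return np.array(sorted(self.trajectory), dtype=int)

    def centroid_at(self, frame: int) -> np.ndarray:
        return self.trajectory[frame]


def _robust_background_threshold(smoothed: np.ndarray) -> float:
    """Background median + 5 robust SD (MAD-based).

    Robust to a handful of very bright responders that would dominate a
    bimodal-histogram threshold like Otsu's.
    """
    bg = float(np.median(smoothed))
    mad = float(np.median(np.abs(smoothed - bg)))
    return bg + 5.0 * 1.4826 * mad


def detect_features(
    frame: np.ndarray,
    min_area_px: int = 20,
    max_area_px: int = 5000,
    sigma: float = 1.0,
    threshold: str = "background",
) -> list[Feature]:
    """Detect candidate cell regions in one frame.

    Gaussian pre-smoothing, thresholding (``"background"``: median + 5
    robust SD; ``"otsu"``: Otsu's method), connected components, area
    gate. Centroids and mean intensities are computed on the raw frame.
    Returns an empty list on a blank frame.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    smoothed = ndimage.gaussian_filter(frame, sigma) if sigma > 0 else frame
    if threshold == "background":
        thr = _robust_background_threshold(smoothed)
    elif threshold == "otsu":
        if smoothed.max() == smoothed.min():
            return []
        thr = float(filters.threshold_otsu(smoothed))
    else:
        raise ValueError(f"unknown threshold method {threshold!r}")
    binary = smoothed > thr
    if not binary.any():
        return []
    labels, n = ndimage.label(binary)
    if n == 0:
        return []
    flat = labels.ravel()
    areas = np.bincount(flat, minlength=n + 1)
    # per-label pixel coordinates via one stable sort
    order = np.argsort(flat, kind="stable")
    sorted_labels = flat[order]
    boundaries = np.searchsorted(sorted_labels, np.arange(n + 2))
    h, w = frame.shape
    bg = float(np.median(smoothed))
    sm_flat = smoothed.ravel()
    feats: list[Feature] = []
    for lab in range(1, n + 1):
        a = int(areas[lab])
        if a < min_area_px:  # max gate is applied after the half-max cut
            continue
        idx = order[boundaries[lab]:boundaries[lab + 1]]
        # cut the component at its half-max: the supra-threshold blur skirt
        # of a bright cell would otherwise dilute the mean intensity, and
        # the dilution would grow with brightness, biasing dI/I0 downward
        local = sm_flat[idx]
        cut = bg + 0.5 * (float(np.percentile(local, 90)) - bg)
        keep = idx[local >= cut]
        if not (min_area_px <= len(keep) <= max_area_px):
            continue
        rows_k = (keep // w).astype(np.int32)
        cols_k = (keep % w).astype(np.int32)
        vals = frame.ravel()[keep]
        feats.append(
            Feature(
                centroid=np.array([rows_k.mean(), cols_k.mean()]),
                area=len(keep),
                mean_intensity=float(vals.mean()),
                pixels=(rows_k, cols_k),
            )
        )
    return feats


class _Track:
    __slots__ = ("record", "last_frame", "last_centroid", "diameter")

    def __init__(self, record: CellRecord, frame: int, feat: Feature):
        self.record = record
        self.last_frame = frame
        self.last_centroid = feat.centroid
        self.diameter = feat.equivalent_diameter

    def add(self, frame: int, feat: Feature) -> None:
        rec = self.record
        rec.trajectory[frame] = feat.centroid
        rec.masks[frame] = feat.pixels
        rec.intensities[frame] = feat.mean_intensity
        rec.n_pixels[frame] = feat.area
        rec.last_seen_frame = frame
        self.last_frame = frame
        self.last_centroid = feat.centroid
        # slow running update keeps the gate scale-honest as focus changes
        self.diameter = 0.9 * self.diameter + 0.1 * feat.equivalent_diameter


def track_cells(
    stack: MovieStack,
    per_frame_features: list[list[Feature]],
    config: RunConfig | None = None,
    max_missed_frames: int = 5,
) -> list[CellRecord]:
    """Link per-frame detections into cell trajectories.

    Nearest-centroid association with a maximum step gate of
    ``track_gate_diameters`` cell diameters per frame. When two tracks
    claim the same detection within the gate, both are flagged as
    overlapping (and excluded later). Tracks unmatched for more than
    ``max_missed_frames`` frames are closed; unmatched detections open
    new tracks.
    """
    config = config or RunConfig()
    if len(per_frame_features) != stack.n_frames:
        raise ValueError("need features for every frame")
    tracks: list[_Track] = []
    closed: list[_Track] = []
    next_id = 0
    for k, feats in enumerate(per_frame_features):
        active = [t for t in tracks if k - t.last_frame <= max_missed_frames]
        newly_closed = [t for t in tracks if k - t.last_frame > max_missed_frames]
        closed.extend(newly_closed)
        tracks = active
        assigned: dict[int, list[int]] = {}
        if feats and tracks:
            cents = np.array([f.centroid for f in feats])
            for ti, tr in enumerate(tracks):
                d = np.hypot(*(cents - tr.last_centroid).T)
                gate = config.track_gate_diameters * max(tr.diameter, 1.0) * (k - tr.last_frame)
                j = int(np.argmin(d))
                if d[j] <= gate:
                    assigned.setdefault(j, []).append(ti)
        used = set()
        for j, claimants in assigned.items():
            if len(claimants) > 1:
                # ambiguous: two cells within gate of one detection
                dists = [
                    float(np.hypot(*(feats[j].centroid - tracks[ti].last_centroid)))
                    for ti in claimants
                ]
                order = np.lexsort((
                    [tracks[ti].record.cell_id for ti in claimants], dists))
                for ti in claimants:
                    tracks[ti].record.overlap = True
                winner = claimants[int(order[0])]
            else:
                winner = claimants[0]
            tracks[winner].add(k, feats[j])
            used.add(j)
        for j, f in enumerate(feats):
            if j in used:
                continue
            rec = CellRecord(cell_id=next_id, first_seen_frame=k, last_seen_frame=k)
            next_id += 1
            tr = _Track(rec, k, f)
            tr.add(k, f)
            tracks.append(tr)
    closed.extend(tracks)
    records = sorted((t.record for t in closed), key=lambda r: r.cell_id)
    for rec in records:
        areas = [rec.n_pixels[f] for f in rec.n_pixels]
        rec.diameter_px = 2.0 * np.sqrt(np.median(areas) / np.pi) if areas else 0.0
    log_stage("track", n_detections=sum(len(f) for f in per_frame_features), n_tracks=len(records))
    return records


def detect_landing(record: CellRecord, config: RunConfig, n_frames: int | None = None) -> int | None:
    """First frame from which the cell stops moving for good.

    Returns the first frame ``f`` such that the per-frame displacement
    stays below ``motion_stop_threshold`` px/frame for the next
    ``motion_stop_frames`` consecutive frames and the cell remains
    present until the end of the movie; ``None`` if the cell never
    stops. Landing marks the moment a cell in suspension touches the
    surface — an immediate cessation of movement.
    """
    frames = record.frames
    if len(frames) < config.motion_stop_frames + 1:
        return None
    if n_frames is not None and record.last_seen_frame < n_frames - 1 - 5:
        return None  # disappeared before movie end: never landed in view
    # displacement per frame on the detected grid (gaps count as motion over the gap)
    pos = np.array([record.trajectory[f] for f in frames])
    dpos = np.hypot(*np.diff(pos, axis=0).T)
    dframes = np.diff(frames)
    step = dpos / dframes
    m = config.motion_stop_frames
    slow = step < config.motion_stop_threshold
    # also require frame continuity inside the stationarity window
    contiguous = dframes == 1
    ok = slow & contiguous
    for i in range(len(ok) - m + 1):
        if ok[i:i + m].all() and slow[i:].all():
            if i == 0 and record.first_seen_frame > 0:
                # track born mid-movie already stationary: no cessation of
                # movement was ever observed (e.g. a re-detected fragment
                # after an overlap), so no landing can be assigned
                return None
            return int(frames[i])
    return None


def filter_cells(
    records: list[CellRecord],
    stack: MovieStack,
    config: RunConfig,
) -> list[CellRecord]:
    """Apply the inclusion rules, setting ``included``/``exclusion_reason``.

    Exclusions: never landed; overlapping boundaries; landing later than
    the landing window (default 300 s); centroid at landing closer than
    ``edge_margin_diameters`` cell diameters to any image edge. Counts
    per reason are logged.
    """
    h, w = stack.shape
    counts = {"included": 0, "no_landing": 0, "overlap": 0, "late_landing": 0, "edge": 0}
    for rec in records:
        if rec.landing_frame is None:
            rec.included, rec.exclusion_reason = False, "no_landing"
        elif rec.overlap:
            rec.included, rec.exclusion_reason = False, "overlap"
        elif stack.frame_time(rec.landing_frame) - stack.origin_time > config.landing_window:
            rec.included, rec.exclusion_reason = False, "late_landing"
        else:
            r, c = rec.centroid_at(rec.landing_frame)
            margin = config.edge_margin_diameters * rec.diameter_px
            if min(r, c, h - 1 - r, w - 1 - c) < margin:
                rec.included, rec.exclusion_reason = False, "edge"
            else:
                rec.included, rec.exclusion_reason = True, "none"
        counts["included" if rec.included else rec.exclusion_reason] += 1
    log_stage("filter", n_tracks=len(records), **counts)
    return records


def segment_movie(stack: MovieStack, config: RunConfig | None = None) -> list[CellRecord]:
    """Full segmentation stage: detect -> track -> landing -> filters."""
    config = config or RunConfig()
    per_frame = [
        detect_features(
            stack.frames[k],
            min_area_px=config.min_area_px,
            max_area_px=config.max_area_px,
            sigma=config.detect_sigma,
            threshold=config.detect_threshold,
        )
        for k in range(stack.n_frames)
    ]
    records = track_cells(stack, per_frame, config)
    for rec in records:
        rec.landing_frame = detect_landing(rec, config, n_frames=stack.n_frames)
    return filter_cells(records, stack, config)
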