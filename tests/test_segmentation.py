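import numpy as np
import pytest

from caflux.movie_io import MovieStack, RunConfig
from caflux.segmentation import (
    CellRecord,
    detect_features,
    detect_landing,
    filter_cells,
    track_cells,
)


def disks_frame(centers, radius=8, hi=100.0, size=200):
    frame = np.zeros((size, size))
    rr, cc = np.mgrid[:size, :size]
    for r0, c0 in centers:
        frame[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = hi
    return frame


def stationary_record(n_frames=10, pos=(50.0, 50.0), start=0, cell_id=0, last=None):
    rec = CellRecord(cell_id=cell_id, first_seen_frame=start)
    for k in range(start, start + n_frames):
        rec.trajectory[k] = np.array(pos)
        rec.masks[k] = (np.array([int(pos[0])]), np.array([int(pos[1])]))
        rec.intensities[k] = 100.0
        rec.n_pixels[k] = 1
    rec.last_seen_frame = start + n_frames - 1
    rec.diameter_px = 16.0
    return rec


def moving_then_stopped_record(steps, cell_id=0):
    """Trajectory from per-frame step sizes (applied along the row axis)."""
    rec = CellRecord(cell_id=cell_id, first_seen_frame=0)
    pos = np.array([50.0, 50.0])
    for k, s in enumerate([0.0] + list(steps)):
        pos = pos + np.array([s, 0.0])
        rec.trajectory[k] = pos.copy()
        rec.masks[k] = (np.array([int(pos[0])]), np.array([int(pos[1])]))
        rec.intensities[k] = 100.0
        rec.n_pixels[k] = 1
    rec.last_seen_frame = len(steps)
    rec.diameter_px = 16.0
    return rec


class TestDetectFeatures:
    def test_blank_frame_yields_nothing(self):
        assert detect_features(np.zeros((64, 64))) == []

    def test_single_disk_centroid_within_1px(self):
        frame = disks_frame([(80, 120)], radius=10, size=200)
        feats = detect_features(frame)
        assert len(feats) == 1
        assert np.hypot(*(feats[0].centroid - np.array([80, 120]))) < 1.0

    def test_fifty_disks_all_found(self):
        centers = [(25 + 35 * i, 25 + 35 * j) for i in range(8) for j in range(7)][:50]
        frame = disks_frame(centers, radius=8, size=300)
        feats = detect_features(frame)
        assert len(feats) == 50

    def test_masks_disjoint_within_frame(self):
        centers = [(40, 40), (40, 100), (100, 70)]
        frame = disks_frame(centers, radius=10, size=150)
        feats = detect_features(frame)
        seen = set()
        for f in feats:
            px = set(zip(f.pixels[0].tolist(), f.pixels[1].tolist()))
            assert not (px & seen)
            seen |= px

    def test_area_gate_applied(self):
        frame = disks_frame([(50, 50)], radius=3, size=100)  # area ~ 29
        assert detect_features(frame, min_area_px=100) == []


class TestTrackCells:
    def test_single_stationary_cell(self):
        frames = np.stack([disks_frame([(60, 60)], size=120)] * 10)
        stack = MovieStack(frames, frame_interval=0.5)
        feats = [detect_features(f) for f in frames]
        records = track_cells(stack, feats)
        assert len(records) == 1
        rec = records[0]
        assert len(rec.trajectory) == 10
        pos = np.array(list(rec.trajectory.values()))
        assert np.ptp(pos, axis=0).max() == 0.0

    def test_crossing_cells_flagged_as_overlap(self):
        # two cells converge onto the same position -> merged detection
        frames = []
        for k in range(12):
            c1 = (60, 30 + 5 * k)
            c2 = (60, 130 - 5 * k)
            frames.append(disks_frame([c1, c2], radius=8, size=160))
        stack = MovieStack(np.stack(frames), frame_interval=0.5)
        feats = [detect_features(f) for f in frames]
        records = track_cells(stack, feats)
        long_tracks = [r for r in records if len(r.trajectory) >= 5]
        assert len(long_tracks) >= 2
        assert all(r.overlap for r in long_tracks[:2])

    def test_synthetic_movie_track_recall(self, small_analysis):
        stack, gt, _, result, matched = small_analysis
        assert matched["matched"].mean() >= 0.95


class TestDetectLanding:
    def test_landing_at_first_zero_step(self):
        rec = moving_then_stopped_record([3, 3, 3, 0, 0, 0, 0, 0])
        config = RunConfig(motion_stop_threshold=0.5, motion_stop_frames=3)
        # steps: frames 0->1..: positions move for 3 steps then freeze at frame 3
        assert detect_landing(rec, config) == 3

    def test_never_stopping_cell(self):
        rec = moving_then_stopped_record([3] * 20)
        assert detect_landing(rec, RunConfig(motion_stop_frames=3)) is None

    def test_time_shift_equivariance(self):
        steps = [3, 3, 3, 3, 0, 0, 0, 0, 0, 0]
        config = RunConfig(motion_stop_threshold=0.5, motion_stop_frames=3)
        base = detect_landing(moving_then_stopped_record(steps), config)
        rec = moving_then_stopped_record(steps)
        shifted = CellRecord(cell_id=0, first_seen_frame=rec.first_seen_frame + 7)
        for k in sorted(rec.trajectory):
            shifted.trajectory[k + 7] = rec.trajectory[k]
            shifted.masks[k + 7] = rec.masks[k]
            shifted.intensities[k + 7] = rec.intensities[k]
            shifted.n_pixels[k + 7] = rec.n_pixels[k]
        shifted.last_seen_frame = rec.last_seen_frame + 7
        assert detect_landing(shifted, config) == base + 7

    def test_born_stationary_mid_movie_has_no_landing(self):
        rec = stationary_record(n_frames=20, start=50)
        assert detect_landing(rec, RunConfig()) is None

    def test_accuracy_on_synthetic_movie(self, small_analysis):
        _, _, _, _, matched = small_analysis
        inc = matched[matched["matched"] & matched["included"]]
        assert (inc["landing_error_frames"].abs() <= 1).mean() >= 0.95


class TestFilterCells:
    def _stack(self, n=20, size=200):
        return MovieStack(np.zeros((n, size, size), dtype=np.uint16), frame_interval=0.5)

    def test_late_landing_excluded(self):
        stack = MovieStack(np.zeros((700, 50, 50), dtype=np.uint16), frame_interval=0.5)
        rec = stationary_record(pos=(25.0, 25.0))
        rec.landing_frame = 620  # t = 310 s > 300 s window
        filter_cells([rec], stack, RunConfig())
        assert not rec.included and rec.exclusion_reason == "late_landing"

    def test_edge_cell_excluded(self):
        stack = self._stack()
        rec = stationary_record(pos=(5.0, 100.0))
        rec.landing_frame = 0
        rec.diameter_px = 20.0
        filter_cells([rec], stack, RunConfig(edge_margin_diameters=1.0))
        assert not rec.included and rec.exclusion_reason == "edge"

    def test_clean_centered_cell_included(self):
        stack = self._stack(n=300)
        rec = stationary_record(n_frames=300, pos=(100.0, 100.0))
        rec.landing_frame = 200  # t = 100 s
        filter_cells([rec], stack, RunConfig())
        assert rec.included and rec.exclusion_reason == "none"

    def test_overlap_and_no_landing_reasons(self):
        stack = self._stack()
        a = stationary_record(pos=(100.0, 100.0), cell_id=0)
        a.landing_frame = None
        b = stationary_record(pos=(100.0, 60.0), cell_id=1)
        b.landing_frame = 2
        b.overlap = True
        filter_cells([a, b], stack, RunConfig())
        assert a.exclusion_reason == "no_landing"
        assert b.exclusion_reason == "overlap"
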