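import numpy as np
import pytest

from caflux.movie_io import RunConfig
from caflux.synthetic import transient_shape
from caflux.traces import NormalizedTrace, RawTrace, normalize_trace, smooth_trace
from caflux.events import (
    EventAnnotation,
    align_trace,
    annotate_cell,
    classify_responder,
    derivative,
    find_event_peaks,
    triggering_interval,
)


def ntrace(values, interval=0.5, I0=None, cell_id=0):
    values = np.asarray(values, dtype=float)
    imax = values.max()
    return NormalizedTrace(
        cell_id=cell_id,
        times=np.arange(len(values)) * interval,
        R=values / imax,
        I0=float(values[0] if I0 is None else I0),
        Imax=float(imax),
    )


def responder_intensities(n=600, dt=0.5, t_land=30.0, t_trig=120.0, i0=100.0, fold=6.0,
                          dim=1.3, rise=3.0, decay=40.0):
    t = np.arange(n) * dt
    vals = np.where(t < t_land, i0 / dim, i0)
    vals = vals + fold * i0 * transient_shape(t - t_trig, rise, decay)
    return vals


def build_trace(vals, dt=0.5, t_land=30.0, smooth=True):
    tr = RawTrace(cell_id=0, times=np.arange(len(vals)) * dt,
                  intensities=np.asarray(vals, float),
                  n_pixels=np.ones(len(vals), int))
    if smooth:
        tr = smooth_trace(tr, 7, 2)
    return normalize_trace(tr, baseline_window=9, t_landing=t_land)


class TestDerivative:
    def test_linear_R(self):
        tr = ntrace(np.linspace(0.0, 10.0, 21) + 1, interval=0.5)
        d = derivative(tr)
        np.testing.assert_allclose(d.dRdt, np.full(21, (10.0 / 20 / 0.5) / 11.0), rtol=1e-9)

    def test_constant_R_zero(self):
        d = derivative(ntrace([5.0] * 10))
        np.testing.assert_array_equal(d.dRdt, np.zeros(10))

    def test_quadratic_exact_in_interior(self):
        t = np.arange(20) * 0.5
        vals = 1.0 + 0.1 * t + 0.05 * t**2
        tr = ntrace(vals)
        d = derivative(tr)
        expected = (0.1 + 0.1 * t) / vals.max()
        np.testing.assert_allclose(d.dRdt[1:-1], expected[1:-1], rtol=1e-9)

    def test_non_uniform_grid_rejected(self):
        tr = NormalizedTrace(0, np.array([0.0, 1.0, 3.0]), np.array([0.1, 0.2, 1.0]), 1.0, 10.0)
        with pytest.raises(ValueError, match="uniform"):
            derivative(tr)


class TestFindEventPeaks:
    def test_single_large_peak_is_trigger(self):
        vals = responder_intensities()
        n = build_trace(vals)
        _, trig = find_event_peaks(derivative(n), t_landing=30.0, config=RunConfig())
        assert trig is not None
        assert abs(trig.onset_time - 120.0) <= 1.0

    def test_flat_after_landing_gives_none(self):
        vals = responder_intensities(fold=0.0)
        n = build_trace(vals)
        _, trig = find_event_peaks(derivative(n), t_landing=30.0, config=RunConfig())
        assert trig is None

    def test_onset_accuracy_on_synthetic_movie(self, small_analysis):
        _, _, _, _, matched = small_analysis
        errs = matched["trigger_error_s"].dropna()
        assert len(errs) > 5
        assert (errs.abs() <= 1.0).mean() >= 0.95


class TestClassifyResponder:
    def test_sixfold_with_decay_is_responder(self):
        n = build_trace(responder_intensities(fold=6.0))
        _, trig = find_event_peaks(derivative(n), 30.0, RunConfig())
        is_resp, fold = classify_responder(n, trig, RunConfig())
        assert is_resp
        assert fold == pytest.approx(6.0, rel=0.05)

    def test_threefold_below_default_threshold(self):
        n = build_trace(responder_intensities(fold=3.0))
        _, trig = find_event_peaks(derivative(n), 30.0, RunConfig())
        is_resp, fold = classify_responder(n, trig, RunConfig())
        assert not is_resp
        assert fold == pytest.approx(3.0, rel=0.05)

    def test_monotone_rise_without_decrease_rejected(self):
        t = np.arange(300) * 0.5
        vals = 10.0 + 80.0 * (t / t.max()) ** 2  # keeps rising to trace end
        n = build_trace(vals, t_land=0.0)
        _, trig = find_event_peaks(derivative(n), 0.0, RunConfig())
        is_resp, fold = classify_responder(n, trig, RunConfig())
        assert fold > 5.0
        assert not is_resp

    @pytest.mark.parametrize("thr", [1.0, 3.0, 5.0, 8.0, 30.0])
    def test_threshold_monotonicity(self, thr):
        # raising the threshold can only remove responders
        for fold in (2.0, 6.0, 12.0):
            n = build_trace(responder_intensities(fold=fold))
            cfg_lo = RunConfig(response_threshold=thr)
            cfg_hi = RunConfig(response_threshold=thr * 1.5)
            _, trig = find_event_peaks(derivative(n), 30.0, cfg_lo)
            hi, _ = classify_responder(n, trig, cfg_hi)
            lo, _ = classify_responder(n, trig, cfg_lo)
            assert lo or not hi

    def test_scale_invariance_of_classification_and_T(self):
        for c in (0.1, 7.0):
            n1 = build_trace(responder_intensities())
            n2 = build_trace(responder_intensities() * c)
            a1 = annotate_cell(n1, 30.0, RunConfig())
            a2 = annotate_cell(n2, 30.0, RunConfig())
            assert a1.is_responder == a2.is_responder
            assert a1.T == pytest.approx(a2.T, abs=1e-9)
            np.testing.assert_allclose(n1.R, n2.R, rtol=1e-9)


class TestAlignTrace:
    def test_origin_two_seconds_after_landing(self):
        n = build_trace(responder_intensities(), t_land=50.0)
        aligned = align_trace(n, 50.0, RunConfig(align_offset=2.0))
        j = np.argmin(np.abs(n.times - 52.0))
        assert aligned.times[j] == pytest.approx(0.0)

    def test_zero_offset_origin_at_landing(self):
        n = build_trace(responder_intensities())
        aligned = align_trace(n, 30.0, RunConfig(align_offset=0.0))
        j = np.argmin(np.abs(n.times - 30.0))
        assert aligned.times[j] == pytest.approx(0.0)

    def test_two_cells_share_post_alignment_grid(self):
        cfg = RunConfig()
        n1 = build_trace(responder_intensities(t_land=30.0), t_land=30.0)
        n2 = build_trace(responder_intensities(t_land=60.0), t_land=60.0)
        a1 = align_trace(n1, 30.0, cfg)
        a2 = align_trace(n2, 60.0, cfg)
        common1 = set(np.round(a1.times, 6)) & set(np.round(a2.times, 6))
        assert len(common1) > 100


class TestTriggeringInterval:
    def test_subtraction(self):
        ann = EventAnnotation(0, t_landing=50.0, t_triggering=163.0,
                              is_responder=True, peak_response=6.0, I0=100, Imax=700)
        assert triggering_interval(ann) == pytest.approx(113.0)

    def test_none_for_non_responder(self):
        ann = EventAnnotation(0, t_landing=50.0, t_triggering=None,
                              is_responder=False, peak_response=0.5, I0=100, Imax=150)
        assert triggering_interval(ann) is None

    def test_time_shift_equivariance(self):
        vals = responder_intensities()
        a0 = annotate_cell(build_trace(vals, t_land=30.0), 30.0, RunConfig())
        shifted = RawTrace(0, np.arange(len(vals)) * 0.5 + 40.0, vals, np.ones(len(vals), int))
        n_sh = normalize_trace(smooth_trace(shifted, 7, 2), baseline_window=9, t_landing=70.0)
        a1 = annotate_cell(n_sh, 70.0, RunConfig())
        assert a1.t_triggering == pytest.approx(a0.t_triggering + 40.0, abs=1e-6)
        assert a1.T == pytest.approx(a0.T, abs=1e-6)

    def test_recovery_on_synthetic_movie(self, small_analysis):
        # per-cell comparison over matched responders: detected T within
        # +/- 1 s of the generated landing-to-trigger delay for >= 95%
        _, gt, _, result, matched = small_analysis
        ann_by_id = {a.cell_id: a for a in result.annotations}
        errors = []
        for _, row in matched.iterrows():
            if not (row["matched"] and row["included"] and row["true_is_responder"]):
                continue
            ann = ann_by_id.get(row["detected_cell_id"])
            if ann is None or not ann.is_responder:
                continue
            true_T = (row["true_trigger_frame"] - row["true_landing_frame"]) * 0.5
            errors.append(ann.T - true_T)
        errors = np.array(errors)
        assert len(errors) > 5
        assert (np.abs(errors) <= 1.0).mean() >= 0.95
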