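import numpy as np
import pytest
from scipy import signal as sps

from neurosteps import (
    FILTER_BANDS,
    AccelRecording,
    StepAnnotationSet,
    apply_filter,
    assign_axes,
    make_windows,
    window_starts,
)
from tests.conftest import make_sinusoid_recording


def _recording_from_channels(ch0, ch1, ch2, fs=100.0):
    n = len(ch0)
    t = np.arange(n) / fs
    return AccelRecording("s", "waist", fs, t, np.column_stack([ch0, ch1, ch2]))


class TestAxisAssignment:
    def test_gravity_axis(self):
        rec = _recording_from_channels(np.zeros(100), np.zeros(100), np.full(100, 9.81))
        axes = assign_axes(rec)
        assert axes.vertical_index == 2
        assert axes.vertical_sign == 1

    def test_upside_down_sensor(self):
        rec = _recording_from_channels(np.zeros(100), np.zeros(100), np.full(100, -9.81))
        axes = assign_axes(rec)
        assert axes.vertical_index == 2
        assert axes.vertical_sign == -1

    def test_anteroposterior_by_correlation(self):
        rng = np.random.default_rng(0)
        vert = 9.81 + np.sin(2 * np.pi * 1.0 * np.arange(500) / 100)
        correlated = (vert - 9.81) + rng.normal(0, 0.05, 500)
        independent = rng.normal(0, 1.0, 500)
        rec = _recording_from_channels(correlated, independent, vert)
        axes = assign_axes(rec)
        assert axes.vertical_index == 2
        assert axes.anteroposterior_index == 0

    def test_rotation_invariance(self):
        # permuting/flipping axes leaves the recovered vertical signal intact
        rng = np.random.default_rng(1)
        vert = 9.81 + np.sin(2 * np.pi * np.arange(300) / 100)
        ap = 0.5 * (vert - 9.81) + rng.normal(0, 0.02, 300)
        ml = rng.normal(0, 0.02, 300)
        rec = _recording_from_channels(ap, ml, vert)
        axes = assign_axes(rec)
        recovered = axes.vertical_sign * rec.accel[:, axes.vertical_index]
        flipped = _recording_from_channels(-vert, ml, ap)  # permute + flip
        axes2 = assign_axes(flipped)
        recovered2 = axes2.vertical_sign * flipped.accel[:, axes2.vertical_index]
        np.testing.assert_array_equal(recovered, recovered2)

    def test_zero_variance_fallback(self):
        rec = _recording_from_channels(np.zeros(100), np.zeros(100), np.full(100, 9.81))
        assert assign_axes(rec).anteroposterior_index == 0

    def test_empty_recording_rejected(self):
        rec = _recording_from_channels(np.array([]), np.array([]), np.array([]))
        with pytest.raises(ValueError, match="empty"):
            assign_axes(rec)


class TestFilters:
    def test_band_definitions(self):
        assert FILTER_BANDS["wide"].kind == "lowpass" and FILTER_BANDS["wide"].high_cut == 15.0
        assert (FILTER_BANDS["medium"].low_cut, FILTER_BANDS["medium"].high_cut) == (0.2, 5.0)
        assert (FILTER_BANDS["narrow"].low_cut, FILTER_BANDS["narrow"].high_cut) == (0.5, 3.0)
        assert all(b.order == 5 for b in FILTER_BANDS.values())

    def test_bandpass_rejects_dc(self):
        rec = make_sinusoid_recording(0.0, amplitude=0.0, duration_s=20.0)  # constant g
        out = apply_filter(rec, "narrow")
        assert np.abs(out.accel[:, 2]).max() < 1e-6

    @pytest.mark.parametrize("freq,band,lo,hi", [
        (2.0, "narrow", 0.95, 1.05),   # passband (small ripple allowed)
        (10.0, "narrow", 0.0, 0.05),   # stopband
        (1.0, "medium", 0.95, 1.05),
        (5.0, "wide", 0.95, 1.05),
    ])
    def test_sinusoid_gain(self, freq, band, lo, hi):
        rec = make_sinusoid_recording(freq, duration_s=30.0)
        out = apply_filter(rec, band)
        # steady-state amplitude away from the edges
        core = out.accel[500:-500, 2]
        gain = (core.max() - core.min()) / 2.0
        assert lo <= gain <= hi

    def test_zero_phase(self):
        rec = make_sinusoid_recording(2.0, duration_s=30.0)
        out = apply_filter(rec, "narrow")
        x = rec.accel[500:-500, 2] - rec.accel[500:-500, 2].mean()
        y = out.accel[500:-500, 2]
        xc = np.correlate(x, y, mode="full")
        lag = int(np.argmax(xc)) - (len(x) - 1)
        assert lag == 0

    def test_matches_independent_filtfilt(self):
        # cross-check against the transfer-function form of the same design
        rec = make_sinusoid_recording(1.5, duration_s=10.0, noise_sd=0.1)
        out = apply_filter(rec, "narrow")
        b, a = sps.butter(5, [0.5, 3.0], btype="bandpass", fs=100.0)
        expected = sps.filtfilt(b, a, rec.accel[:, 2])
        # the transfer-function form of an order-10 bandpass is mildly
        # ill-conditioned, so agreement is approximate
        np.testing.assert_allclose(out.accel[100:-100, 2], expected[100:-100], atol=2e-3)

    def test_short_recording_rejected(self):
        rec = make_sinusoid_recording(2.0, duration_s=0.2)
        with pytest.raises(ValueError, match="warm-up"):
            apply_filter(rec, "narrow")

    def test_nyquist_violation_rejected(self):
        rec = make_sinusoid_recording(2.0, duration_s=10.0, sample_rate=20.0)
        with pytest.raises(ValueError, match="sample_rate"):
            apply_filter(rec, "wide")


class TestWindows:
    def test_grid_geometry(self):
        starts = window_starts(10.0, 5.0)
        np.testing.assert_allclose(starts, [0.0, 2.5, 5.0])

    def test_half_open_counting(self):
        rec = make_sinusoid_recording(1.0, duration_s=10.0)
        ann = StepAnnotationSet(events=((1.0, "walking"), (2.0, "walking"), (7.0, "walking")))
        windows = make_windows(rec, ann, 5.0)
        assert windows[0].true_step_count == 2   # [0, 5)
        boundary = StepAnnotationSet(events=((2.5, "walking"),))
        w = make_windows(rec, boundary, 5.0)
        # event at an exact start boundary belongs to the later window too
        assert [x.true_step_count for x in w] == [1, 1, 0]

    def test_exclusion_invalidates_intersecting_windows(self):
        rec = make_sinusoid_recording(1.0, duration_s=10.0)
        ann = StepAnnotationSet(events=(), excluded=((4.0, 6.0),))
        windows = make_windows(rec, ann, 5.0)
        assert [w.valid for w in windows] == [False, False, False]
        ann2 = StepAnnotationSet(events=(), excluded=((9.6, 9.9),))
        windows2 = make_windows(rec, ann2, 5.0)
        assert [w.valid for w in windows2] == [True, True, False]

    def test_too_short_recording_gives_empty_list(self):
        rec = make_sinusoid_recording(1.0, duration_s=1.0)
        assert make_windows(rec, StepAnnotationSet(events=()), 5.0) == []

    def test_label_conservation_non_overlapping(self):
        rec = make_sinusoid_recording(1.0, duration_s=20.0)
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 20, 37))
        ann = StepAnnotationSet(events=tuple((float(t), "walking") for t in times))
        windows = make_windows(rec, ann, 5.0)
        non_overlap = [w for w in windows if (w.start / 5.0) == int(w.start / 5.0)]
        assert sum(w.true_step_count for w in non_overlap) == 37

    def test_overlap_double_counting_identity(self):
        # with 50 % overlap, Σ counts = 2×total − (first half of first window
        # + last half of last window)
        rec = make_sinusoid_recording(1.0, duration_s=20.0)
        rng = np.random.default_rng(1)
        times = np.sort(rng.uniform(0, 20, 53))
        ann = StepAnnotationSet(events=tuple((float(t), "walking") for t in times))
        windows = make_windows(rec, ann, 5.0)
        first_half = np.sum((times >= 0) & (times < 2.5))
        last_half = np.sum((times >= windows[-1].start + 2.5) & (times < windows[-1].end))
        uncovered = np.sum(times >= windows[-1].end)
        total_covered = 53 - uncovered
        assert sum(w.true_step_count for w in windows) == 2 * total_covered - first_half - last_half

    def test_brute_force_label_agreement(self):
        rec = make_sinusoid_recording(1.0, duration_s=13.0)
        rng = np.random.default_rng(2)
        times = np.sort(rng.uniform(0, 13, 29))
        ann = StepAnnotationSet(events=tuple((float(t), "walking") for t in times))
        for length in (0.5, 2.0, 5.0):
            for w in make_windows(rec, ann, length):
                brute = sum(1 for t in times if w.start <= t < w.end)
                assert w.true_step_count == brute
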