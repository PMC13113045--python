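import numpy as np
import pytest

from cardiomap import activation as act
from cardiomap import synth
from cardiomap.io import FrameStack, RoiSet


def pulse_wave_stack(n_px=10, n_frames=14, baseline=100.0, peak=200.0):
    """Plane wave at 1 pixel/frame: pixel j flashes at frames j and j+1."""
    frames = np.full((n_frames, 1, n_px), baseline)
    for j in range(n_px):
        frames[j, 0, j] = peak
        if j + 1 < n_frames:
            frames[j + 1, 0, j] = peak
    return FrameStack(frames, 110.0, 5.0)


class TestActivationMap:
    def test_plane_wave_one_pixel_per_frame(self):
        stack = pulse_wave_stack()
        amap = act.activation_map(stack, theta=0.10)
        times = amap.times_ms[0]
        assert np.allclose(times, np.arange(10) * 110.0)

    def test_uniform_movie_is_empty_flagged(self):
        stack = FrameStack(np.full((8, 4, 4), 100.0), 110.0, 5.0)
        amap = act.activation_map(stack)
        assert amap.is_empty and amap.n_activated == 0

    def test_full_field_flash_is_simultaneous(self):
        frames = np.full((10, 4, 4), 100.0)
        frames[5] = 300.0
        amap = act.activation_map(FrameStack(frames, 110.0, 5.0))
        assert np.allclose(amap.times_ms, 0.0)
        assert amap.first_frame == 5

    def test_global_scaling_invariance(self):
        stack = pulse_wave_stack()
        a = act.activation_map(stack)
        scaled = FrameStack(stack.frames * 3.7, 110.0, 5.0)
        b = act.activation_map(scaled)
        assert np.array_equal(a.frames, b.frames)

    def test_theta_required_positive(self):
        with pytest.raises(ValueError):
            act.activation_map(pulse_wave_stack(), theta=0.0)

    def test_never_activated_distinct_from_time_zero(self):
        stack = pulse_wave_stack()
        amap = act.activation_map(stack)
        t = amap.times_ms
        assert np.isnan(t[0, 0]) is np.False_  # pixel 0 activates at 0 ms
        assert t[0, 0] == 0.0


class TestSplitBeats:
    def test_multi_beat_windows(self):
        stack, truth = synth.gen_wave_movie(n_beats=3, seed=4)
        windows = act.split_beats(stack)
        assert len(windows) == 3
        assert windows[0][0] == 0 and windows[-1][1] == stack.n_frames

    def test_constant_movie_single_window(self):
        stack = FrameStack(np.full((10, 4, 4), 7.0), 110.0, 5.0)
        assert act.split_beats(stack) == [(0, 10)]


class TestClassifyEvent:
    def test_simultaneous_cluster_is_single_frame(self):
        frames = np.full((10, 4, 4), 100.0)
        frames[3] = 300.0
        amap = act.activation_map(FrameStack(frames, 110.0, 5.0))
        roi = RoiSet(np.ones((4, 4), dtype=int))
        ev = act.classify_event(amap, roi, 1, pixel_size=5.0)
        assert ev.outcome == "single_frame" and ev.frames_spanned == 1

    def test_two_frame_span_is_multi_frame(self):
        frames = np.full((10, 1, 4), 100.0)
        frames[3, 0, :2] = 300.0
        frames[4, 0, 2:] = 300.0
        amap = act.activation_map(FrameStack(frames, 110.0, 5.0))
        ev = act.classify_event(amap, RoiSet(np.ones((1, 4), dtype=int)), 1, 5.0)
        assert ev.outcome == "multi_frame" and ev.frames_spanned == 2

    def test_too_few_activated_pixels_rejected(self):
        frames = np.full((6, 2, 2), 100.0)
        frames[2, 0, 0] = 300.0
        amap = act.activation_map(FrameStack(frames, 110.0, 5.0))
        with pytest.raises(ValueError, match="activated"):
            act.classify_event(amap, RoiSet(np.ones((2, 2), dtype=int)), 1, 5.0)


class TestSpaceTime:
    def test_plane_wave_band_slope(self):
        stack, truth = synth.gen_wave_movie(cv=2.0, cluster_length_um=600.0,
                                            grid=(32, 140), seed=6, noise_sd=0.0)
        row = stack.shape[1] // 2
        cols = np.nonzero(truth.cluster_mask[row])[0]
        path = np.column_stack([np.full_like(cols, row), cols])
        stp = act.space_time_plot(stack, path)
        # first-crossing time of the normalized band advances with position
        onset_frames = (stp > 0.5).argmax(axis=1)
        fit = np.polyfit(np.arange(len(cols)) * 5.0, onset_frames * 110.0, 1)
        assert 1.0 / fit[0] == pytest.approx(2.0, rel=0.1)  # µm/ms = mm/s

    def test_constant_movie_rows(self):
        stack = FrameStack(np.full((6, 3, 3), 5.0), 110.0, 5.0)
        stp = act.space_time_plot(stack, np.array([[0, 0], [0, 1]]))
        assert stp.shape == (2, 6)
        assert np.allclose(stp, 0.0)

    def test_reversed_path_mirrors(self):
        stack = pulse_wave_stack()
        path = np.column_stack([np.zeros(10, int), np.arange(10)])
        a = act.space_time_plot(stack, path)
        b = act.space_time_plot(stack, path[::-1])
        assert np.array_equal(a, b[::-1])

    def test_path_outside_image_rejected(self):
        stack = pulse_wave_stack()
        with pytest.raises(ValueError, match="outside"):
            act.space_time_plot(stack, np.array([[0, 0], [5, 5]]))


class TestSynchronization:
    def test_embedded_rois_in_one_wave_are_synchronized(self):
        stack, truth = synth.gen_wave_movie(cv=20.0, seed=8)
        amap = act.activation_map(stack)
        labels = np.zeros(truth.cluster_mask.shape, dtype=int)
        labels[truth.cluster_mask] = 1
        ys, xs = np.nonzero(truth.cluster_mask)
        labels[ys[:20], xs[:20]] = 2   # small embedded patch
        roi = RoiSet(labels, {1: "monolayer", 2: "MSC"})
        table, ok = act.synchronization(amap, roi)
        assert ok
        assert (table["offset_ms"] <= stack.frame_interval).all()

    def test_phase_shifted_group_not_synchronized(self):
        frames = np.full((14, 2, 4), 100.0)
        frames[2, :, :2] = 300.0     # group A beats at frame 2
        frames[5, :, 2:] = 300.0     # group B at +3 frames
        amap = act.activation_map(FrameStack(frames, 110.0, 5.0))
        labels = np.zeros((2, 4), dtype=int)
        labels[:, :2] = 1
        labels[:, 2:] = 2
        table, ok = act.synchronization(amap, RoiSet(labels, {1: "A", 2: "B"}))
        assert not ok
        assert table.set_index("group").loc["B", "offset_ms"] == pytest.approx(330.0)

    def test_single_group_offset_zero(self):
        frames = np.full((8, 2, 2), 100.0)
        frames[3] = 300.0
        amap = act.activation_map(FrameStack(frames, 110.0, 5.0))
        roi = RoiSet(np.ones((2, 2), dtype=int), {1: "only"})
        table, ok = act.synchronization(amap, roi)
        assert ok and table["offset_ms"].iloc[0] == 0.0

    def test_silent_group_reported_non_participating(self):
        frames = np.full((8, 2, 4), 100.0)
        frames[3, :, :2] = 300.0
        amap = act.activation_map(FrameStack(frames, 110.0, 5.0))
        labels = np.zeros((2, 4), dtype=int)
        labels[:, :2] = 1
        labels[:, 2:] = 2
        table, ok = act.synchronization(amap, RoiSet(labels, {1: "A", 2: "B"}))
        assert not ok
        assert table.set_index("group").loc["B", "n_activated"] == 0


class TestEstimateCv:
    def test_recovers_true_cv_when_wave_spans_frames(self):
        for seed in range(5):
            stack, truth = synth.gen_wave_movie(cv=2.0, cluster_length_um=600.0,
                                                grid=(32, 140), seed=seed)
            amap = act.activation_map(stack)
            cv = act.estimate_cv(amap, stack.pixel_size, mask=truth.cluster_mask)
            assert cv == pytest.approx(2.0, rel=0.10)

    def test_flat_map_gives_infinite_cv(self):
        frames = np.full((8, 4, 4), 100.0)
        frames[3] = 300.0
        amap = act.activation_map(FrameStack(frames, 110.0, 5.0))
        assert act.estimate_cv(amap, 5.0) == np.inf
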