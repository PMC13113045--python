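import math

import numpy as np
import pandas as pd
import pytest

from cardiomap import synth


class TestWaveMovie:
    def test_traversal_time_matches_length_over_cv(self):
        """A 300 µm cluster crossed at 20.55 mm/s takes ~14.6 ms."""
        _, truth = synth.gen_wave_movie(cv=20.55, cluster_length_um=300.0, seed=0)
        expected = truth.traversal_time_ms
        # the analytic value L/CV, up to pixel discretization of the span
        assert expected == pytest.approx(300.0 / 20.55, rel=0.03)

    def test_near_infinite_cv_gives_flat_activation(self):
        _, truth = synth.gen_wave_movie(cv=1e9, seed=1)
        assert truth.traversal_time_ms < 1e-3
        onsets = truth.activation_true[truth.cluster_mask]
        assert np.allclose(onsets, onsets[0], atol=1e-3)

    def test_activation_truth_finite_exactly_on_mask(self):
        _, truth = synth.gen_wave_movie(seed=2)
        assert np.isfinite(truth.activation_true[truth.cluster_mask]).all()
        assert np.isnan(truth.activation_true[~truth.cluster_mask]).all()

    def test_cluster_length_is_mask_caliper(self):
        _, truth = synth.gen_wave_movie(cluster_length_um=300.0, pixel_size=5.0, seed=3)
        assert truth.cluster_length_um == pytest.approx(300.0, rel=0.05)

    def test_single_frame_capture_frequency_matches_formula(self):
        """Monte-Carlo capture frequency matches p = max(0, 1 - T/dt),
        including the T >= dt regime where p = 0."""
        n = 4000
        for cv, expect_zero in [(20.0, False), (2.0, True)]:
            _, truth0 = synth.gen_wave_movie(cv=cv, n_beats=1, seed=0,
                                             grid=(16, 68), cluster_width_um=50.0)
            t_true = truth0.traversal_time_ms
            p = max(0.0, 1.0 - t_true / 110.0)
            rng = np.random.default_rng(99)
            phases = rng.uniform(0, 110.0, size=n)
            # oracle: a beat is captured iff no frame boundary falls inside
            captured = np.floor(phases / 110.0) == np.floor((phases + t_true) / 110.0)
            emp = captured.mean()
            se = math.sqrt(max(p * (1 - p), 1e-12) / n)
            if expect_zero:
                assert p == 0.0 and emp == 0.0
            else:
                assert abs(emp - p) <= 3 * se + 1e-9

    def test_generator_outcomes_agree_with_truth_record(self):
        stack, truth = synth.gen_wave_movie(n_beats=5, seed=7, grid=(16, 68),
                                            cluster_width_um=50.0)
        outcomes = synth.single_frame_outcomes(truth, stack.frame_interval)
        assert len(outcomes) == 5

    @pytest.mark.parametrize("bad", [
        dict(grid=(0, 10)), dict(cv=-1.0), dict(frame_interval=0.0),
        dict(grid=(8, 8), cluster_length_um=300.0),
    ])
    def test_parameter_errors(self, bad):
        with pytest.raises(ValueError):
            synth.gen_wave_movie(**bad)

    def test_seed_reproducibility(self):
        a, _ = synth.gen_wave_movie(seed=5)
        b, _ = synth.gen_wave_movie(seed=5)
        assert np.array_equal(a.frames, b.frames)


class TestSpontaneousTraces:
    def test_analytic_cat50_is_tau_ln2(self):
        """tau = 408 ms gives the analytic CaT50 of 283 ms."""
        _, truths = synth.gen_spontaneous_traces(n_cells=2, tau_decay=408.0,
                                                 tau_sd=0.0, seed=0)
        assert truths[0].cat50_ms == pytest.approx(408.0 * math.log(2), abs=1e-9)
        assert truths[0].cat50_ms == pytest.approx(283, abs=0.5)

    def test_noiseless_amplitude_identity(self):
        # onset aligned to the sample grid: the detected peak equals the
        # generated amplitude exactly
        trace, truth = synth.gen_single_transient(408.0, frame_interval=110.0,
                                                  onset_ms=220.0, noise_sd=0.0)
        assert trace.max() == pytest.approx(truth.baseline + truth.amplitude,
                                            abs=1e-12)

    def test_zero_variance_periods_are_exact(self):
        df, _ = synth.gen_spontaneous_traces(n_cells=3, period_sd=0.0,
                                             noise_sd=0.0, irregular_fraction=0.0,
                                             tau_sd=0.0, seed=2)
        assert set(df.columns) == {"id", "time_ms", "value"}

    def test_irregular_cells_have_long_intervals(self):
        _, truths = synth.gen_spontaneous_traces(n_cells=10, irregular_fraction=1.0,
                                                 seed=3)
        assert all(t.period_ms > 5000 for t in truths)

    def test_duration_too_short_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            synth.gen_spontaneous_traces(duration_s=1.0, period_mean=1000.0)

    def test_reproducible(self):
        a, _ = synth.gen_spontaneous_traces(n_cells=4, seed=9)
        b, _ = synth.gen_spontaneous_traces(n_cells=4, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestCellImage:
    def test_rod_mask_aspect_ratio(self):
        truth = synth.CellImageTruth(100.0, 20.0)
        _, mask = synth.gen_cell_image(truth)
        ys, xs = np.nonzero(mask)
        extent = (xs.max() - xs.min() + 1) * 0.2
        width = (ys.max() - ys.min() + 1) * 0.2
        assert extent / width == pytest.approx(5.0, rel=0.05)

    def test_circle_circularity(self):
        from cardiomap.morphometry import descriptors

        truth = synth.CellImageTruth(50.0, 50.0)
        _, mask = synth.gen_cell_image(truth)
        d = descriptors(mask, 0.2)
        assert d.circularity == pytest.approx(1.0, abs=0.03)

    def test_striation_period_by_construction(self):
        from cardiomap.morphometry import striation_fft

        truth = synth.CellImageTruth(100.0, 20.0, striation_period_um=2.0, seed=4)
        img, mask = synth.gen_cell_image(truth, pixel_size=0.2)
        res = striation_fft(img, mask, 0.2)
        assert res.is_striated
        assert res.dominant_period_um == pytest.approx(2.0, abs=0.3)

    def test_aliasing_rejected(self):
        truth = synth.CellImageTruth(100.0, 20.0, striation_period_um=1.0)
        with pytest.raises(ValueError, match="alias"):
            synth.gen_cell_image(truth, pixel_size=0.3)

    def test_truth_invariants(self):
        with pytest.raises(ValueError):
            synth.CellImageTruth(10.0, 20.0)   # width > length
        with pytest.raises(ValueError):
            synth.CellImageTruth(100.0, 20.0, striation_period_um=0.5)


class TestEphysSweeps:
    def test_density_truth_arithmetic(self):
        """A -153.2 pA fast peak at 20 pF is -7.66 pA/pF by construction."""
        truth = synth.EphysTruth(cm_pF=20.0)
        assert truth.g_fast_in * truth.cm_pF == pytest.approx(153.2)
        assert truth.density_truth()["fast_in"] == pytest.approx(-7.66)

    def test_null_outward_component(self):
        truth = synth.EphysTruth(g_out=0.0, cm_pF=20.0)
        df = synth.gen_ephys_sweeps(truth, synth.PROTOCOL_IV, noise_sd=0.0,
                                    leak_pA=0.0, seed=0)
        for _, sw in df.groupby("sweep_id"):
            step = sw[sw["command_mV"] >= 0]
            tail = step.tail(100)["current_pA"].to_numpy()
            assert np.allclose(tail, 0.0, atol=1e-9)

    def test_capacitance_scaling_identity(self):
        t1 = synth.EphysTruth(cm_pF=15.0)
        t2 = synth.EphysTruth(cm_pF=30.0)
        d1 = synth.gen_ephys_sweeps(t1, noise_sd=0.0, leak_pA=0.0, seed=0)
        d2 = synth.gen_ephys_sweeps(t2, noise_sd=0.0, leak_pA=0.0, seed=0)
        assert np.allclose(d2["current_pA"], 2 * d1["current_pA"], atol=1e-9)
        assert t1.density_truth() == t2.density_truth()

    def test_coarse_sampling_rejected(self):
        with pytest.raises(ValueError, match="fast"):
            synth.gen_ephys_sweeps(synth.EphysTruth(), sample_interval=2.5)

    def test_cm_validation(self):
        with pytest.raises(ValueError):
            synth.EphysTruth(cm_pF=0.0)

    def test_ap_trace_construction(self):
        df = synth.gen_ap_trace(noise_sd=0.0)
        vm = df["vm_mV"].to_numpy()
        assert vm.max() == pytest.approx(25.0, abs=0.5)
        assert vm[0] == pytest.approx(-50.0)
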