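"""Axon preprocessing, reward-aligned binning, ramp metrics."""

import numpy as np
import pytest

from placecode import axons as ax
from placecode import behavior as bhv


class TestMergeRois:
    def test_identical_traces_merge(self, rng):
        base = rng.random(500)
        merged = ax.merge_correlated_rois(np.stack([base, base]))
        assert merged.shape[0] == 1
        np.testing.assert_allclose(merged[0], base)

    def test_independent_noise_stays_separate(self, rng):
        traces = rng.normal(0, 1, (2, 2000))
        merged = ax.merge_correlated_rois(traces)
        assert merged.shape[0] == 2

    def test_chain_merges_transitively(self, rng):
        """A~B and B~C merge {A, B, C} even when A and C correlate weakly."""
        t = np.linspace(0, 20 * np.pi, 3000)
        b = np.sin(t)
        a = b + rng.normal(0, 0.55, t.size)
        c = -0.0 + b + rng.normal(0, 0.55, t.size)
        corr = np.corrcoef(np.stack([a, b, c]))
        assert corr[0, 1] >= 0.7 and corr[1, 2] >= 0.7 and corr[0, 2] < 0.7
        merged = ax.merge_correlated_rois(np.stack([a, b, c]))
        assert merged.shape[0] == 1

    def test_single_roi_passthrough(self, rng):
        traces = rng.random((1, 100))
        np.testing.assert_array_equal(ax.merge_correlated_rois(traces), traces)


class TestAxonDff:
    def test_constant_trace_zero(self):
        out = ax.axon_dff(np.full(3000, 5.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_drift_removed_events_preserved(self, rng):
        T = 6000
        drift = 5.0 + np.linspace(0, 0.5, T)
        events = np.zeros(T)
        for onset in (1000, 2500, 4200):
            events[onset:onset + 30] = 3.0
        out = ax.axon_dff(drift + events)
        # baseline regions near zero, event amplitude preserved within 10%
        assert abs(np.median(out)) < 0.1
        expected = 3.0 / drift[1000]
        assert out[1000:1030].max() == pytest.approx(expected, rel=0.1)

    def test_short_trace_truncates_window_with_warning(self):
        with pytest.warns(UserWarning, match="shorter than baseline window"):
            out = ax.axon_dff(np.full(500, 2.0), window=2000)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_nonpositive_baseline_errors(self):
        with pytest.raises(ValueError, match="positive"):
            ax.axon_dff(np.zeros(3000))


class TestTimeBinning:
    def test_linear_ramp_monotone_bins(self, axon_session):
        s = axon_session["session"]
        table = axon_session["lap_table"]
        laps = table.select(condition="R")
        matrix, missing = ax.bin_by_time_to_reward(s.dff[0], s, laps)
        assert matrix.shape == (len(laps), 40)
        pre = np.nanmean(matrix[:, :ax.N_PRE_BINS], axis=0)
        # ramp rises toward reward: last pre-bin is the largest
        assert np.argmax(pre) >= ax.N_PRE_BINS - 3
        diffs = np.diff(pre[2:])
        assert (diffs > -0.02).mean() >= 0.9

    def test_constant_signal_all_zero_after_min_subtraction(self, axon_session):
        s = axon_session["session"]
        laps = axon_session["lap_table"].select(condition="R")
        matrix, _ = ax.bin_by_time_to_reward(np.full(s.n_frames, 0.7), s, laps)
        np.testing.assert_allclose(matrix, 0.0, atol=1e-12)

    def test_unrewarded_laps_align_to_teleport(self, axon_session):
        s = axon_session["session"]
        laps = axon_session["lap_table"].select(condition="UR")
        matrix, missing = ax.bin_by_time_to_reward(s.dff[0], s, laps)
        assert matrix.shape[0] == len(laps)
        assert np.isfinite(matrix[:, :ax.N_PRE_BINS]).all()

    def test_rows_nonnegative_with_zero_min(self, axon_session):
        s = axon_session["session"]
        laps = [l for l in axon_session["lap_table"] if not l.partial]
        matrix, _ = ax.bin_by_time_to_reward(s.dff[0], s, laps)
        assert np.nanmin(matrix) >= 0.0
        np.testing.assert_allclose(np.nanmin(matrix, axis=1), 0.0, atol=1e-12)


class TestRampMetrics:
    def test_r_means_exactly_one(self, axon_session):
        s = axon_session["session"]
        laps = [l for l in axon_session["lap_table"] if not l.partial]
        profile = ax.ramp_profile(s.dff[0], s, laps)
        assert profile.condition_mean("slope", "R") == pytest.approx(1.0)
        assert profile.condition_mean("max", "R") == pytest.approx(1.0)
        assert profile.condition_mean("slope_max", "R") == pytest.approx(1.0)

    def test_silent_relow_ramp_near_zero(self):
        """With the low-expectation ramp amplitude at zero, slope*max in
        RE_low laps is near zero."""
        from placecode.simulate import SimConfig, generate_axon_session

        cfg = SimConfig(ramp_amplitudes={"R": 1.0, "RE_HIGH": 0.57,
                                         "RE_LOW": 0.0, "RR": 1.0})
        s, _ = generate_axon_session(cfg, seed=2)
        table = bhv.segment_laps(s)
        zone = bhv.anticipation_zone(s, table)
        bhv.detect_lick_stop_lap(s, table, zone)
        laps = [l for l in table if not l.partial]
        profile = ax.ramp_profile(s.dff[0], s, laps)
        assert abs(profile.condition_mean("slope_max", "RE_LOW")) < 0.15

    def test_invariant_to_additive_offset(self, axon_session):
        """Adding a constant to the trace leaves slope*max unchanged
        (absorbed by per-lap min subtraction)."""
        s = axon_session["session"]
        laps = [l for l in axon_session["lap_table"] if not l.partial]
        p1 = ax.ramp_profile(s.dff[0], s, laps)
        p2 = ax.ramp_profile(s.dff[0] + 3.7, s, laps)
        ok = ~p1.excluded & ~p2.excluded
        np.testing.assert_allclose(p1.slope_max[ok], p2.slope_max[ok],
                                   rtol=1e-8)

    def test_amplitude_recovery(self):
        """Configured slope*max levels are recovered per condition."""
        from placecode.simulate import generate_axon_session

        rec = {"RE_HIGH": [], "RE_LOW": []}
        for seed in range(4):
            s, _ = generate_axon_session(seed=seed)
            table = bhv.segment_laps(s)
            zone = bhv.anticipation_zone(s, table)
            bhv.detect_lick_stop_lap(s, table, zone)
            laps = [l for l in table if not l.partial]
            profile = ax.ramp_profile(s.dff[0], s, laps)
            for k in rec:
                rec[k].append(profile.condition_mean("slope_max", k))
        assert np.nanmean(rec["RE_HIGH"]) == pytest.approx(0.57, abs=0.1)
        assert np.nanmean(rec["RE_LOW"]) == pytest.approx(0.24, abs=0.1)


class TestMotionAlignment:
    def test_short_crossing_no_epoch(self):
        v = np.zeros(600)
        v[100:110] = 2.0          # 0.33 s, below the 1 s minimum
        with pytest.warns(UserWarning, match="no motion epochs"):
            res = ax.motion_aligned_activity(np.zeros(600), v)
        assert res["n_epochs"] == 0

    def test_window_starts_two_seconds_before_onset(self):
        v = np.zeros(900)
        v[300:600] = 5.0
        trace = np.arange(900, dtype=float)
        res = ax.motion_aligned_activity(trace, v)
        assert res["n_epochs"] == 1
        # window covers -2 s .. +8 s around frame 300
        assert res["dff"][0, 0] == 300 - 60
        assert res["time_s"][0] == pytest.approx(-2.0)

    def test_velocity_coupled_axon_correlates(self, rng):
        T = 3000
        v = np.zeros(T)
        for onset in (300, 1200, 2100):
            v[onset:onset + 400] = np.linspace(0, 20, 400)
        trace = v / 20.0 + rng.normal(0, 0.02, T)
        res = ax.motion_aligned_activity(trace, v)
        assert res["n_epochs"] == 3
        r = np.corrcoef(res["mean_dff"], res["mean_velocity"])[0, 1]
        assert r >= 0.8
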