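"""Lap segmentation, lick-stop detection, engagement, helpers."""

import numpy as np
import pytest

from placecode.session import SessionRecord, BinningSpec
from placecode import behavior as bhv


def _sawtooth_session(n_laps=10, frames_per_lap=120, condition="R"):
    T = n_laps * frames_per_lap
    pos = np.tile(np.linspace(0, 199.9, frames_per_lap), n_laps)
    return SessionRecord(
        time=np.arange(T) / 30.0,
        position=pos,
        velocity=np.full(T, 199.9 / (frames_per_lap / 30.0)),
        lick=np.zeros(T, dtype=bool),
        reward=np.zeros(T, dtype=bool),
        condition=np.full(T, condition, dtype=object),
        dff=np.zeros((1, T)),
    )


class TestSegmentLaps:
    def test_sawtooth_ten_laps(self):
        table = bhv.segment_laps(_sawtooth_session(10))
        complete = table.select(condition="R")
        assert len(complete) == 10
        # frames partition exactly
        frames = sum(l.end_frame - l.start_frame for l in table)
        assert frames == 10 * 120

    def test_condition_change_mid_track_splits(self):
        s = _sawtooth_session(2)
        s.condition[180:] = "UR"      # switch mid second lap
        table = bhv.segment_laps(s)
        partial = [l for l in table if l.partial]
        assert len(partial) == 2
        assert {l.condition for l in partial} == {"R", "UR"}

    def test_no_wrap_truncated_lap_with_warning(self):
        s = _sawtooth_session(1)
        s.position = np.linspace(0, 150.0, s.n_frames)   # never completes
        with pytest.warns(UserWarning, match="no complete lap"):
            table = bhv.segment_laps(s)
        assert len(table) == 1
        assert table.laps[0].partial

    def test_synthetic_lap_count_matches_ground_truth(self, small_session):
        table = small_session["lap_table"]
        counts = small_session["truth"]["lap_counts"]
        for cond, n in counts.items():
            assert len(table.select(condition=cond)) == n


class TestAnticipationZone:
    def _with_licks(self, first_lick_positions):
        s = _sawtooth_session(len(first_lick_positions))
        for i, p in enumerate(first_lick_positions):
            if p is None:
                continue
            lap = slice(i * 120, (i + 1) * 120)
            idx = i * 120 + np.argmin(np.abs(s.position[lap] - p))
            s.lick[idx] = True
        return s

    def test_constant_first_lick(self):
        s = self._with_licks([180.0] * 5)
        table = bhv.segment_laps(s)
        assert bhv.anticipation_zone(s, table) == pytest.approx(180.0, abs=1.0)

    def test_mean_of_alternating(self):
        s = self._with_licks([170.0, 190.0, 170.0, 190.0])
        table = bhv.segment_laps(s)
        assert bhv.anticipation_zone(s, table) == pytest.approx(180.0, abs=1.0)

    def test_lickfree_laps_ignored(self):
        s = self._with_licks([180.0, None, 180.0])
        table = bhv.segment_laps(s)
        assert bhv.anticipation_zone(s, table) == pytest.approx(180.0, abs=1.0)

    def test_no_licks_raises(self):
        s = _sawtooth_session(3)
        table = bhv.segment_laps(s)
        with pytest.raises(ValueError, match="no licks"):
            bhv.anticipation_zone(s, table)


class TestLickStopRule:
    def _ur_session(self, lick_pattern):
        n = len(lick_pattern) + 2
        s = _sawtooth_session(n)
        s.condition[:2 * 120] = "R"
        s.condition[2 * 120:] = "UR"
        zone_frames = np.flatnonzero(s.position >= 180.0)
        # R laps lick, UR laps follow the pattern
        for lap in range(n):
            lap_frames = zone_frames[(zone_frames >= lap * 120)
                                     & (zone_frames < (lap + 1) * 120)]
            licking = lap < 2 or lick_pattern[lap - 2]
            if licking and lap_frames.size:
                s.lick[lap_frames[0]] = True
        return s

    @pytest.mark.parametrize("pattern,expected", [
        ([1, 1, 1, 0, 0, 0, 0, 0], 6),
        ([1, 0, 0, 1, 0, 0], 4),       # first run wins despite the lap-4 lick
        ([1, 1, 1, 1, 1, 1], bhv.NEVER),
    ])
    def test_first_occurrence_rule(self, pattern, expected):
        s = self._ur_session(pattern)
        table = bhv.segment_laps(s)
        zone = bhv.anticipation_zone(s, table)
        stop = bhv.detect_lick_stop_lap(s, table, zone)
        assert stop == expected
        for lap in table.select(condition="UR"):
            if expected == bhv.NEVER or lap.lap_index < expected:
                assert lap.re_label == bhv.RE_HIGH
            else:
                assert lap.re_label == bhv.RE_LOW

    def test_invariant_to_out_of_zone_licks(self):
        s = self._ur_session([1, 1, 0, 0, 0, 0])
        table = bhv.segment_laps(s)
        zone = bhv.anticipation_zone(s, table)
        baseline = bhv.detect_lick_stop_lap(s, table, zone)
        # heavy licking at the track start, outside the anticipation zone
        s.lick[s.position < 100.0] = True
        assert bhv.detect_lick_stop_lap(s, table, zone) == baseline == 5


class TestApproachRatio:
    def _ratio_for(self, mid, end):
        v = np.full(40, mid)
        v[35:] = end
        return bhv.approach_ratio(v)

    @pytest.mark.parametrize("mid,end,expected", [
        (30.0, 30.0, 1.0),
        (30.0, 24.0, 1.25),
        (30.0, 30.0 / 1.3, 1.3),
    ])
    def test_arithmetic(self, mid, end, expected):
        assert self._ratio_for(mid, end) == pytest.approx(expected)

    def test_zero_end_velocity_undefined(self):
        assert np.isnan(self._ratio_for(30.0, 0.0))


class TestEngagementClassification:
    def test_threshold_is_lower_bound(self, small_session):
        table = small_session["lap_table"]
        r = np.array([l.approach_ratio for l in table.select(condition="R")])
        threshold = r.mean() - 1.5 * r.std(ddof=1)
        for lap in table.select(condition="UR", re_label=bhv.RE_LOW):
            expected = bhv.ENGAGED if lap.approach_ratio >= threshold \
                else bhv.DISENGAGED
            assert lap.engagement == expected

    def test_scale_invariance(self, small_session):
        """Multiplying all velocities by a constant changes no label."""
        import copy

        s = small_session["session"]
        scaled = copy.deepcopy(s)
        scaled.velocity = scaled.velocity * 3.0
        table = bhv.segment_laps(scaled)
        zone = bhv.anticipation_zone(scaled, table)
        bhv.detect_lick_stop_lap(scaled, table, zone)
        bhv.classify_engagement_approach(table)
        orig = {(l.condition, l.lap_index): l.engagement
                for l in small_session["lap_table"]}
        for lap in table:
            assert lap.engagement == orig[(lap.condition, lap.lap_index)]

    def test_recovery_against_ground_truth(self, small_session):
        table = small_session["lap_table"]
        truth = {(d["condition"], d["lap"]): d["engaged"]
                 for d in small_session["truth"]["laps"]}
        laps = table.select(condition="UR", re_label=bhv.RE_LOW)
        agree = sum((l.engagement == bhv.ENGAGED) == truth[("UR", l.lap_index)]
                    for l in laps)
        assert agree / len(laps) >= 0.9


class TestPupilEngagement:
    def test_template_correlation_extremes(self):
        from placecode.simulate import SimConfig, generate_session

        cfg = SimConfig(n_cells=0, laps={"R": 8, "UR": 10}, with_pupil=True,
                        disengaged_fraction=0.5, pupil_noise_sd=0.005)
        session, truth = generate_session(cfg, seed=3)
        table = bhv.segment_laps(session)
        zone = bhv.anticipation_zone(session, table)
        bhv.detect_lick_stop_lap(session, table, zone)
        report = bhv.pupil_engagement(session, table)
        truth_by_lap = {(d["condition"], d["lap"]): d["engaged"]
                        for d in truth["laps"]}
        rows = [r for r in report["laps"] if r["condition"] == "UR"]
        agree = sum(
            (r["engagement"] == bhv.ENGAGED) == truth_by_lap[("UR", r["lap_index"])]
            for r in rows)
        assert agree / len(rows) >= 0.9

    def test_absent_pupil_channel_errors(self, small_session):
        with pytest.raises(ValueError, match="pupil"):
            bhv.pupil_engagement(small_session["session"],
                                 small_session["lap_table"])


class TestMatchedVelocityLaps:
    def test_range_inclusion(self):
        matched, slower = bhv.match_velocity_laps([6.0, 7.0, 8.0], [7.5, 20.0])
        assert matched.tolist() == [0]
        assert slower.tolist() == [1]

    def test_all_matched_empty_slower(self):
        matched, slower = bhv.match_velocity_laps([6, 8], [6.5, 7.0, 7.9])
        assert slower.size == 0

    def test_histogram_variant(self):
        matched, slower = bhv.match_velocity_laps(
            [6.2, 8.4], [6.5, 7.5], method="histogram", bin_width_s=1.0)
        # 7.5 falls in the empty 7-8 s bin
        assert matched.tolist() == [0]
        assert slower.tolist() == [1]


class TestRollingAverage:
    @pytest.mark.parametrize("series,window,expected_last", [
        ([0, 0, 3], 3, 1.0),
        ([5, 5, 5, 5], 3, 5.0),
        ([1, 2, 3], 1, 3.0),
    ])
    def test_trailing_mean(self, series, window, expected_last):
        out = bhv.rolling_average(series, window)
        assert out.shape == (len(series),)
        assert out[-1] == pytest.approx(expected_last)

    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(bhv.rolling_average([2.0] * 6, 3), 2.0)
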