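"""Place-field detection, parameters, fate ledger, density, reward cells."""

import numpy as np
import pytest

from placecode.session import BinningSpec
from placecode import placefields as pf
from placecode import behavior as bhv

SPEC = BinningSpec()


class TestFieldCom:
    def test_symmetric_bump_at_bin_center(self):
        m = np.zeros((3, 40))
        m[:, 18:23] = [1.0, 2.0, 4.0, 2.0, 1.0]
        com, _ = pf.field_com(m, (18, 22))
        assert com == pytest.approx(102.5)       # center of bin 20

    def test_two_bin_arithmetic(self):
        m = np.zeros((1, 40))
        m[0, 0], m[0, 1] = 1.0, 3.0
        com, _ = pf.field_com(m, (0, 1))
        assert com == pytest.approx(6.25)        # (2.5 + 22.5) / 4

    def test_single_bin_gives_center(self):
        m = np.zeros((2, 40))
        m[:, 7] = 1.0
        com, _ = pf.field_com(m, (7, 7))
        assert com == pytest.approx(SPEC.centers[7])

    def test_all_zero_flagged_nan(self):
        com, per_lap = pf.field_com(np.zeros((3, 40)), (5, 9))
        assert np.isnan(com)
        assert np.isnan(per_lap).all()

    def test_translation_shifts_com_by_bin_width(self):
        m = np.zeros((2, 40))
        m[:, 10:15] = [1.0, 2.0, 3.0, 2.0, 1.0]
        com1, _ = pf.field_com(m, (10, 14))
        com2, _ = pf.field_com(np.roll(m, 1, axis=1), (11, 15))
        assert com2 - com1 == pytest.approx(SPEC.bin_width)


class TestReliability:
    def test_identical_laps_every_lap_hit(self):
        m = np.zeros((5, 40))
        m[:, 10:14] = 0.5
        assert pf.field_reliability(m, (10, 13), hit_fraction=1.0) == \
            pytest.approx(1.0)

    def test_half_lap_hits_gives_half(self):
        """Identical firing on half the laps anchors the index at 0.5."""
        m = np.zeros((6, 40))
        m[::2, 10:14] = [0.2, 0.5, 0.5, 0.2]
        assert pf.field_reliability(m, (10, 13), hit_fraction=0.5) == \
            pytest.approx(0.5)

    def test_reliability_not_above_hit_fraction(self, rng):
        m = rng.random((8, 40))
        r = pf.field_reliability(m, (5, 12), hit_fraction=0.6)
        assert 0.0 <= r <= 0.6


class TestFieldParams:
    def test_zero_outside_gives_zero_ratio(self):
        m = np.zeros((2, 40))
        m[:, 10:15] = 0.4
        out_in, width, intensity = pf.field_params(m, (10, 14), False)
        assert out_in == 0.0
        assert width == 25.0
        assert intensity == pytest.approx(0.4)

    def test_uniform_activity_ratio_one(self):
        m = np.full((2, 40), 0.3)
        out_in, _, _ = pf.field_params(m, (10, 14), False)
        assert out_in == pytest.approx(1.0)

    def test_intensity_is_peak_of_mean(self):
        m = np.zeros((2, 40))
        m[0, 12], m[1, 12] = 0.3, 0.42
        _, _, intensity = pf.field_params(m, (11, 13), False)
        assert intensity == pytest.approx(0.36)


class TestCandidates:
    def test_single_bump_single_candidate(self):
        curve = np.zeros(40)
        curve[10:17] = [0.1, 0.3, 0.5, 0.6, 0.5, 0.3, 0.1]
        cands = pf.candidate_fields(curve, rel_floor=0.0)
        assert cands == [(10, 16, False)]

    def test_two_bumps_treated_independently(self):
        curve = np.zeros(40)
        curve[5:9] = 0.5
        curve[25:30] = 0.4
        cands = pf.candidate_fields(curve, rel_floor=0.0)
        assert len(cands) == 2

    def test_flat_curve_no_candidates(self):
        assert pf.candidate_fields(np.zeros(40)) == []

    def test_run_touching_track_end_clipped(self):
        curve = np.zeros(40)
        curve[36:] = 0.5
        cands = pf.candidate_fields(curve, rel_floor=0.0)
        assert cands == [(36, 39, True)]


class TestTransients:
    def test_flat_trace_no_transients(self):
        assert pf.detect_transients(np.zeros(1000)) == []

    def test_single_event_found(self):
        t = np.arange(0, 3, 1 / 30)
        kernel = np.exp(-t / 0.5) - np.exp(-t / 0.05)
        trace = np.zeros(2000)
        trace[500:500 + kernel.size] = 0.5 * kernel / kernel.max()
        trace += np.random.default_rng(0).normal(0, 0.02, 2000)
        transients = pf.detect_transients(trace)
        assert len(transients) == 1
        a, b = transients[0]
        assert a <= 500 + np.argmax(kernel) <= b

    def test_event_recovery_on_synthetic_cell(self, small_session):
        """Most planted hit-laps show a detected in-field transient."""
        s = small_session["session"]
        truth = small_session["truth"]
        table = small_session["lap_table"]
        laps = {("R", l.lap_index): l for l in table.select(condition="R")}
        hits = misses = 0
        for rec in truth["cells"][:10]:
            if "R" not in rec["com"]:
                continue
            tmask = pf.transient_mask(s.dff[rec["cell"]], s.frame_rate)
            for h in rec["lap_hits"]:
                if h["condition"] != "R":
                    continue
                lap = laps[("R", h["lap"])]
                found = tmask[lap.start_frame:lap.end_frame].any()
                if h["hit"]:
                    hits += found
                    misses += not found
        assert hits / (hits + misses) >= 0.95


class TestCriteria:
    def _session_with_field(self):
        from placecode.simulate import SimConfig, generate_session

        cfg = SimConfig(n_cells=6, laps={"R": 20}, place_cell_fraction=1.0,
                        reward_overrep_weight=0.0)
        session, truth = generate_session(cfg, seed=12)
        table = bhv.segment_laps(session)
        return session, truth, table.select(condition="R")

    def test_boundary_width_10cm_rejected(self):
        """A 2-bin (10 cm) candidate fails criterion 1: width must exceed
        10 cm."""
        session, _, laps = self._session_with_field()
        rate_map = pf.bin_activity(session, laps, 0, SPEC)
        rate_map.matrix[:, :] = 0.0
        rate_map.matrix[:, 10:12] = 0.5
        tmask = np.ones(session.n_frames, dtype=bool)
        res = pf.apply_field_criteria((10, 11, False), rate_map, session,
                                      tmask, pf.FieldConfig(),
                                      np.random.default_rng(0))
        assert isinstance(res, pf.Rejection)
        assert res.criterion == 1

    def test_in_out_ratio_boundary(self):
        """In-field mean 0.4 vs out-field 0.11 is a 3.6x ratio: fails the
        >4x criterion."""
        session, _, laps = self._session_with_field()
        rate_map = pf.bin_activity(session, laps, 0, SPEC)
        rate_map.matrix[:, :] = 0.11
        rate_map.matrix[:, 10:14] = 0.4
        tmask = np.ones(session.n_frames, dtype=bool)
        res = pf.apply_field_criteria((10, 13, False), rate_map, session,
                                      tmask, pf.FieldConfig(),
                                      np.random.default_rng(0))
        assert isinstance(res, pf.Rejection)
        assert res.criterion == 3

    def test_detected_fields_satisfy_all_criteria(self, small_session):
        s = small_session["session"]
        laps = small_session["lap_table"].select(condition="R")
        fields, rejections = pf.detect_place_fields(
            s, laps, rng=np.random.default_rng(1), return_rejections=True)
        config = pf.FieldConfig()
        for flds in fields.values():
            for f in flds:
                assert f.width > config.min_width_cm or f.clipped
                assert f.p_boot < config.p_threshold
                assert f.lap_hit_fraction > config.min_lap_fraction
                assert 0.0 <= f.reliability <= f.lap_hit_fraction + 1e-12
                assert f.start_bin * 5.0 <= f.com <= (f.end_bin + 1) * 5.0
        for r in rejections:
            assert r.criterion in (1, 2, 3, 4, 5, 6)


class TestBootstrap:
    def test_coherent_field_low_p(self, rng):
        m = np.full((20, 40), 0.02)
        m[:, 10:14] = 0.6
        assert pf.bootstrap_pvalue(m, (10, 13), 1000, rng) <= 0.01

    def test_uniform_rows_not_significant(self, rng):
        m = rng.random((20, 40)) * 0.1 + 0.2
        p = pf.bootstrap_pvalue(m, (10, 13), 500, rng)
        assert p > 0.05

    def test_add_one_estimator_upper_bound(self, rng):
        """When the observed statistic is weakest, p reaches 1 exactly."""
        m = np.full((10, 40), 0.3)
        m[:, 10:14] = 0.0      # in-field mean below every shuffle
        p = pf.bootstrap_pvalue(m, (10, 13), 200, rng)
        assert p == 1.0


class TestFateLedger:
    def _field(self, cell, cond, start, end):
        return pf.PlaceField(cell, cond, start, end, False,
                             com=(start + end + 1) * 2.5, width=(end - start + 1) * 5.0,
                             reliability=0.5, out_in_ratio=0.1, intensity=0.3,
                             p_boot=0.01, lap_hit_fraction=0.6)

    def test_overlap_is_stable(self):
        fbc = {"R": {0: [self._field(0, "R", 10, 15)]},
               "RE_LOW": {0: [self._field(0, "RE_LOW", 14, 20)]}}
        fate = pf.classify_fate(fbc)
        assert fate["records"][0]["fate_relow"] == "stable"

    def test_disjoint_is_remapped(self):
        fbc = {"R": {0: [self._field(0, "R", 30, 35)]},
               "RE_LOW": {0: [self._field(0, "RE_LOW", 2, 6)]}}
        fate = pf.classify_fate(fbc)
        assert fate["records"][0]["fate_relow"] == "remapped"
        # the non-overlapping RE_low field is newly formed
        assert len(fate["new_relow"]) == 1

    def test_no_field_is_disappeared(self):
        fbc = {"R": {0: [self._field(0, "R", 30, 35)]}, "RE_LOW": {0: []}}
        fate = pf.classify_fate(fbc)
        assert fate["records"][0]["fate_relow"] == "disappeared"

    def test_fates_partition_r_fields(self, small_session):
        s = small_session["session"]
        table = small_session["lap_table"]
        rng = np.random.default_rng(2)
        fbc = {}
        for key in ("R", "RE_LOW", "RR"):
            if key == "RE_LOW":
                laps = table.select(condition="UR", re_label=bhv.RE_LOW,
                                    engagement=bhv.ENGAGED)
            else:
                laps = table.select(condition=key)
            fbc[key] = pf.detect_place_fields(s, laps, rng=rng)
        fate = pf.classify_fate(fbc)
        c = fate["counts"]
        assert c["stable"] + c["disappear"] + c["remap"] == c["r_total"]

    def test_printed_count_arithmetic(self):
        """169 of 605 fields stable throughout gives 27.9%."""
        assert pf.round1(100.0 * 169 / 605) == 27.9


class TestFieldDensity:
    def test_all_coms_at_end_extreme_delta(self):
        d = pf.field_density([175.0] * 30)
        assert d["overrep_delta"] == pytest.approx(100.0)

    def test_uniform_coms_near_zero_delta(self, rng):
        coms = rng.uniform(0, 200, 600)
        d = pf.field_density(coms)
        assert abs(d["overrep_delta"]) < 3.0
        assert d["ks_p"] > 0.01

    def test_too_few_coms_errors(self):
        with pytest.raises(ValueError, match="at least 20"):
            pf.field_density([100.0] * 5)


class TestRewardCells:
    def _rewarded_sessions(self):
        from placecode.simulate import SimConfig, generate_session

        reward_cells = {0}
        sessions = []
        for env_seed, cond in ((21, "R"), (22, "N")):
            cfg = SimConfig(n_cells=5, laps={cond: 12}, place_cell_fraction=0.0,
                            noise_sd=0.02, out_of_field_rate_hz=0.0)
            session, _ = generate_session(cfg, seed=env_seed)
            # plant a reward cell: transient at every reward delivery
            t = np.arange(0, 2, 1 / 30)
            kernel = (np.exp(-t / 0.5) - np.exp(-t / 0.05))
            kernel = 0.6 * kernel / kernel.max()
            for r in np.flatnonzero(session.reward):
                lo = max(0, r - 5)
                end = min(session.n_frames, lo + kernel.size)
                session.dff[0, lo:end] += kernel[: end - lo]
            sessions.append(session)
        s_r, s_n = sessions
        return s_r, s_n, reward_cells

    def test_planted_reward_cell_found(self):
        s_r, s_n, planted = self._rewarded_sessions()
        laps_r = bhv.segment_laps(s_r).select(condition="R")
        laps_n = bhv.segment_laps(s_n).select(condition="N")
        res = pf.identify_reward_cells(s_r, s_n, laps_r, laps_n)
        assert set(res["cells"]) == planted
        assert abs(res["profiles"][0]["time_com_s"]) <= 1.0

    def test_cell_firing_in_one_environment_only_excluded(self):
        s_r, s_n, _ = self._rewarded_sessions()
        s_n.dff[0] = 0.0        # silence the cell in the novel environment
        laps_r = bhv.segment_laps(s_r).select(condition="R")
        laps_n = bhv.segment_laps(s_n).select(condition="N")
        res = pf.identify_reward_cells(s_r, s_n, laps_r, laps_n)
        assert res["cells"] == []


class TestSummaryArithmetic:
    def test_percentages_reproducible_from_counts(self):
        counts = {"r_total": 605, "stable": 222, "disappear": 249,
                  "remap": 134, "relow_total": 663, "new_relow": 296,
                  "rr_total": 674, "new_rr": 140, "rr_stable": 311,
                  "rr_remap": 89, "stable_throughout": 169,
                  "reappear_rr": 126, "new_relow_stable_rr": 64,
                  "new_relow_gone_rr": 204}
        out = pf.summarize_fates(counts)
        assert out["stable_pct"] == 36.7
        assert out["disappear_pct"] == 41.2
        assert out["remap_pct"] == 22.1
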