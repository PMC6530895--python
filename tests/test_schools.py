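"""Candidate extraction, linking, morphology, minima and beam corrections."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import echoprey as ep
from echoprey._utils import FLOOR_DB
from echoprey.schools import CandidateRegion, school_metrics


def _blank_echogram(n_pings=100, n_bins=236, cell_w=0.25, max_range=35.0):
    z = np.linspace(0.0, max_range, n_bins)
    intensity = np.full((n_pings, n_bins), FLOOR_DB)
    return ep.Echogram(intensity, z, np.arange(n_pings) * cell_w)


def _full_domain(eg):
    mask = np.ones_like(eg.intensity, dtype=bool)
    return ep.AnalysisDomain(3.0, np.full(eg.n_pings, eg.depth_axis[-1]),
                             0.0, mask)


def _paint(eg, ping_slice, bin_slice, value=-20.0):
    eg.intensity[ping_slice, bin_slice] = value


class TestDetectCandidates:
    params = ep.ShapesParams()

    def test_single_block_gives_one_candidate(self):
        eg = _blank_echogram()
        _paint(eg, slice(10, 30), slice(50, 70))
        cands = ep.detect_candidates(eg, _full_domain(eg), self.params)
        assert len(cands) == 1

    def test_all_floor_gives_none(self):
        eg = _blank_echogram()
        assert ep.detect_candidates(eg, _full_domain(eg), self.params) == []

    def test_two_separated_blocks_stay_separate(self):
        eg = _blank_echogram()
        _paint(eg, slice(10, 20), slice(50, 60))
        _paint(eg, slice(60, 70), slice(120, 130))
        cands = ep.detect_candidates(eg, _full_domain(eg), self.params)
        assert len(cands) == 2

    def test_diagonal_touch_does_not_connect(self):
        # 4-connectivity: corner-touching blocks are distinct candidates
        eg = _blank_echogram()
        _paint(eg, slice(10, 20), slice(50, 60))
        _paint(eg, slice(20, 30), slice(60, 70))
        cands = ep.detect_candidates(eg, _full_domain(eg), self.params)
        assert len(cands) == 2

    def test_domain_mask_excludes_samples(self):
        eg = _blank_echogram()
        _paint(eg, slice(10, 30), slice(50, 70))
        dom = _full_domain(eg)
        dom.mask[:] = False
        assert ep.detect_candidates(eg, dom, self.params) == []


class TestLinkCandidates:
    def _cand(self, p0, p1, b0, b1):
        cells = np.array([(p, b) for p in range(p0, p1 + 1)
                          for b in range(b0, b1 + 1)])
        return CandidateRegion(cells)

    def test_two_candidates_within_gap_merge(self):
        # two 4 m blocks, 2 m apart (cells 0.25 m): one school, L ~ 10 m
        params = ep.ShapesParams(max_horizontal_link_m=5.0,
                                 max_vertical_link_m=2.0)
        a = self._cand(0, 15, 50, 55)     # 4 m
        b = self._cand(24, 39, 50, 55)    # gap of 8 pings = 2 m
        merged = ep.link_candidates([a, b], params, cell_width_m=0.25,
                                    cell_height_m=0.15)
        assert len(merged) == 1
        p0, p1 = merged[0].ping_span
        assert (p1 - p0 + 1) * 0.25 == pytest.approx(10.0)

    def test_gap_beyond_link_distance_not_merged(self):
        params = ep.ShapesParams(max_horizontal_link_m=1.0)
        a = self._cand(0, 15, 50, 55)
        b = self._cand(24, 39, 50, 55)
        merged = ep.link_candidates([a, b], params, cell_width_m=0.25,
                                    cell_height_m=0.15)
        assert len(merged) == 2

    def test_chain_merges_transitively(self):
        params = ep.ShapesParams(max_horizontal_link_m=2.0,
                                 max_vertical_link_m=1.0)
        a = self._cand(0, 4, 50, 55)
        b = self._cand(10, 14, 50, 55)   # within 2 m of a and c
        c = self._cand(20, 24, 50, 55)   # a-c gap is 15 cells = 3.75 m
        merged = ep.link_candidates([a, b, c], params, cell_width_m=0.25,
                                    cell_height_m=0.15)
        assert len(merged) == 1

    def test_result_invariant_to_input_order(self):
        params = ep.ShapesParams()
        cands = [self._cand(0, 4, 50, 55), self._cand(10, 14, 52, 57),
                 self._cand(60, 70, 100, 110)]
        m1 = ep.link_candidates(cands, params, cell_width_m=0.25,
                                cell_height_m=0.15)
        m2 = ep.link_candidates(cands[::-1], params, cell_width_m=0.25,
                                cell_height_m=0.15)
        spans1 = [(c.ping_span, c.bin_span) for c in m1]
        spans2 = [(c.ping_span, c.bin_span) for c in m2]
        assert spans1 == spans2


class TestSchoolMetrics:
    def test_rectangle_arithmetic(self):
        # 20 cells along-track x 20 bins vertical, 0.30 x 0.15 m cells
        eg = _blank_echogram(n_pings=40, cell_w=0.30)
        cells = np.array([(p, b) for p in range(10, 30)
                          for b in range(60, 80)])
        L, T, A, D, I = school_metrics(CandidateRegion(cells), eg)
        assert L == pytest.approx(20 * 0.30)
        assert T == pytest.approx(20 * eg.cell_height_m)
        assert A == pytest.approx(400 * 0.30 * eg.cell_height_m)

    def test_constant_field_mean_intensity(self):
        eg = _blank_echogram()
        _paint(eg, slice(10, 20), slice(50, 60), value=-25.0)
        cells = np.array([(p, b) for p in range(10, 20)
                          for b in range(50, 60)])
        _, _, _, _, mean_int = school_metrics(CandidateRegion(cells), eg)
        assert mean_int == pytest.approx(-25.0)

    def test_l_shape_area_below_bounding_box(self):
        eg = _blank_echogram()
        cells = np.array([(p, b) for p in range(10, 30)
                          for b in range(50, 55)]
                         + [(p, b) for p in range(10, 15)
                            for b in range(55, 70)])
        L, T, A, D, _ = school_metrics(CandidateRegion(cells), eg)
        assert A < L * T

    def test_depth_is_cell_weighted_mean(self):
        eg = _blank_echogram()
        cells = np.array([(10, 100), (10, 120)])
        _, _, _, D, _ = school_metrics(CandidateRegion(cells), eg)
        assert D == pytest.approx(
            0.5 * (eg.depth_axis[100] + eg.depth_axis[120]))


class TestFilterSchools:
    def _school(self, L, T):
        return ep.DetectedSchool(ping_span=(0, 1), depth_span=(5, 6),
                                 length_m=L, thickness_m=T, area_m2=L * T,
                                 mean_depth_m=5.0, mean_intensity_db=-20.0)

    def test_minimum_dimension_rule(self):
        schools = [self._school(6, 2.5), self._school(4, 2.5),
                   self._school(6, 1)]
        params = ep.ShapesParams(min_school_length_m=5.0,
                                 min_school_thickness_m=2.0)
        kept, dropped = ep.filter_schools(schools, params)
        assert len(kept) == 1 and dropped == 2
        assert kept[0].length_m == 6 and kept[0].thickness_m == 2.5

    def test_tiny_minima_keep_everything(self):
        schools = [self._school(6, 2.5), self._school(4, 2.5)]
        params = ep.ShapesParams(min_candidate_length_m=1e-6,
                                 min_candidate_thickness_m=1e-6,
                                 min_school_length_m=1e-6,
                                 min_school_thickness_m=1e-6)
        kept, dropped = ep.filter_schools(schools, params)
        assert len(kept) == 2 and dropped == 0

    def test_presets_match_study_settings(self):
        assert ep.SHAPES_PRESETS["ground_truth"].min_school_length_m == 3.0
        assert ep.SHAPES_PRESETS["ground_truth"].min_school_thickness_m == 1.5
        assert ep.SHAPES_PRESETS["survey_results"].min_school_length_m == 5.0
        assert ep.SHAPES_PRESETS["survey_results"].min_school_thickness_m == 2.0
        assert ep.SHAPES_PRESETS["survey_methods"].min_school_thickness_m == 3.0


class TestBeamCorrect:
    def test_length_correction_oracle(self):
        lc, tc, ac, valid = ep.beam_correct(20.0, 3.0, 40.0, 10.0,
                                            beam_angle_deg=12.0,
                                            sound_speed_ms=1500.0,
                                            pulse_width_ms=0.2)
        assert lc == pytest.approx(20 - 2 * 10 * math.tan(math.radians(6)),
                                   abs=1e-9)
        assert lc == pytest.approx(17.898, abs=1e-3)
        assert tc == pytest.approx(2.85, abs=1e-12)
        assert ac == pytest.approx(40 * lc * tc / 60.0, abs=1e-9)
        assert ac == pytest.approx(34.0, abs=0.01)
        assert valid

    def test_identity_limit(self):
        lc, tc, ac, valid = ep.beam_correct(20.0, 3.0, 40.0, 0.0,
                                            pulse_width_ms=0.0)
        assert (lc, tc, ac) == (20.0, 3.0, 40.0) and valid

    def test_nonpositive_corrections_flagged_invalid(self):
        # deep narrow school: beam wider than the school
        lc, tc, ac, valid = ep.beam_correct(2.0, 3.0, 5.0, 30.0)
        assert lc <= 0 and not valid
        lc, tc, ac, valid = ep.beam_correct(20.0, 0.1, 1.0, 5.0)
        assert tc <= 0 and not valid

    def test_zero_extent_is_invalid(self):
        *_, valid = ep.beam_correct(0.0, 0.0, 0.0, 5.0)
        assert not valid

    @settings(deadline=None, max_examples=100)
    @given(
        L=st.floats(1.0, 100.0), T=st.floats(0.5, 15.0),
        frac=st.floats(0.1, 1.0), D=st.floats(0.0, 30.0),
        phi=st.floats(1.0, 25.0), C=st.floats(1400.0, 1600.0),
        tau=st.floats(0.05, 1.0))
    def test_randomized_grid_matches_trigonometric_oracle(
            self, L, T, frac, D, phi, C, tau):
        A = frac * L * T
        lc, tc, ac, valid = ep.beam_correct(L, T, A, D, phi, C, tau)
        lc_ref = L - 2.0 * D * math.tan(math.radians(phi) / 2.0)
        tc_ref = T - C * tau / 2000.0
        assert lc == pytest.approx(lc_ref, abs=1e-9)
        assert tc == pytest.approx(tc_ref, abs=1e-9)
        if valid:
            assert ac == pytest.approx(A * lc_ref * tc_ref / (L * T),
                                       abs=1e-9)
            assert 0 < ac / A <= 1.0 + 1e-12
        else:
            assert lc_ref <= 0 or tc_ref <= 0

    def test_lc_strictly_decreasing_in_depth(self):
        depths = np.linspace(0, 20, 10)
        lcs = [ep.beam_correct(20.0, 3.0, 40.0, d)[0] for d in depths]
        assert np.all(np.diff(lcs) < 0)

    def test_tc_independent_of_depth(self):
        tcs = {ep.beam_correct(20.0, 3.0, 40.0, d)[1]
               for d in (0.0, 5.0, 25.0)}
        assert len(tcs) == 1


class TestEndToEndRecovery:
    def test_each_planted_school_recovered_once(self, gt_pipeline,
                                                gt_schools):
        schools, _ = gt_schools
        scene = gt_pipeline["scene"]
        eg = gt_pipeline["cleaned"]
        assert len(schools) == len(scene.schools)
        cw, chh = eg.cell_width_m, eg.cell_height_m
        phi = math.radians(eg.meta["beam_angle_deg"])
        matched = set()
        for true in scene.schools:
            center_x = true.center_ping * scene.cell_along_m
            hits = [i for i, s in enumerate(schools)
                    if abs(0.5 * sum(s.along_track_span_m) - center_x)
                    < true.length_m]
            assert len(hits) == 1
            i = hits[0]
            assert i not in matched
            matched.add(i)
            s = schools[i]
            smear = 2 * s.mean_depth_m * math.tan(phi / 2)
            assert abs(s.length_m - true.length_m) <= 2 * cw + smear
            assert abs(s.thickness_m - true.thickness_m) <= 2 * chh + 1e-9
            assert abs(s.mean_depth_m - true.center_depth_m) <= 3 * chh

    def test_lowering_threshold_never_shrinks_area(self, gt_pipeline):
        areas = {}
        for thr in (-40.0, -37.0, -35.0, -33.0, -30.0):
            params = ep.ShapesParams(threshold_db=thr)
            schools, _ = ep.detect_schools(gt_pipeline["cleaned"],
                                           gt_pipeline["domain"], params)
            areas[thr] = sum(s.area_m2 for s in schools)
        thresholds = sorted(areas)
        vals = [areas[t] for t in thresholds]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_mean_intensity_matches_planted_cores(self, gt_pipeline,
                                                  gt_schools):
        schools, _ = gt_schools
        cores = sorted(s.core_intensity_db
                       for s in gt_pipeline["scene"].schools)
        measured = sorted(s.mean_intensity_db for s in schools)
        for c, m in zip(cores, measured):
            assert abs(m - c) < 1.5  # edge cells and quantization
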