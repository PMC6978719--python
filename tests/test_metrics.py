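import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icas_hemoflow import (
    FivePoints,
    classify_extremum_location,
    coarse_label,
    detect_lesion_extent,
    exclusion_filter,
    extract_indices,
    locate_five_points,
    sample_cohort,
)
from icas_hemoflow.errors import InputError, InvalidGeometryError
from icas_hemoflow.solver.wall import WallProfile


def flat_profile(n=101, length=0.05, wss=2.0, pressure=12000.0):
    s = np.linspace(0.0, length, n)
    return WallProfile(arc_length=s, wss=np.full(n, float(wss)),
                       wall_pressure=np.full(n, float(pressure)),
                       side_label="wall", axial_positions=s.copy())


POINTS = FivePoints(0.01, 0.015, 0.02, 0.025, 0.03)


class TestFivePoints:
    def test_symmetric_extent_gives_arc_midpoints(self):
        prof = flat_profile()
        pts = locate_five_points(prof, (0.01, 0.02, 0.03))
        assert pts.s_m_up == pytest.approx(0.015)
        assert pts.s_m_down == pytest.approx(0.025)
        assert (pts.s_apex - pts.s_origin) == pytest.approx(
            pts.s_terminal - pts.s_apex)

    def test_asymmetric_extent_midpoints(self):
        prof = flat_profile(length=0.05)
        pts = locate_five_points(prof, (0.01, 0.016, 0.02))
        assert pts.s_m_up == pytest.approx(0.013)
        assert pts.s_m_down == pytest.approx(0.018)

    def test_degenerate_extent_rejected(self):
        prof = flat_profile()
        with pytest.raises(InvalidGeometryError):
            locate_five_points(prof, (0.02, 0.02, 0.03))

    def test_extent_outside_profile_rejected(self):
        prof = flat_profile(length=0.05)
        with pytest.raises(InputError):
            locate_five_points(prof, (0.01, 0.03, 0.06))


class TestClassification:
    @pytest.mark.parametrize("s, label", [
        (0.02, "Apex"),
        (0.0175, "Mup-to-apex"),
        (0.03, "Terminal"),
        (0.01, "Origin"),
        (0.0125, "Origin-to-Mup"),
        (0.0275, "Mdown-to-terminal"),
    ])
    def test_named_points_and_sections(self, s, label):
        assert classify_extremum_location(s, POINTS) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            classify_extremum_location(0.005, POINTS)

    @given(st.floats(min_value=0.01, max_value=0.03))
    @settings(max_examples=100, deadline=None)
    def test_total_on_lesion(self, s):
        label = classify_extremum_location(s, POINTS)
        assert coarse_label(label) in {
            "Origin", "Origin-to-Mup", "Upstream", "Mup-to-apex", "Apex",
            "Downstream", "Mdown", "Terminal"}

    def test_tolerance_controls_point_snapping(self):
        near_apex = 0.02 + 0.0003   # 1.5% of the 0.02 lesion length
        assert classify_extremum_location(near_apex, POINTS, 0.02) == "Apex"
        assert classify_extremum_location(
            near_apex, POINTS, 0.001) == "Apex-to-Mdown"


class TestExtractIndices:
    def test_constant_profiles_give_unit_ratios_and_zero_drops(self):
        prof = flat_profile()
        idx = extract_indices(prof, POINTS)
        assert idx.wss_ratio_max_over_origin == pytest.approx(1.0)
        assert idx.wss_ratio_min_over_origin == pytest.approx(1.0)
        assert idx.pressure_ratio_terminal_over_origin == pytest.approx(1.0)
        assert idx.pressure_drop_total == pytest.approx(0.0)
        assert all(d == pytest.approx(0.0) for d in idx.segment_drops)
        # ties resolve to the most upstream position: the origin
        assert idx.wss_max.arc_position == pytest.approx(POINTS.s_origin)
        assert idx.pressure_min.arc_position == pytest.approx(
            POINTS.s_origin)

    def test_segment_drops_sum_to_total(self):
        rng = np.random.default_rng(4)
        prof = flat_profile()
        prof.wall_pressure = 12000.0 + np.cumsum(rng.normal(0, 5, len(
            prof.arc_length)))
        idx = extract_indices(prof, POINTS)
        assert sum(idx.segment_drops) == pytest.approx(
            idx.pressure_drop_total, rel=1e-10)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_extrema_match_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        prof = flat_profile(n=201)
        prof.wss = np.abs(1.0 + rng.normal(0, 0.5, 201))
        prof.wall_pressure = 12000 + rng.normal(0, 100, 201)
        idx = extract_indices(prof, POINTS)
        s = prof.arc_length
        inside = (s >= POINTS.s_origin) & (s <= POINTS.s_terminal)
        assert idx.wss_max.value == pytest.approx(prof.wss[inside].max())
        assert idx.wss_min.value == pytest.approx(prof.wss[inside].min())
        assert idx.pressure_max.value == pytest.approx(
            prof.wall_pressure[inside].max())
        i = np.flatnonzero(inside)[np.argmax(prof.wss[inside])]
        assert idx.wss_max.arc_position == pytest.approx(s[i])

    def test_zero_origin_wss_yields_nan_ratios_but_absolutes(self):
        prof = flat_profile()
        prof.wss[:] = 0.0
        idx = extract_indices(prof, POINTS)
        assert not idx.ratios_defined
        assert np.isnan(idx.wss_ratio_max_over_origin)
        assert idx.pressure_drop_total == pytest.approx(0.0)
        assert idx.wss_max.value == 0.0

    def test_solver_output_has_physical_index_signs(self, stenosed_case_50):
        geom, _, _, prof = stenosed_case_50
        extent = detect_lesion_extent(geom)
        pts = locate_five_points(prof, extent)
        idx = extract_indices(prof, pts)
        assert idx.pressure_ratio_terminal_over_origin < 1.0
        assert idx.wss_ratio_max_over_origin > 1.0
        assert idx.wss_max.label in ("Mup", "Mup-to-apex", "Apex",
                                     "Apex-to-Mdown", "Mdown")
        assert idx.pressure_max.label in ("Origin", "Origin-to-Mup", "Mup")


class TestExclusions:
    def test_rules(self):
        import dataclasses
        cases = sample_cohort(1, seed=0)
        base = dataclasses.replace(cases[0],
                                   distance_to_nearest_lesion=None,
                                   at_bifurcation=False)
        tandem_near = dataclasses.replace(base, case_id="t1",
                                          distance_to_nearest_lesion=0.019)
        tandem_far = dataclasses.replace(base, case_id="t2",
                                         distance_to_nearest_lesion=0.025)
        at_bif = dataclasses.replace(base, case_id="b1", at_bifurcation=True)
        retained, excluded = exclusion_filter(
            [base, tandem_near, tandem_far, at_bif])
        assert [c.case_id for c in retained] == [base.case_id, "t2"]
        reasons = {c.case_id: r for c, r in excluded}
        assert reasons == {"t1": "tandem", "b1": "bifurcation"}
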