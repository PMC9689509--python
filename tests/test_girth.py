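"""Triangulation-to-girth pipeline: reconstruction, closed-curve fitting,
selection rules and session measurement."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from girthvision.geometry import Point3DSet, project, rotation_about_axis
from girthvision.girth import (
    GirthResult,
    IncompleteGirdleError,
    MeasurementReport,
    fit_girth,
    mad,
    measure_session,
    reconstruct_line,
    select_measurement,
)
from girthvision.matching import MatchedPairList


def ellipse_perimeter(a, b):
    value, err = quad(lambda u: np.hypot(a * np.sin(u), b * np.cos(u)),
                      0, 2 * np.pi, limit=200)
    assert err < 1e-9
    return value


def circle_points(r=0.15, n=36, z=0.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([r * np.cos(th), r * np.sin(th), np.full(n, z)], axis=-1)


class TestReconstructLine:
    def exact_pairs(self, session, rig):
        """Matched pair lists built from exact ground-truth projections."""
        gt = session.ground_truth
        row0 = gt.corners_initial[list(gt.corner_rows).index(0.0)]
        out, truth = [], []
        for view in session.views:
            cols = gt.interior_cols_per_pair[view.pair_index]
            world = gt.corners_at(view.angle)[list(gt.corner_rows).index(0.0)][cols]
            pl = project(world, rig.stereo.left, rig.left_pose)
            pr = project(world, rig.stereo.right, rig.right_pose)
            order = np.argsort(pl[:, 0])
            out.append(MatchedPairList(pl[order], pr[np.argsort(pr[:, 0])],
                                       line_index=0, angle=view.angle))
            truth.append(row0[cols][order])
        return out, np.concatenate(truth)

    def test_exact_projections_reconstruct_ground_truth(
        self, clean_session, default_rig
    ):
        pairs, truth = self.exact_pairs(clean_session, default_rig)
        pts = reconstruct_line(
            pairs, default_rig.stereo,
            axis_point=default_rig.axis_point_left,
            axis_dir=default_rig.axis_dir_left,
        )
        # de-rotated points are expressed in the left-camera frame; map the
        # world-frame truth into it for comparison
        truth_cam = default_rig.left_pose.apply(truth)
        assert len(pts) == len(truth)
        assert np.abs(pts.points - truth_cam).max() < 1e-4

    def test_full_circle_coverage_after_merging(self, clean_session, default_rig):
        from girthvision.scene import azimuth_coverage_deg

        pairs, _ = self.exact_pairs(clean_session, default_rig)
        pts = reconstruct_line(
            pairs, default_rig.stereo,
            axis_point=default_rig.axis_point_left,
            axis_dir=default_rig.axis_dir_left,
        )
        cov = azimuth_coverage_deg(pts.points, default_rig.axis_point_left,
                                   default_rig.axis_dir_left)
        assert cov >= 300.0

    def test_merge_equals_union_of_subdivisions(self, clean_session, default_rig):
        pairs, _ = self.exact_pairs(clean_session, default_rig)
        whole = reconstruct_line(pairs, default_rig.stereo,
                                 axis_point=default_rig.axis_point_left,
                                 axis_dir=default_rig.axis_dir_left)
        parts = [
            reconstruct_line([p], default_rig.stereo,
                             axis_point=default_rig.axis_point_left,
                             axis_dir=default_rig.axis_dir_left)
            for p in pairs
        ]
        merged = Point3DSet.concatenate(parts)
        assert np.allclose(whole.points, merged.points, atol=1e-12)

    def test_empty_input_raises(self, default_rig):
        with pytest.raises(ValueError):
            reconstruct_line([], default_rig.stereo)


class TestFitGirth:
    def test_circle_circumference(self):
        got = fit_girth(circle_points())
        assert abs(got - 2 * np.pi * 15.0) < 0.05  # cm

    def test_ellipse_matches_quadrature_oracle(self):
        a, b = 0.16, 0.12
        th = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        pts = np.stack([a * np.cos(th), b * np.sin(th), np.zeros(36)], -1)
        truth = ellipse_perimeter(a, b) * 100
        assert abs(fit_girth(pts) - truth) / truth < 1e-3

    def test_density_refinement_is_stable(self):
        a, b = 0.14, 0.11
        vals = []
        for n in (24, 48, 96):
            th = np.linspace(0, 2 * np.pi, n, endpoint=False)
            pts = np.stack([a * np.cos(th), b * np.sin(th), np.zeros(n)], -1)
            vals.append(fit_girth(pts))
        assert abs(vals[1] - vals[0]) / vals[0] < 1e-3
        assert abs(vals[2] - vals[1]) / vals[1] < 1e-3

    def test_invariant_to_point_ordering(self):
        pts = circle_points(0.12, 30)
        rng = np.random.default_rng(0)
        shuffled = pts[rng.permutation(len(pts))]
        assert np.isclose(fit_girth(pts), fit_girth(shuffled), atol=1e-9)

    def test_invariant_to_rigid_motion_of_points_and_axis(self):
        pts = circle_points(0.13, 32)
        base = fit_girth(pts)
        R = rotation_about_axis(37.0, np.array([1.0, 2.0, 2.0]) / 3.0)
        t = np.array([0.4, -0.2, 1.3])
        moved = pts @ R.T + t
        got = fit_girth(moved, axis_point=t, axis_dir=R @ np.array([0, 0, 1.0]))
        assert abs(got - base) / base < 1e-3

    def test_noise_off_plane_points_still_fit(self):
        rng = np.random.default_rng(1)
        pts = circle_points(0.13, 32)
        pts[:, 2] += rng.normal(0, 0.002, 32)
        got = fit_girth(pts)
        assert abs(got - 2 * np.pi * 13) / (2 * np.pi * 13) < 0.01

    def test_insufficient_points_raise(self):
        with pytest.raises(IncompleteGirdleError):
            fit_girth(circle_points(n=5))

    def test_half_girdle_raises(self):
        th = np.linspace(0, np.pi, 18)
        pts = np.stack([0.1 * np.cos(th), 0.1 * np.sin(th), np.zeros(18)], -1)
        with pytest.raises(IncompleteGirdleError, match="incomplete girdle"):
            fit_girth(pts)


class TestSelectMeasurement:
    def test_stated_rules_on_reference_examples(self):
        assert select_measurement({-1: 95.1, 0: 96.0, 1: 94.7}, "bust") == 96.0
        assert select_measurement({-1: 82.9, 0: 83.4, 1: 83.1}, "waist") == 82.9

    @given(st.tuples(st.floats(40, 140), st.floats(40, 140), st.floats(40, 140)))
    def test_max_for_bust_hip_thigh_min_for_waist(self, triple):
        lines = dict(zip((-1, 0, 1), triple))
        for part in ("bust", "hip", "thigh"):
            assert select_measurement(lines, part) == max(triple)
        assert select_measurement(lines, "waist") == min(triple)

    def test_shifted_parts_use_the_two_step_line(self):
        assert select_measurement({2: 88.8}, "under-bust") == 88.8
        assert select_measurement({2: 51.2, 0: 60.0}, "mid-thigh") == 51.2
        with pytest.raises(ValueError, match="invalid line set"):
            select_measurement({0: 60.0}, "under-bust")

    def test_wrong_line_count_or_part_raises(self):
        with pytest.raises(ValueError, match="invalid line set"):
            select_measurement({0: 90.0}, "bust")
        with pytest.raises(ValueError):
            select_measurement({-1: 1, 0: 2, 1: 3}, "forearm")


class TestMad:
    def test_identical_series_is_zero(self):
        assert mad([3.0, 4.0], [3.0, 4.0]) == 0.0

    def test_reference_example(self):
        assert mad([1, 3], [2, 2]) == 1.0

    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=20),
        st.floats(-50, 50),
    )
    def test_symmetric_and_shift_invariant(self, xs, shift):
        ys = [x + 1.5 for x in xs]
        assert np.isclose(mad(xs, ys), mad(ys, xs))
        assert np.isclose(
            mad(xs, ys), mad([x + shift for x in xs], [y + shift for y in ys]),
            atol=1e-6,
        )

    def test_incompatible_series_raise(self):
        with pytest.raises(ValueError):
            mad([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            mad([], [])

    def test_report_carries_mad_and_error_rates(self):
        rep = MeasurementReport("waist", [80.0, 82.0], [81.0, 81.0])
        assert rep.mad_cm == 1.0
        assert np.allclose(rep.errors_cm, [-1.0, 1.0])
        assert np.allclose(rep.error_rates_pct, [-100 / 81, 100 / 81])


class TestMeasureSession:
    def test_noise_free_default_session_recovers_girth_within_one_percent(
        self, clean_session
    ):
        res = measure_session(clean_session)
        truth = clean_session.ground_truth.girth_m * 100
        assert res.ground_truth_cm == pytest.approx(truth)
        assert abs(res.selected_cm - truth) / truth < 0.01
        assert set(res.per_line_cm) == {-1, 0, 1}
        n = clean_session.ground_truth.n_cells
        assert all(c == n for c in res.per_line_counts.values())

    def test_selected_value_is_one_of_the_line_values(self, clean_session):
        res = measure_session(clean_session)
        assert res.selected_cm in res.per_line_cm.values()
        assert isinstance(res, GirthResult)

    def test_shifted_part_measures_the_dedicated_line(self, clean_session):
        res = measure_session(clean_session, body_part="under-bust")
        assert set(res.per_line_cm) == {2}
        truth = clean_session.ground_truth.girth_m * 100
        assert abs(res.selected_cm - truth) / truth < 0.01
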