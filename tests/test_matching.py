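"""Regional constraint, x-order correspondence, pixel step and the full
matching procedure."""

import logging

import numpy as np
import pytest
from hypothesis import given, strategies as st

from girthvision.corners import CornerSet
from girthvision.markers import MarkerCentroids
from girthvision.matching import (
    ConstraintError,
    CountMismatchError,
    MatchedPairList,
    ShiftOutOfBoundsError,
    nstep,
    order_and_match,
    regional_constrain,
    run_algorithm1,
    shift_baseline,
)


def corner_set(points, view="left"):
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return CornerSet(pts[:, 0], pts[:, 1], np.ones(len(pts)), view=view)


class TestRegionalConstrain:
    def test_keeps_exactly_the_strict_interior(self):
        out = regional_constrain(corner_set([(1, 1), (5, 5), (9, 9)]), (0, 0), (6, 6))
        assert set(zip(out.xs, out.ys)) == {(1, 1), (5, 5)}

    def test_swapping_marker_roles_changes_nothing(self):
        cs = corner_set([(1, 1), (5, 5), (9, 9)])
        a = regional_constrain(cs, (0, 0), (6, 6))
        b = regional_constrain(cs, (6, 6), (0, 0))
        assert np.array_equal(a.xy, b.xy)

    def test_boundary_corners_are_excluded(self):
        cs = corner_set([(2, 3), (0, 1), (4, 5)])
        with pytest.raises(ConstraintError):
            # (0,1) and (4,5) sit exactly on the rectangle edges
            regional_constrain(cs, (0, 1), (4, 5))

    @given(
        st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 100)),
            min_size=0, max_size=60,
        ),
        st.tuples(st.floats(0, 100), st.floats(0, 100)),
        st.tuples(st.floats(0, 100), st.floats(0, 100)),
    )
    def test_matches_brute_force_predicate(self, pts, red, cyan):
        if red[0] == cyan[0] or red[1] == cyan[1]:
            return
        expected = [
            p for p in pts
            if min(red[0], cyan[0]) < p[0] < max(red[0], cyan[0])
            and min(red[1], cyan[1]) < p[1] < max(red[1], cyan[1])
        ]
        cs = corner_set(pts) if pts else corner_set(np.empty((0, 2)))
        if len(expected) < 2:
            with pytest.raises(ConstraintError):
                regional_constrain(cs, red, cyan)
        else:
            out = regional_constrain(cs, red, cyan)
            assert sorted(zip(out.xs, out.ys)) == sorted(expected)

    def test_degenerate_centroids_raise(self):
        with pytest.raises(ValueError):
            regional_constrain(corner_set([(1, 1), (2, 2)]), (3, 0), (3, 5))


class TestOrderAndMatch:
    def test_sorts_each_view_by_x_then_pairs_in_order(self):
        left = corner_set([(2, 0), (1, 0), (3, 0)])
        right = corner_set([(11, 0), (13, 0), (12, 0)], view="right")
        pairs = order_and_match(left, right)
        assert np.allclose(pairs.left_xy[:, 0], [1, 2, 3])
        assert np.allclose(pairs.right_xy[:, 0], [11, 12, 13])

    def test_count_mismatch_raises_without_truncation(self):
        with pytest.raises(CountMismatchError):
            order_and_match(corner_set([(1, 0), (2, 0)]), corner_set([(1, 0)]))

    def test_x_ties_break_by_ascending_y(self):
        left = corner_set([(1, 5), (1, 2), (2, 0)])
        right = corner_set([(7, 1), (7, 4), (8, 0)], view="right")
        pairs = order_and_match(left, right)
        assert np.allclose(pairs.left_xy[0], [1, 2])
        assert np.allclose(pairs.left_xy[1], [1, 5])
        assert np.allclose(pairs.right_xy[0], [7, 1])

    def test_pair_list_invariants_enforced(self):
        with pytest.raises(ValueError):
            MatchedPairList([[2, 0], [1, 0]], [[1, 0], [2, 0]])
        with pytest.raises(CountMismatchError):
            MatchedPairList([[1, 0]], [[1, 0], [2, 0]])

    def test_matching_is_a_pure_function_of_the_sets(self):
        rng = np.random.default_rng(5)
        pts_l = rng.uniform(0, 50, size=(10, 2))
        pts_r = pts_l + [30, 0]
        for perm_seed in range(3):
            p = np.random.default_rng(perm_seed).permutation(10)
            pairs = order_and_match(corner_set(pts_l[p]), corner_set(pts_r[p]))
            base = order_and_match(corner_set(pts_l), corner_set(pts_r))
            assert np.allclose(pairs.left_xy, base.left_xy)
            assert np.allclose(pairs.right_xy, base.right_xy)


class TestNstep:
    def test_reference_distance_gives_25_pixels(self):
        assert nstep(2.4) == 25

    def test_polynomial_at_two_metres(self):
        # 7.02*4 - 45.18*2 + 93.43 = 31.15 -> 31
        assert nstep(2.0) == 31

    def test_strictly_decreasing_over_the_working_range(self):
        ds = np.linspace(0.05, 3.2, 200)
        a, b, c = 7.02, -45.18, 93.43
        vals = a * ds**2 + b * ds + c
        assert np.all(np.diff(vals) < 0)
        assert nstep(1.6) > nstep(2.0) > nstep(2.8)

    def test_outside_validity_range_warns_but_returns(self, caplog):
        with caplog.at_level(logging.WARNING, logger="girthvision.matching"):
            value = nstep(1.0)
        assert value == int(round(7.02 - 45.18 + 93.43))
        assert any("validity range" in r.message for r in caplog.records)

    def test_nonpositive_distance_raises(self):
        with pytest.raises(ValueError):
            nstep(0.0)


class TestShiftBaseline:
    def centroids(self):
        return MarkerCentroids((10, 100), (90, 126), (12, 101), (92, 127))

    def test_zero_offset_is_identity(self):
        c = self.centroids()
        s = shift_baseline(c, 0, 25)
        assert s.left_red == c.left_red and s.right_cyan == c.right_cyan

    def test_inverse_pair_restores_centroids(self):
        c = self.centroids()
        s = shift_baseline(shift_baseline(c, 1, 25), -1, 25)
        assert s.left_red == c.left_red and s.left_cyan == c.left_cyan

    def test_only_y_moves_by_offset_times_step(self):
        s = shift_baseline(self.centroids(), 2, 25)
        assert s.left_red == (10, 150)
        assert s.right_cyan == (92, 177)

    def test_leaving_the_image_raises(self):
        with pytest.raises(ShiftOutOfBoundsError):
            shift_baseline(self.centroids(), -5, 25, image_height=200)
        with pytest.raises(ShiftOutOfBoundsError):
            shift_baseline(self.centroids(), 3, 25, image_height=200)


class TestAlgorithm1OnRender:
    def test_pair_count_equals_ground_truth_and_zero_mismatches(
        self, clean_session, default_rig
    ):
        from girthvision.scene import count_mismatches

        gt = clean_session.ground_truth
        for view in clean_session.views[:2]:
            pairs = run_algorithm1(
                view.left_image, view.right_image,
                left_mask=view.left_mask, right_mask=view.right_mask,
                angle=view.angle,
            )
            expected = len(gt.interior_cols_per_pair[view.pair_index])
            assert len(pairs) == expected
            assert np.all(np.diff(pairs.left_xy[:, 0]) > 0)
            assert np.all(np.diff(pairs.right_xy[:, 0]) > 0)
            bad, total = count_mismatches(pairs, gt, default_rig)
            assert bad == 0 and total == expected

    def test_matched_pairs_lie_on_the_baseline_row(
        self, clean_session, default_rig
    ):
        from girthvision.scene import identify_corner

        view = clean_session.views[0]
        pairs = run_algorithm1(
            view.left_image, view.right_image,
            left_mask=view.left_mask, right_mask=view.right_mask,
            angle=view.angle,
        )
        for i in range(len(pairs)):
            ident = identify_corner(
                pairs.left_xy[i], clean_session.ground_truth, view.angle,
                default_rig.stereo.left, default_rig.left_pose,
            )
            assert ident is not None and ident[0] == 0.0

    def test_shifted_rectangle_captures_the_adjacent_row(
        self, clean_session, default_rig
    ):
        from girthvision.matching import extract_centroids
        from girthvision.scene import identify_corner

        view = clean_session.views[0]
        base = extract_centroids(view.left_image, view.right_image,
                                 left_mask=view.left_mask,
                                 right_mask=view.right_mask)
        shifted = shift_baseline(base, 1, nstep(2.4), image_height=480)
        pairs = run_algorithm1(
            view.left_image, view.right_image,
            left_mask=view.left_mask, right_mask=view.right_mask,
            centroids=shifted, angle=view.angle,
        )
        assert len(pairs) > 0
        for i in range(len(pairs)):
            ident = identify_corner(
                pairs.left_xy[i], clean_session.ground_truth, view.angle,
                default_rig.stereo.left, default_rig.left_pose,
            )
            # +1 step down the image is one checkerboard row below baseline
            assert ident is not None and ident[0] == 1.0
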