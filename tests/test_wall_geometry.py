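"""Wall contours, segmentation, tangent/normal bases, flow decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comflow.errors import (DegenerateGeometryError, InvalidContourError)
from comflow.flow_core import FlowField
from comflow.wall_geometry import (WallContour, decompose, polyline_tangent,
                                   segment_center, split_six, subdivide,
                                   tangent_normal)


class TestWallContour:
    def test_apex_must_be_interior(self):
        pts = np.column_stack([np.linspace(0, 20, 11), np.full(11, 5.0)])
        with pytest.raises(InvalidContourError):
            WallContour(pts, pts + [0, 3], apex_index=0, image_shape=(32, 32))

    def test_coincident_points_rejected(self):
        pts = np.column_stack([np.linspace(0, 20, 11), np.full(11, 5.0)])
        pts[4] = pts[3]
        with pytest.raises(InvalidContourError):
            WallContour(pts, pts + [0, 3], apex_index=5, image_shape=(32, 32))


class TestSplitSix:
    def test_six_segments_with_nonempty_rois(self, six_segments):
        assert len(six_segments) == 6
        assert all(s.roi_mask.any() for s in six_segments)

    def test_partition_tiles_wall_mask(self, six_segments, small_contour):
        wall = small_contour.wall_mask()
        union = np.zeros_like(wall)
        for s in six_segments:
            assert not (union & s.roi_mask).any()
            union |= s.roi_mask
        np.testing.assert_array_equal(union, wall)

    def test_arc_lengths_partition_total(self, six_segments, small_contour):
        arc = small_contour.arc_lengths()
        lens = [arc[s.endo_span[1]] - arc[s.endo_span[0]]
                for s in six_segments]
        assert sum(lens) == pytest.approx(arc[-1], rel=1e-9)

    def test_symmetric_contour_gives_mirror_symmetric_spans(
            self, six_segments, small_contour):
        arc = small_contour.arc_lengths()
        lens = [arc[s.endo_span[1]] - arc[s.endo_span[0]]
                for s in six_segments]
        spacing = np.linalg.norm(np.diff(small_contour.endo_points, axis=0),
                                 axis=1).max()
        # left-side span lengths mirror the right-side ones
        for a, b in zip(lens[:3], lens[:2:-1]):
            assert abs(a - b) <= 2 * spacing

    def test_degenerate_apex_rejected(self):
        pts = np.column_stack([np.linspace(0, 20, 11), np.full(11, 5.0)])
        pts[:, 1] += np.linspace(0, 1, 11)
        with pytest.raises(InvalidContourError):
            split_six(WallContour(pts, pts + [0, 3], apex_index=1,
                                  image_shape=(32, 32)))


class TestSubdivide:
    def test_twelve_segments(self, twelve_segments):
        assert len(twelve_segments) == 12
        labels = {s.label for s in twelve_segments}
        assert len(labels) == 12
        assert all(("upper" in s.label) or ("lower" in s.label)
                   for s in twelve_segments)

    def test_children_partition_parent_roi(self, six_segments,
                                           twelve_segments):
        for parent in six_segments:
            kids = [s for s in twelve_segments
                    if s.label.startswith(parent.label + "-")]
            assert len(kids) == 2
            union = kids[0].roi_mask | kids[1].roi_mask
            assert not (kids[0].roi_mask & kids[1].roi_mask).any()
            np.testing.assert_array_equal(union, parent.roi_mask)

    def test_child_arc_lengths_equal_within_sample_spacing(
            self, six_segments, twelve_segments, small_contour):
        arc = small_contour.arc_lengths()
        spacing = np.linalg.norm(np.diff(small_contour.endo_points, axis=0),
                                 axis=1).max()
        for parent in six_segments:
            kids = [s for s in twelve_segments
                    if s.label.startswith(parent.label + "-")]
            lens = [arc[s.endo_span[1]] - arc[s.endo_span[0]] for s in kids]
            assert abs(lens[0] - lens[1]) <= spacing


def _vertical_contour():
    """Straight vertical wall used for the collinear special cases."""
    endo = np.column_stack([np.linspace(2, 30, 15), np.full(15, 10.0)])
    endo[7, 1] = 10.0
    epi = endo + [0.0, -4.0]
    return WallContour(endo, epi, apex_index=7, image_shape=(40, 40))


class TestSegmentCenter:
    def test_straight_vertical_span_returns_chord_midpoint(self):
        c = _vertical_contour()
        center = segment_center((0, 14), c)
        np.testing.assert_allclose(center, [16.0, 10.0], atol=1e-12)

    def test_semicircular_span_matches_circle_geometry(self):
        # endo = upper-left quarter of a circle; the horizontal march from
        # the chord midpoint must land on the analytic circle point
        theta = np.linspace(np.pi, np.pi / 2, 40)
        R, cx, cy = 10.0, 20.0, 20.0
        endo = np.column_stack([cy + R * np.sin(theta),
                                cx + R * np.cos(theta)])
        epi = np.column_stack([cy + (R + 3) * np.sin(theta),
                               cx + (R + 3) * np.cos(theta)])
        c = WallContour(endo, epi, apex_index=20, image_shape=(40, 40))
        center = segment_center((0, 39), c)
        row = 0.5 * (endo[0, 0] + endo[-1, 0])
        expected_col = cx - np.sqrt(R * R - (row - cy) ** 2)
        assert center[0] == pytest.approx(row)
        assert center[1] == pytest.approx(expected_col, abs=0.02)

    def test_horizontal_span_falls_back_to_arc_midpoint(self):
        endo = np.column_stack([np.full(11, 5.0), np.linspace(2, 22, 11)])
        endo[5, 0] = 5.0
        epi = endo + [4.0, 0.0]
        c = WallContour(endo, epi, apex_index=5, image_shape=(32, 32))
        center = segment_center((0, 10), c)
        np.testing.assert_allclose(center, [5.0, 12.0], atol=1e-9)


class TestTangentNormal:
    def test_collinear_horizontal_points(self):
        t = polyline_tangent([5.0, 0.0], [5.0, 4.0], [5.0, 8.0])
        np.testing.assert_allclose(t, [0.0, 1.0], atol=1e-12)

    def test_circle_tangent_perpendicular_to_radius(self):
        ang = np.array([0.3, 0.4, 0.5])
        pts = np.column_stack([np.sin(ang), np.cos(ang)])
        t = polyline_tangent(pts[0], pts[1], pts[2])
        assert abs(np.dot(t, pts[1])) < 1e-6

    def test_coincident_vertices_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            polyline_tangent([1.0, 1.0], [1.0, 1.0], [2.0, 2.0])

    def test_segment_basis_is_orthonormal_and_inward(self, six_segments,
                                                     small_contour):
        for s in six_segments:
            assert np.linalg.norm(s.tangent) == pytest.approx(1.0)
            assert np.linalg.norm(s.normal) == pytest.approx(1.0)
            assert abs(np.dot(s.tangent, s.normal)) < 1e-12
            to_cavity = small_contour.cavity_centroid - s.center
            assert np.dot(s.normal, to_cavity) > 0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_random_triples_give_unit_orthogonal_basis(self, seed):
        r = np.random.default_rng(seed)
        pts = r.normal(size=(3, 2)) * 10
        if min(np.linalg.norm(pts[1] - pts[0]),
               np.linalg.norm(pts[2] - pts[1])) < 1e-3:
            return
        d1 = (pts[1] - pts[0]) / np.linalg.norm(pts[1] - pts[0])
        d2 = (pts[2] - pts[1]) / np.linalg.norm(pts[2] - pts[1])
        if np.linalg.norm(d1 + d2) < 1e-6:
            return
        t = polyline_tangent(*pts)
        n = np.array([-t[1], t[0]])
        assert np.linalg.norm(t) == pytest.approx(1.0)
        assert abs(np.dot(t, n)) < 1e-12


class TestDecompose:
    def test_flow_along_normal(self, six_segments):
        seg = six_segments[0]
        shape = seg.roi_mask.shape
        flow = FlowField(np.full(shape, seg.normal[1]),
                         np.full(shape, seg.normal[0]))
        radial, circ = decompose(flow, seg)
        np.testing.assert_allclose(radial, 1.0, atol=1e-12)
        np.testing.assert_allclose(circ, 0.0, atol=1e-12)

    def test_hand_computed_axis_aligned_case(self, six_segments):
        seg = six_segments[0]
        # force a known basis: tangent along +col, normal along +row
        seg2 = type(seg)(label="x", endo_span=seg.endo_span,
                         center=seg.center, tangent=np.array([0.0, 1.0]),
                         normal=np.array([1.0, 0.0]),
                         roi_mask=seg.roi_mask)
        flow = FlowField(np.ones(seg.roi_mask.shape),
                         np.ones(seg.roi_mask.shape))
        radial, circ = decompose(flow, seg2)
        np.testing.assert_allclose(radial, 1.0)
        np.testing.assert_allclose(circ, 1.0)

    @given(seed=st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_energy_conservation_and_invertibility(self, six_segments, seed):
        r = np.random.default_rng(seed)
        seg = six_segments[seed % 6]
        u = r.normal(size=seg.roi_mask.shape)
        v = r.normal(size=seg.roi_mask.shape)
        radial, circ = decompose(FlowField(u, v), seg)
        np.testing.assert_allclose(radial ** 2 + circ ** 2, u * u + v * v,
                                   atol=1e-12)
        # reconstruct: flow = radial * normal + circ * tangent
        ru = radial * seg.normal[1] + circ * seg.tangent[1]
        rv = radial * seg.normal[0] + circ * seg.tangent[0]
        np.testing.assert_allclose(ru, u, atol=1e-12)
        np.testing.assert_allclose(rv, v, atol=1e-12)
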