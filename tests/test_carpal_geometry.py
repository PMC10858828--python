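"""Geometry pipeline: outlines, centreline, joint widths, bounding boxes,
wrist angle — with analytic and brute-force oracles."""

import numpy as np
import pytest
from shapely.geometry import Polygon

import carpodyn as cd
from carpodyn import carpal_geometry as geom
from conftest import disk_mask, random_convex_polygon


def circle_polygon(cx, cy, r, n=96):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


def brute_force_segment_polygon_hits(p0, p1, poly):
    """Exhaustive segment-edge intersection oracle (O(edges))."""
    hits = []
    d = p1 - p0
    ring = np.vstack([poly, poly[:1]])
    for a, b in zip(ring[:-1], ring[1:]):
        e = b - a
        den = d[0] * (-e[1]) - d[1] * (-e[0])
        if abs(den) < 1e-14:
            continue
        rhs = a - p0
        t = (rhs[0] * (-e[1]) - rhs[1] * (-e[0])) / den
        u = (d[0] * rhs[1] - d[1] * rhs[0]) / den
        if -1e-12 <= t <= 1 + 1e-12 and -1e-12 <= u <= 1 + 1e-12:
            hits.append(p0 + t * d)
    return np.asarray(hits)


def brute_force_min_rect_area(points, step_deg=0.1):
    """Orientation sweep oracle for the minimal-area enclosing rectangle."""
    best = np.inf
    pts = np.asarray(points, dtype=float)
    for ang in np.arange(0.0, 90.0, step_deg):
        a = np.deg2rad(ang)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        q = pts @ rot.T
        ext = q.max(axis=0) - q.min(axis=0)
        best = min(best, ext[0] * ext[1])
    return best


class TestExtractOutline:
    def test_disk_perimeter_area_centroid(self):
        mask = disk_mask(radius_px=10, label=4)
        o = cd.extract_outline(mask, 4, spacing_mm=1.0)
        perim = Polygon(o.points).length
        assert perim == pytest.approx(2 * np.pi * 10, rel=0.03)
        assert Polygon(o.points).area == pytest.approx(np.pi * 100, rel=0.05)
        np.testing.assert_allclose(o.centroid, [32.0, 32.0], atol=0.1)

    def test_absent_bone_is_invalid(self):
        with pytest.raises(cd.InvalidOutlineError, match="absent"):
            cd.extract_outline(disk_mask(label=4), 7, spacing_mm=1.0)

    def test_tiny_component_is_invalid(self):
        m = np.zeros((16, 16), dtype=np.uint8)
        m[4, 4] = 3
        m[4, 5] = 3
        with pytest.raises(cd.InvalidOutlineError):
            cd.extract_outline(m, 3, spacing_mm=1.0)

    def test_largest_component_wins(self):
        m = disk_mask(radius_px=8, label=5)
        m[0:3, 0:3] = 5  # small spurious island
        o = cd.extract_outline(m, 5, spacing_mm=1.0)
        np.testing.assert_allclose(o.centroid, [32.0, 32.0], atol=0.3)

    def test_smoothing_changes_area_under_five_percent(self):
        mask = disk_mask(radius_px=10, label=4)
        smoothed = cd.extract_outline(mask, 4, spacing_mm=1.0)
        raw = cd.extract_outline(mask, 4, spacing_mm=1.0, smooth_span_px=0.0)
        assert abs(smoothed.area - raw.area) / raw.area < 0.05


class TestCentreline:
    def test_anchors_are_centroids_in_bone_order(self):
        outlines = {b: cd.BoneOutline(bone_id=b, points=circle_polygon(x, 0, 3))
                    for b, x in zip((3, 4, 5), (0.0, 10.0, 20.0))}
        c = cd.proximal_centreline(outlines[3], outlines[4], outlines[5])
        np.testing.assert_allclose(c.anchors[:, 0], [0, 10, 20], atol=1e-6)
        (s1a, s1b), (s2a, s2b) = c.segments
        np.testing.assert_allclose(s1b, s2a)

    def test_permutation_invariant(self):
        outlines = [cd.BoneOutline(bone_id=b, points=circle_polygon(x, x / 2, 3))
                    for b, x in zip((3, 4, 5), (0.0, 10.0, 20.0))]
        a = cd.proximal_centreline(*outlines)
        b = cd.proximal_centreline(outlines[2], outlines[0], outlines[1])
        np.testing.assert_allclose(a.anchors, b.anchors)

    def test_coincident_centroids_rejected(self):
        o1 = cd.BoneOutline(bone_id=3, points=circle_polygon(0, 0, 3))
        o2 = cd.BoneOutline(bone_id=4, points=circle_polygon(0, 0, 4))
        o3 = cd.BoneOutline(bone_id=5, points=circle_polygon(9, 0, 3))
        with pytest.raises(ValueError, match="distinct"):
            cd.proximal_centreline(o1, o2, o3)


class TestCortexIntersections:
    def test_two_circles_analytic(self):
        """Circles r=5 mm, centres 14 mm apart: cortex points at 5 mm from
        each centre, separation 4 mm."""
        a = circle_polygon(0, 0, 5)
        b = circle_polygon(14, 0, 5)
        pa, pb = cd.cortex_intersections((0, 0), (14, 0), a, b)
        np.testing.assert_allclose(pa, [5, 0], atol=1e-3)
        np.testing.assert_allclose(pb, [9, 0], atol=1e-3)
        oa = cd.BoneOutline(bone_id=3, points=a)
        ob = cd.BoneOutline(bone_id=4, points=b)
        w, ok = cd.joint_width(oa, ob)
        assert ok and w == pytest.approx(4.0, abs=1e-3)

    def test_overlapping_outlines_clamped_and_flagged(self):
        oa = cd.BoneOutline(bone_id=3, points=circle_polygon(0, 0, 5))
        ob = cd.BoneOutline(bone_id=4, points=circle_polygon(7, 0, 5))
        w, ok = cd.joint_width(oa, ob)
        assert w == 0.0 and not ok

    def test_matches_brute_force_on_random_convex_polygons(self, rng):
        for _ in range(30):
            a = random_convex_polygon(rng, center=(0.0, 0.0))
            b = random_convex_polygon(rng, center=(40.0, 5.0))
            ca = np.array(Polygon(a).centroid.coords[0])
            cb = np.array(Polygon(b).centroid.coords[0])
            pa, pb = cd.cortex_intersections(ca, cb, a, b)
            ha = brute_force_segment_polygon_hits(ca, cb, a)
            hb = brute_force_segment_polygon_hits(ca, cb, b)
            ea = ha[np.argmin(np.linalg.norm(ha - cb, axis=1))]
            eb = hb[np.argmin(np.linalg.norm(hb - ca, axis=1))]
            np.testing.assert_allclose(pa, ea, atol=1e-8)
            np.testing.assert_allclose(pb, eb, atol=1e-8)


class TestJointWidths:
    def test_phantom_widths_match_ground_truth(self, short_series):
        spec, _, masks, truth = short_series
        for i in (0, 10, 20):
            sl = cd.sl_joint_width(masks[i], spacing_mm=1.0)
            lt = cd.lt_joint_width(masks[i], spacing_mm=1.0)
            assert sl == pytest.approx(truth.true_gap_sl_mm[i], abs=0.5)
            assert lt == pytest.approx(truth.true_gap_lt_mm[i], abs=0.5)

    def test_lt_independent_of_scaphoid_pose(self, short_series):
        _, _, masks, _ = short_series
        m = masks[5].copy()
        lt_before = cd.lt_joint_width(m, spacing_mm=1.0)
        m2 = m.copy()
        m2[m2 == 3] = 0  # remove the scaphoid entirely
        assert cd.lt_joint_width(m2, spacing_mm=1.0) == pytest.approx(lt_before,
                                                                      abs=1e-9)

    def test_scale_covariance(self, short_series):
        _, _, masks, _ = short_series
        w1 = cd.sl_joint_width(masks[0], spacing_mm=1.0)
        w2 = cd.sl_joint_width(masks[0], spacing_mm=2.0)
        assert w2 == pytest.approx(2.0 * w1, rel=1e-9)

    def test_mirror_symmetry(self, short_series):
        _, _, masks, _ = short_series
        m = masks[3]
        mirrored = m[:, ::-1].copy()
        assert cd.sl_joint_width(mirrored, 1.0) == pytest.approx(
            cd.sl_joint_width(m, 1.0), abs=0.1)
        assert cd.lt_joint_width(mirrored, 1.0) == pytest.approx(
            cd.lt_joint_width(m, 1.0), abs=0.1)

    def test_rigid_invariance_in_continuous_coordinates(self, short_series):
        """Rotating + translating the extracted outlines leaves widths
        within 0.1 mm and the wrist angle within 0.2 deg."""
        _, _, masks, _ = short_series
        m = masks[7]
        s = cd.extract_outline(m, 3, 1.0)
        l = cd.extract_outline(m, 4, 1.0)
        w0, _ = cd.joint_width(s, l)
        ang = np.deg2rad(30.0)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        shift = np.array([13.0, -8.0])
        s2 = cd.BoneOutline(bone_id=3, points=s.points @ rot.T + shift)
        l2 = cd.BoneOutline(bone_id=4, points=l.points @ rot.T + shift)
        w1, _ = cd.joint_width(s2, l2)
        assert w1 == pytest.approx(w0, abs=0.1)

        distal = np.vstack([cd.extract_outline(m, b, 1.0).points for b in (6, 7, 8, 9)])
        radius = cd.extract_outline(m, 1, 1.0)
        ulna = cd.extract_outline(m, 2, 1.0)
        forearm = np.vstack([radius.points, ulna.points])
        ulnar = ulna.centroid - radius.centroid
        a0 = cd.wrist_angle_from_points(distal, forearm, ulnar)
        a1 = cd.wrist_angle_from_points(distal @ rot.T + shift,
                                        forearm @ rot.T + shift, ulnar @ rot.T)
        assert a1 == pytest.approx(a0, abs=0.2)


class TestMinBoundingBox:
    def test_axis_aligned_rectangle(self):
        corners = np.array([[0, 0], [4, 0], [4, 2], [0, 2], [2, 1]], dtype=float)
        box = cd.min_bounding_box(corners)
        assert box.extent == pytest.approx((4.0, 2.0))
        np.testing.assert_allclose(box.center, [2.0, 1.0], atol=1e-9)

    def test_rotated_rectangle_rigid_invariance(self):
        corners = np.array([[0, 0], [4, 0], [4, 2], [0, 2]], dtype=float)
        a = np.deg2rad(30)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        box = cd.min_bounding_box(corners @ rot.T)
        assert box.extent == pytest.approx((4.0, 2.0), abs=1e-9)
        axis_angle = np.degrees(np.arctan2(box.long_axis[1], box.long_axis[0]))
        assert axis_angle % 180 == pytest.approx(30.0, abs=1e-6)

    def test_matches_brute_force_orientation_sweep(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(20, 2)) * [7, 3]
            area = cd.min_bounding_box(pts).area
            oracle = brute_force_min_rect_area(pts)
            assert area <= oracle * 1.0001
            assert area == pytest.approx(oracle, rel=0.005)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cd.min_bounding_box(np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValueError, match="degenerate|collinear"):
            cd.min_bounding_box(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))


class TestWristAngle:
    def test_phantom_angle_recovery(self, short_series):
        spec, _, masks, truth = short_series
        for i in (0, 8, 16, 24):
            meas = cd.wrist_angle(masks[i], spacing_mm=1.0)
            assert meas == pytest.approx(truth.true_angle_deg[i], abs=2.0)

    def test_neutral_phantom_near_zero(self):
        spec = cd.make_phantom_spec("healthy", "right", seed=0)
        _, mask, _ = cd.render_frame(spec, 0.0)
        assert abs(cd.wrist_angle(mask, 1.0)) <= 1.0

    def test_ulnar_positive_both_sides(self):
        for side in ("left", "right"):
            spec = cd.make_phantom_spec("healthy", side, seed=0)
            _, mask, _ = cd.render_frame(spec, 12.0)
            assert cd.wrist_angle(mask, 1.0) > 8.0

    def test_missing_bones_invalid(self, short_series):
        _, _, masks, _ = short_series
        m = masks[0].copy()
        m[m == 7] = 0  # capitate gone
        with pytest.raises(cd.InvalidOutlineError):
            cd.wrist_angle(m, 1.0)


class TestMeasureSeries:
    def test_one_measurement_per_frame_and_flags(self, short_series):
        _, _, masks, truth = short_series
        broken = masks.copy()
        broken[4][broken[4] == 4] = 0  # lunate missing in one frame
        ms = cd.measure_series(broken, spacing_mm=1.0, frame_interval_s=0.095)
        assert len(ms) == len(masks)
        assert not ms[4].valid and np.isnan(ms[4].sl_width_mm)
        valid = [m for i, m in enumerate(ms) if i != 4]
        assert all(m.valid for m in valid)
        errs = [abs(m.sl_width_mm - truth.true_gap_sl_mm[m.frame_index])
                for m in valid]
        assert np.mean(np.array(errs) <= 0.5) >= 0.95

    def test_empty_stack(self):
        assert cd.measure_series([], spacing_mm=1.0) == []

    def test_tabulation_and_sweep_direction(self, short_series):
        _, _, masks, _ = short_series
        ms = cd.measure_series(masks[:20], spacing_mm=1.0, frame_interval_s=0.095)
        df = cd.measurements_to_frame(ms)
        assert list(df.columns) == ["frame", "t_s", "angle_deg", "sl_mm",
                                    "lt_mm", "valid", "sweep_direction"]
        # first half of the first cycle sweeps radial -> ulnar
        assert (df["sweep_direction"].iloc[2:18] == "radial_to_ulnar").all()
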