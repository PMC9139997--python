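import math

import numpy as np
import pytest
from PIL import Image, ImageDraw
from shapely.geometry import Polygon

from partmorph.skeleton_core import (
    CompositionError,
    GrowthParams,
    InvalidParameterError,
    MainBody,
    SkeletalPath,
    attach_part,
    build_silhouette,
    compose_shape,
    grow_path,
    make_main_body,
    smooth_path,
)
from partmorph.part_manipulation import curved_limb_params


class TestGrowPath:
    def test_zero_angle_range_is_collinear(self, rng):
        params = GrowthParams(
            n_joints=4, angle_range_deg=0.0, seg_length_range=(1.0, 1.0)
        )
        path = grow_path((0, 0), 90.0, params, rng)
        assert path.n_joints == 4
        np.testing.assert_allclose(path.joints[:, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(path.joints[:, 1], [0, 1, 2, 3], atol=1e-12)
        np.testing.assert_allclose(path.turning_angles_deg, 0.0, atol=1e-12)

    def test_joint_count_and_derived_shapes(self, rng):
        for n in (3, 4, 5):
            path = grow_path((0, 0), 0.0, GrowthParams(n_joints=n), rng)
            assert path.n_joints == n
            assert len(path.segment_lengths) == n - 1
            assert len(path.turning_angles_deg) == n - 2

    def test_determinism_and_seed_sensitivity(self):
        params = GrowthParams(n_joints=5)
        a = grow_path((0, 0), 30.0, params, np.random.default_rng(7))
        b = grow_path((0, 0), 30.0, params, np.random.default_rng(7))
        c = grow_path((0, 0), 30.0, params, np.random.default_rng(8))
        np.testing.assert_array_equal(a.joints, b.joints)
        assert np.abs(a.joints - c.joints).max() > 0

    def test_too_few_joints_rejected(self):
        with pytest.raises(InvalidParameterError):
            GrowthParams(n_joints=1)

    def test_turning_angles_bounded_by_range(self):
        """Every turning angle of 1000 random paths stays within ±range."""
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            r = float(rng.uniform(5, 120))
            params = GrowthParams(n_joints=int(rng.integers(3, 7)), angle_range_deg=r)
            path = grow_path((0, 0), float(rng.uniform(0, 360)), params, rng)
            assert np.all(np.abs(path.turning_angles_deg) <= r + 1e-9)

    def test_segment_lengths_within_range(self, rng):
        params = GrowthParams(n_joints=6, seg_length_range=(0.05, 0.07))
        path = grow_path((0, 0), 0.0, params, rng)
        assert np.all(path.segment_lengths >= 0.05 - 1e-12)
        assert np.all(path.segment_lengths <= 0.07 + 1e-12)


class TestSmoothPath:
    def test_collinear_stays_collinear(self, rng):
        params = GrowthParams(n_joints=5, angle_range_deg=0.0)
        path = grow_path((0, 0), 90.0, params, rng)
        dense = smooth_path(path, 16)
        assert np.abs(dense[:, 0]).max() < 1e-9

    def test_interpolates_joints_and_endpoints(self, rng):
        path = grow_path((0, 0), 45.0, GrowthParams(n_joints=4), rng)
        spp = 8
        dense = smooth_path(path, spp)
        assert dense.shape == ((path.n_joints - 1) * spp + 1, 2)
        np.testing.assert_array_equal(dense[0], path.joints[0])
        np.testing.assert_array_equal(dense[-1], path.joints[-1])
        for i in range(path.n_joints):
            np.testing.assert_allclose(dense[i * spp], path.joints[i], atol=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_arc_length_at_least_endpoint_distance(self, seed):
        """Numeric arc-length integration of the dense polyline bounds the chord."""
        rng = np.random.default_rng(seed)
        path = grow_path((0, 0), 0.0, GrowthParams(n_joints=5), rng)
        dense = smooth_path(path, 32)
        arc = np.hypot(*np.diff(dense, axis=0).T).sum()
        chord = np.hypot(*(dense[-1] - dense[0]))
        assert arc >= chord - 1e-12


class TestBuildSilhouette:
    def _straight_polyline(self, L, n=65):
        return np.stack([np.zeros(n), np.linspace(0, L, n)], axis=1)

    def test_stadium_bbox_and_area(self):
        L, w = 2.0, 0.3
        poly = build_silhouette(
            self._straight_polyline(L),
            GrowthParams(n_joints=3, width_profile=(1.0,), taper=1.0),
            width_scale=w,
        )
        minx, miny, maxx, maxy = poly.bounds
        assert maxx - minx == pytest.approx(w, rel=1e-6)
        assert maxy - miny == pytest.approx(L + w, rel=1e-6)
        analytic = w * L + math.pi * (w / 2) ** 2
        assert poly.area == pytest.approx(analytic, rel=0.01)
        perimeter = 2 * L + math.pi * w
        assert poly.length == pytest.approx(perimeter, rel=0.01)

    def test_zero_taper_gives_pointed_tip(self):
        L, w = 1.0, 0.2
        poly = build_silhouette(
            self._straight_polyline(L),
            GrowthParams(n_joints=3, width_profile=(1.0,), taper=0.0),
            width_scale=w,
        )
        # no end cap: the silhouette ends exactly at the path tip
        assert poly.bounds[3] == pytest.approx(L, abs=1e-9)

    def test_extreme_curvature_still_single_polygon(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            params = curved_limb_params(rng, width_profile=(1.4, 1.2), taper=0.5)
            path = grow_path((0, 0), 0.0, params, rng)
            dense = smooth_path(path, 12)
            poly = build_silhouette(dense, params, width_scale=0.08)
            assert poly.geom_type == "Polygon"
            assert poly.is_valid


class TestAttachAndCompose:
    def test_attach_orthogonal_to_vertical_flank(self, body):
        shape = compose_shape(body, [])
        params = GrowthParams(n_joints=3, angle_range_deg=0.0)
        rng = np.random.default_rng(0)
        shape = attach_part(shape, "body", 0.25, "left", params, rng)
        gj = shape.global_joints(0)
        first_dir = gj[1] - gj[0]
        first_dir /= np.hypot(*first_dir)
        # mid-flank tangent is near-vertical, so the limb starts near-horizontal
        assert abs(first_dir[0]) > 0.99
        assert gj[0][0] < 0  # rooted on the left flank

    def test_rel_length_contract(self, body):
        rng = np.random.default_rng(3)
        shape = compose_shape(body, [])
        shape = attach_part(
            shape, "body", 0.3, "left", GrowthParams(rel_length=0.5), rng
        )
        assert shape.parts[0].length == pytest.approx(
            0.5 * body.skeleton.length, abs=1e-6
        )

    def test_unknown_parent_rejected(self, body, rng):
        shape = compose_shape(body, [])
        with pytest.raises(KeyError):
            attach_part(shape, 99, 0.3, "left", GrowthParams(), rng)

    def test_empty_composition_is_identity(self, body):
        shape = compose_shape(body, [])
        assert shape.silhouette.equals(body.silhouette)
        assert shape.seg_points.shape == (0, 2)

    def test_one_seg_point_per_part(self, two_pair_shape):
        assert two_pair_shape.seg_points.shape == (two_pair_shape.n_parts, 2)

    def test_union_area_bounds_and_raster_oracle(self, two_pair_shape):
        """Union area agrees with a rasterised pixel-count union on a 1000² grid."""
        shape = two_pair_shape
        polys = [shape.body.silhouette] + [
            p for p in shape.part_polygons if p is not None
        ]
        areas = [p.area for p in polys]
        assert shape.silhouette.area <= sum(areas) + 1e-9
        assert shape.silhouette.area >= max(areas) - 1e-9

        n = 1000
        minx, miny, maxx, maxy = shape.silhouette.bounds
        span = max(maxx - minx, maxy - miny) * 1.02
        cx, cy = (minx + maxx) / 2, (miny + maxy) / 2
        img = Image.new("1", (n, n), 0)
        draw = ImageDraw.Draw(img)
        for poly in polys:
            pts = np.asarray(poly.exterior.coords)
            px = (pts - [cx, cy]) / span * n + n / 2
            draw.polygon([tuple(p) for p in px], fill=1)
        pixel_area = np.asarray(img).sum() * (span / n) ** 2
        assert pixel_area == pytest.approx(shape.silhouette.area, rel=0.01)


class TestPerimeterPoint:
    def test_wraparound_identity(self, body):
        p0, t0 = body.perimeter_point(0.0)
        p1, t1 = body.perimeter_point(1.0)
        np.testing.assert_allclose(p0, p1, atol=1e-12)
        np.testing.assert_allclose(t0, t1, atol=1e-12)

    def test_circle_diametric_opposition(self):
        angles = np.linspace(0, 2 * np.pi, 721)[:-1]
        ring = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        top = int(np.argmax(ring[:, 1]))
        ring = np.roll(ring, -top, axis=0)
        circle = MainBody(
            silhouette=Polygon(ring),
            boundary=ring,
            axis_x=0.0,
            width_scale=2.0,
            skeleton=SkeletalPath(np.array([[0.0, -1.0], [0.0, 1.0]])),
        )
        for t in (0.1, 0.33, 0.7):
            p1, _ = circle.perimeter_point(t)
            p2, _ = circle.perimeter_point(t + 0.5)
            np.testing.assert_allclose(p1, -p2, atol=1e-6)

    @pytest.mark.parametrize("t1,t2", [(0.1, 0.35), (0.2, 0.21), (0.55, 0.9)])
    def test_arc_distance_matches_cumulative_oracle(self, body, t1, t2):
        """High-resolution cumulative chord-length walk reproduces |t2-t1|·C."""
        ts = np.linspace(t1, t2, 4001)
        pts = np.array([body.perimeter_point(t)[0] for t in ts])
        walked = np.hypot(*np.diff(pts, axis=0).T).sum()
        assert walked == pytest.approx(abs(t2 - t1) * body.perimeter, abs=1e-4)


class TestMainBody:
    def test_upright_and_elongated(self, body):
        minx, miny, maxx, maxy = body.silhouette.bounds
        assert (maxy - miny) == pytest.approx(1.0, abs=1e-9)
        assert (maxy - miny) > (maxx - minx)
        assert body.silhouette.is_valid

    def test_boundary_mirror_symmetric(self, body):
        """The perimeter map t -> 1-t reflects points about the body axis."""
        for t in (0.05, 0.2, 0.45):
            p, _ = body.perimeter_point(t)
            q, _ = body.perimeter_point(1.0 - t)
            assert p[0] == pytest.approx(-q[0], abs=1e-9)
            assert p[1] == pytest.approx(q[1], abs=1e-9)
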