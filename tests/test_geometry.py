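"""Heron areas, Newell planes, polygon projection and grid triangulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from burnmetry import (
    CameraExtrinsics,
    CameraIntrinsics,
    DepthMap,
    PointGrid,
    heron_area,
    measure,
    newell_normal,
    projection_area,
    surface_area_3d,
    trace_boundary,
)
from burnmetry.errors import (
    DegenerateContourError,
    NoWoundError,
    UnmeasurableWoundError,
)

coords = st.floats(-5, 5, allow_nan=False)


class TestHeron:
    def test_3_4_5_right_triangle(self):
        assert heron_area([0, 0, 0], [3, 0, 0], [3, 4, 0]) == pytest.approx(6.0)

    def test_collinear_is_zero(self):
        assert heron_area([0, 0, 0], [1, 1, 1], [2, 2, 2]) == 0.0

    @given(pts=st.lists(st.tuples(coords, coords, coords), min_size=3, max_size=3))
    @settings(max_examples=200, derandomize=True)
    def test_matches_cross_product_oracle(self, pts):
        p1, p2, p3 = (np.array(p) for p in pts)
        oracle = 0.5 * np.linalg.norm(np.cross(p2 - p1, p3 - p1))
        assert heron_area(p1, p2, p3) == pytest.approx(oracle, rel=1e-12, abs=1e-12)

    def test_needle_triangle_stability(self):
        # near-degenerate sliver: naive Heron loses the radicand sign
        a = heron_area([0, 0, 0], [1, 0, 0], [0.5, 1e-7, 0])
        assert a == pytest.approx(0.5e-7, rel=1e-3)
        # never negative/nan, even when the height is below side precision
        tiny = heron_area([0, 0, 0], [1, 0, 0], [0.5, 1e-12, 0])
        assert tiny >= 0.0 and np.isfinite(tiny)

    def test_broadcasts(self):
        p1 = np.zeros((4, 3))
        p2 = np.tile([3.0, 0, 0], (4, 1))
        p3 = np.tile([3.0, 4, 0], (4, 1))
        assert heron_area(p1, p2, p3) == pytest.approx([6, 6, 6, 6])


class TestNewell:
    def test_planar_square_ccw(self):
        sq = [(0, 0, 5), (1, 0, 5), (1, 1, 5), (0, 1, 5)]
        plane = newell_normal(sq)
        assert plane.normal == pytest.approx([0, 0, 1], abs=1e-12)
        assert plane.centroid == pytest.approx([0.5, 0.5, 5.0])

    def test_rotated_square_normal_rotates(self):
        sq = np.array([(0, 0, 5), (1, 0, 5), (1, 1, 5), (0, 1, 5)], float)
        R = Rotation.from_euler("x", 45, degrees=True).as_matrix()
        plane = newell_normal(sq @ R.T)
        assert plane.normal == pytest.approx(R @ [0, 0, 1], abs=1e-12)

    def test_orientation_flips_sign(self):
        sq = [(0, 0, 5), (1, 0, 5), (1, 1, 5), (0, 1, 5)]
        assert newell_normal(sq[::-1]).normal == pytest.approx([0, 0, -1], abs=1e-12)

    @pytest.mark.parametrize(
        "bad",
        [
            [(0, 0, 0), (0, 0, 0), (1, 1, 1)],  # coincident pair
            [(0, 0, 0), (1, 1, 1), (2, 2, 2)],  # collinear
            [(0, 0, 0), (1, 0, 0)],  # too few
        ],
    )
    def test_degenerate_contours(self, bad):
        with pytest.raises(DegenerateContourError):
            newell_normal(bad)


class TestProjectionArea:
    @pytest.mark.parametrize("angles", [(0, 0, 0), (30, 0, 0), (17, -40, 65)])
    def test_unit_square_any_orientation(self, angles):
        """A planar polygon projected onto its own plane keeps its area."""
        sq = np.array([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)], float)
        R = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
        assert projection_area(sq @ R.T + [0.2, -0.1, 3.0]) == pytest.approx(
            10_000.0, rel=1e-12
        )

    def test_concave_hexagon_composite_area(self):
        # L-shape: unit square minus a 0.5 x 0.5 corner -> 0.75 m^2
        L = [(0, 0, 0), (1, 0, 0), (1, 0.5, 0), (0.5, 0.5, 0), (0.5, 1, 0), (0, 1, 0)]
        assert projection_area(L) == pytest.approx(7_500.0, rel=1e-12)

    def test_self_intersecting_warns_but_returns(self):
        # one crossing pair of edges but a nonzero net signed area
        crossed = [(0, 0, 0), (3, 0, 0), (3, 1, 0), (1, -0.2, 0), (0, 1, 0)]
        with pytest.warns(RuntimeWarning, match="self-intersecting"):
            area = projection_area(crossed)
        assert np.isfinite(area) and area > 0

    def test_degenerate_contour_raises(self):
        with pytest.raises(DegenerateContourError):
            projection_area([(0, 0, 0), (1, 1, 1), (2, 2, 2)])


def _flat_grid(h, w, pitch=0.01):
    v, u = np.mgrid[0:h, 0:w].astype(float)
    pts = np.stack([u * pitch, v * pitch, np.full_like(u, 0.3)], axis=-1)
    return PointGrid(points=pts, valid=np.ones((h, w), bool))


class TestSurfaceArea3D:
    def test_flat_rectangle_matches_pixel_area_and_contour(self):
        """On a flat plane the triangulated surface equals the projected
        polygon of its contour (the two area definitions coincide)."""
        grid = _flat_grid(10, 20)
        mask = np.ones((10, 20), bool)
        area, count, cov = surface_area_3d(grid, mask)
        expected = 9 * 19 * 0.01**2 * 1e4  # (h-1)(w-1) pixel cells
        assert area == pytest.approx(expected, rel=1e-9)
        assert count == 2 * 9 * 19
        assert cov == 1.0
        contour = trace_boundary(mask)
        poly = np.array([grid.points[r, c] for r, c in contour])
        assert projection_area(poly) == pytest.approx(area, rel=1e-9)

    def test_quarter_cylinder_patch_analytic(self):
        # radius 0.1 m, 90 deg span, 0.2 m length -> R * theta * L
        R, L, h, w = 0.1, 0.2, 192, 256
        phi = np.linspace(-np.pi / 4, np.pi / 4, h)
        x = np.linspace(0, L, w)
        P, X = np.meshgrid(phi, x, indexing="ij")
        pts = np.stack([X, R * np.sin(P), R * np.cos(P)], axis=-1)
        grid = PointGrid(points=pts, valid=np.ones((h, w), bool))
        area, _, _ = surface_area_3d(grid, np.ones((h, w), bool))
        assert area == pytest.approx(R * (np.pi / 2) * L * 1e4, rel=5e-3)

    def test_spherical_cap_analytic(self):
        R, th_max, h, w = 0.1, 0.5, 256, 256
        th = np.linspace(0, th_max, h)
        az = np.linspace(0, 2 * np.pi, w)
        T, A = np.meshgrid(th, az, indexing="ij")
        pts = np.stack(
            [R * np.sin(T) * np.cos(A), R * np.sin(T) * np.sin(A), R * np.cos(T)],
            axis=-1,
        )
        grid = PointGrid(points=pts, valid=np.ones((h, w), bool))
        area, _, _ = surface_area_3d(grid, np.ones((h, w), bool))
        cap = 2 * np.pi * R * R * (1 - np.cos(th_max)) * 1e4
        assert area == pytest.approx(cap, rel=5e-3)

    def test_boundary_triangles_require_all_vertices(self):
        grid = _flat_grid(3, 3)
        mask = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 0]], bool)
        area, count, cov = surface_area_3d(grid, mask)
        # single fully-masked quad -> two triangles
        assert count == 2
        assert area == pytest.approx(0.01**2 * 1e4)
        assert cov == 1.0

    def test_no_triangle_raises(self):
        grid = _flat_grid(4, 4)
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[0, 2] = mask[2, 0] = True  # no adjacent trio
        with pytest.raises(UnmeasurableWoundError):
            surface_area_3d(grid, mask)

    def test_coverage_counts_missing_depth(self):
        grid = _flat_grid(5, 5)
        grid.valid[2, 2] = False
        area_full, _, cov = surface_area_3d(_flat_grid(5, 5), np.ones((5, 5), bool))
        area_holed, _, cov_holed = surface_area_3d(grid, np.ones((5, 5), bool))
        assert cov == 1.0
        assert cov_holed == pytest.approx(12 / 16)  # 4 quads lose the center
        assert area_holed < area_full


class TestTraceBoundary:
    def test_rectangle_contour_is_perimeter(self):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 1:7] = True
        contour = trace_boundary(mask)
        assert set(contour) == {
            (r, c)
            for r in range(2, 6)
            for c in range(1, 7)
            if r in (2, 5) or c in (1, 6)
        }
        u = np.array([c for _, c in contour], float)
        v = np.array([r for r, _ in contour], float)
        signed = 0.5 * (np.dot(u, np.roll(v, -1)) - np.dot(v, np.roll(u, -1)))
        assert signed > 0  # counter-clockwise in (u, v)

    def test_empty_mask_raises(self):
        with pytest.raises(NoWoundError):
            trace_boundary(np.zeros((4, 4), bool))


class TestMeasure:
    def _flat_scene(self, h=64, w=64, z=0.3, f=200.0):
        intr = CameraIntrinsics(fx=f, fy=f, ox=(w - 1) / 2, oy=(h - 1) / 2)
        return DepthMap(np.full((h, w), z)), intr

    def test_flat_disc_ratio_near_one(self):
        depth, intr = self._flat_scene(h=128, w=128)
        v, u = np.mgrid[0:128, 0:128]
        mask = (u - 63.5) ** 2 + (v - 63.5) ** 2 <= 56**2
        res = measure(depth, mask, intr)
        assert len(res.wounds) == 1
        assert res.total_ratio == pytest.approx(1.0, abs=5e-3)

    def test_multi_wound_totals_are_sums(self):
        depth, intr = self._flat_scene()
        v, u = np.mgrid[0:64, 0:64]
        m1 = (u - 16) ** 2 + (v - 20) ** 2 <= 10**2
        m2 = (u - 47) ** 2 + (v - 42) ** 2 <= 12**2
        both = measure(depth, m1 | m2, intr)
        r1 = measure(depth, m1, intr)
        r2 = measure(depth, m2, intr)
        assert len(both.wounds) == 2
        assert both.total_area2d_cm2 == pytest.approx(
            r1.total_area2d_cm2 + r2.total_area2d_cm2, abs=1e-9
        )
        assert both.total_area3d_cm2 == pytest.approx(
            r1.total_area3d_cm2 + r2.total_area3d_cm2, abs=1e-9
        )

    def test_empty_mask_raises(self):
        depth, intr = self._flat_scene()
        with pytest.raises(NoWoundError):
            measure(depth, np.zeros((64, 64), bool), intr)

    def test_low_coverage_flagged(self):
        depth, intr = self._flat_scene()
        vals = depth.values.copy()
        v, u = np.mgrid[0:64, 0:64]
        mask = (u - 31.5) ** 2 + (v - 31.5) ** 2 <= 20**2
        hole = (u - 31.5) ** 2 + (v - 31.5) ** 2 <= 10**2
        vals[hole] = -1.0  # dead returns inside the wound
        res = measure(DepthMap(vals), mask, intr)
        w = res.wounds[0]
        assert w.coverage < 0.95
        assert any("coverage" in msg for msg in w.warnings)

    def test_tiny_component_skipped_with_warning(self):
        depth, intr = self._flat_scene()
        v, u = np.mgrid[0:64, 0:64]
        mask = (u - 31.5) ** 2 + (v - 31.5) ** 2 <= 15**2
        mask[2, 2] = True  # 1-pixel speck
        res = measure(depth, mask, intr)
        assert len(res.wounds) == 1
        assert any("skipped" in msg for msg in res.warnings)
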