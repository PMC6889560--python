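"""Contour backprojection: polygon membership, cone intersection and
per-slice contour extraction."""

import numpy as np
import pytest
import shapely
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon

from dsabox.backprojection import (Contour2D, DisjointConesError, Structure3D,
                                   backproject_contours,
                                   extract_slice_contours, point_in_cone,
                                   points_in_polygon,
                                   rasterize_slice_contours)
from dsabox.drr import VoxelVolume
from dsabox.geometry import RigidPose, make_view_geometry, project_point

BALL_RADIUS = 6.0


def circle_contour(center_uv, radius, view_label, n=32):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    verts = np.asarray(center_uv)[None, :] + radius * np.stack(
        [np.cos(ang), np.sin(ang)], axis=1)
    return Contour2D(view_label=view_label, vertices=verts)


@pytest.fixture(scope="module")
def geoms():
    return [make_view_geometry(v, 1000, 1500, (128, 128), 1.0)
            for v in ("frontal", "sagittal")]


@pytest.fixture(scope="module")
def grid():
    n = 48
    origin = -(np.full(3, n) - 1) / 2  # 1 mm spacing, centered
    return (origin, np.ones(3), (n, n, n))


def ball_circles(geoms, pose, center, radius, margin=1.0):
    """Circular contours circumscribing the projected ball in both views."""
    out = []
    for g in geoms:
        uv = project_point(g, pose, center)
        mag = g.sid / g.sad
        out.append(circle_contour(uv, mag * radius + margin, g.view_label))
    return out


class TestPointsInPolygon:
    def test_square_membership_with_boundary(self):
        square = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
        pts = np.array([[5, 5], [10, 5], [0, 0], [10.01, 5], [-0.1, 2]])
        got = points_in_polygon(pts, square)
        assert got.tolist() == [True, True, True, False, False]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_shapely_winding_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # a star-shaped (hence simple) random polygon
        ang = np.sort(rng.uniform(0, 2 * np.pi, 12))
        r = rng.uniform(2, 10, 12)
        verts = np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)
        poly = Polygon(verts)
        pts = rng.uniform(-11, 11, size=(1000, 2))
        mine = points_in_polygon(pts, verts)
        # covers = boundary-inclusive containment
        theirs = shapely.covers(poly, shapely.points(pts))
        assert np.array_equal(mine, theirs)


class TestPointInCone:
    def test_center_inside_circular_contour(self, geoms):
        g = geoms[0]
        uv = project_point(g, RigidPose(), np.zeros(3))
        contour = circle_contour(uv, 5.0, "frontal")
        assert point_in_cone(contour, g, RigidPose(), np.zeros(3))

    def test_point_outside_polygon(self, geoms):
        g = geoms[0]
        uv = project_point(g, RigidPose(), np.zeros(3))
        contour = circle_contour(uv, 5.0, "frontal")
        # 10 mm lateral at iso -> 15 mm on the detector, well outside r=5
        assert not point_in_cone(contour, g, RigidPose(),
                                 10.0 * g.detector_axis_u)

    def test_non_projectable_point_is_outside_with_warning(self, geoms):
        g = geoms[0]
        contour = circle_contour(g.principal_point, 5.0, "frontal")
        with pytest.warns(UserWarning):
            assert not point_in_cone(contour, g, RigidPose(),
                                     np.array([0.0, -2000.0, 0.0]))


class TestBackprojectContours:
    def test_symmetric_circles_recover_ball_center(self, geoms, grid):
        contours = ball_circles(geoms, RigidPose(), np.zeros(3), BALL_RADIUS)
        s = backproject_contours(contours[0], contours[1], geoms,
                                 RigidPose(), grid)
        com = s.member_coordinates().mean(axis=0)
        assert np.all(np.abs(com) < 0.5)  # half a voxel

    def test_disjoint_cones_raise(self, geoms, grid):
        c_f = circle_contour(np.array([20.0, 127.5]), 4.0, "frontal")
        c_s = circle_contour(np.array([230.0, 127.5]), 4.0, "sagittal")
        with pytest.raises(DisjointConesError):
            backproject_contours(c_f, c_s, geoms, RigidPose(), grid)

    def test_containment_of_true_target_voxels(self, geoms, grid):
        contours = ball_circles(geoms, RigidPose(), np.zeros(3), BALL_RADIUS)
        s = backproject_contours(contours[0], contours[1], geoms,
                                 RigidPose(), grid)
        origin, spacing, dims = grid
        ax = [origin[i] + np.arange(dims[i]) * spacing[i] for i in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        ball = gx**2 + gy**2 + gz**2 <= BALL_RADIUS**2
        assert np.all(s.mask[ball])

    def test_enlarging_a_contour_never_shrinks_the_box(self, geoms, grid):
        small = ball_circles(geoms, RigidPose(), np.zeros(3), BALL_RADIUS)
        big = ball_circles(geoms, RigidPose(), np.zeros(3), BALL_RADIUS + 3)
        s_small = backproject_contours(small[0], small[1], geoms,
                                       RigidPose(), grid)
        s_big = backproject_contours(big[0], small[1], geoms,
                                     RigidPose(), grid)
        assert np.all(s_big.mask[s_small.mask])
        assert s_big.voxel_count >= s_small.voxel_count

    def test_pose_consistency(self, geoms, grid):
        """Contours drawn on images of a posed phantom, backprojected with
        that pose, reproduce the unposed structure (the target sits at a
        fixed CT-frame position either way)."""
        pose = RigidPose(8.0, -5.0, 4.0, 3.0, -2.0, 5.0)
        center_ct = np.array([5.0, -3.0, 2.0])
        ref = ball_circles(geoms, RigidPose(), center_ct, BALL_RADIUS)
        s_ref = backproject_contours(ref[0], ref[1], geoms, RigidPose(), grid)
        posed = ball_circles(geoms, pose, center_ct, BALL_RADIUS)
        s_posed = backproject_contours(posed[0], posed[1], geoms, pose, grid)
        com_ref = s_ref.member_coordinates().mean(axis=0)
        com_posed = s_posed.member_coordinates().mean(axis=0)
        assert np.all(np.abs(com_ref - com_posed) < 1.0)  # one voxel

    def test_supersampling_refines_grid(self, geoms, grid):
        contours = ball_circles(geoms, RigidPose(), np.zeros(3), BALL_RADIUS)
        s1 = backproject_contours(contours[0], contours[1], geoms,
                                  RigidPose(), grid, supersample=1)
        s2 = backproject_contours(contours[0], contours[1], geoms,
                                  RigidPose(), grid, supersample=2)
        assert np.allclose(s2.spacing, 0.5)
        assert s2.voxel_count == pytest.approx(8 * s1.voxel_count, rel=0.15)


class TestSliceContours:
    def test_single_voxel_yields_one_small_loop(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        s = Structure3D(mask, origin=np.zeros(3), spacing=np.ones(3))
        contours = extract_slice_contours(s)
        assert list(contours) == [2]
        assert len(contours[2]) == 1
        poly = contours[2][0]
        # a closed loop around voxel (2,2): centroid at (2,2) mm
        assert np.allclose(poly.mean(axis=0), [2.0, 2.0], atol=0.2)

    def test_solid_cube_gives_one_square_per_slice(self):
        mask = np.zeros((14, 14, 14), dtype=bool)
        mask[2:12, 2:12, 2:12] = True
        s = Structure3D(mask, origin=np.zeros(3), spacing=np.ones(3))
        contours = extract_slice_contours(s)
        assert sorted(contours) == list(range(2, 12))
        for polys in contours.values():
            assert len(polys) == 1
            poly = polys[0]
            assert poly[:, 0].min() == pytest.approx(1.5)
            assert poly[:, 0].max() == pytest.approx(11.5)

    def test_random_blob_round_trip(self):
        rng = np.random.default_rng(11)
        mask = np.zeros((20, 20, 6), dtype=bool)
        blob = rng.random((8, 8, 4)) > 0.4
        mask[6:14, 6:14, 1:5] = blob
        if not mask.any():
            pytest.skip("degenerate draw")
        s = Structure3D(mask, origin=np.zeros(3), spacing=np.ones(3))
        contours = extract_slice_contours(s)
        re = rasterize_slice_contours(contours, s.origin, s.spacing, mask.shape)
        # every original voxel within one voxel of the rasterization & back
        from scipy.ndimage import binary_dilation
        assert np.all(mask <= binary_dilation(re))
        assert np.all(re <= binary_dilation(mask))

    def test_empty_structure_rejected(self):
        s = Structure3D(np.zeros((3, 3, 3), dtype=bool),
                        origin=np.zeros(3), spacing=np.ones(3))
        with pytest.raises(ValueError):
            extract_slice_contours(s)


class TestContour2DValidation:
    def test_requires_three_vertices_and_area(self):
        with pytest.raises(ValueError):
            Contour2D("frontal", np.array([[0, 0], [1, 1]]))
        with pytest.raises(ValueError):
            Contour2D("frontal", np.array([[0, 0], [1, 1], [2, 2]]))

    def test_explicit_closing_vertex_dropped(self):
        c = Contour2D("frontal", np.array([[0, 0], [4, 0], [4, 4], [0, 0]]))
        assert len(c.vertices) == 3
        assert c.area == pytest.approx(8.0)
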