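"""Surface extraction, lofting, area and point-in-mesh geometry."""

import numpy as np
import pytest

import vesselquant as vq
from vesselquant.surfaces import ContourSet, SliceContour, polygon_area

from conftest import circle_contours


def disk_stack(radii_by_slice, shape=(4, 160, 160), spacing=(1.0, 0.3, 0.3), center=(24.0, 24.0)):
    """Binary disk(s) per slice rendered at 300 nm pixels."""
    nz, ny, nx = shape
    dz, dy, dx = spacing
    yc = (np.arange(ny) + 0.5) * dy
    xc = (np.arange(nx) + 0.5) * dx
    data = np.zeros((1, nz, ny, nx), dtype=np.float32)
    for z, disks in radii_by_slice.items():
        for (cy, cx, r) in disks:
            mask = (yc[:, None] - cy) ** 2 + (xc[None, :] - cx) ** 2 <= r**2
            data[0, z][mask] = 100.0
    return vq.ImageStack(data, spacing, ("Lam1",))


class TestExtraction:
    def test_disk_contour_area_matches_pixel_count_oracle(self):
        stack = disk_stack({0: [(24, 24, 10.0)], 1: [(24, 24, 10.0)]})
        cs = vq.extract_slice_contours(stack, "Lam1", threshold=50.0, smoothing_sigma=0.0)
        area = cs.contours[0].area
        # independent oracle: foreground pixel count × pixel area
        oracle = np.count_nonzero(stack.data[0, 0]) * 0.3 * 0.3
        assert area == pytest.approx(oracle, rel=0.02)
        assert area == pytest.approx(np.pi * 100.0, rel=0.05)

    def test_largest_component_wins(self):
        stack = disk_stack({z: [(24, 24, 10.0), (40, 40, 4.0)] for z in range(2)})
        cs = vq.extract_slice_contours(stack, "Lam1", threshold=50.0, smoothing_sigma=0.0)
        assert cs.contours[0].area == pytest.approx(np.pi * 100.0, rel=0.05)
        centroid = cs.contours[0].polygon.mean(axis=0)
        assert np.allclose(centroid, (24, 24), atol=0.5)

    def test_all_zero_channel_is_an_error(self):
        stack = vq.ImageStack(np.zeros((1, 4, 32, 32), np.float32), (1, 0.3, 0.3), ("Lam1",))
        with pytest.raises(ValueError, match="fewer than 2 usable slices"):
            vq.extract_slice_contours(stack, "Lam1", threshold=1.0)

    def test_fixed_threshold_outside_range_is_an_error(self):
        stack = disk_stack({0: [(24, 24, 10.0)], 1: [(24, 24, 10.0)]})
        with pytest.raises(ValueError, match="threshold"):
            vq.extract_slice_contours(stack, "Lam1", threshold=-5.0)
        # a threshold above every intensity leaves no usable slice
        with pytest.raises(ValueError, match="fewer than 2 usable slices"):
            vq.extract_slice_contours(stack, "Lam1", threshold=1e6)

    def test_longest_consecutive_run_is_returned(self):
        # slices 0-1 and 3-5 have signal; the 3-slice run must win
        stack = disk_stack({z: [(24, 24, 8.0)] for z in (0, 1, 3, 4, 5)}, shape=(6, 160, 160))
        cs = vq.extract_slice_contours(stack, "Lam1", threshold=50.0, smoothing_sigma=0.0)
        assert [c.z_index for c in cs.contours] == [3, 4, 5]


class TestLoft:
    def test_circular_rings_stay_on_radius(self):
        mesh = vq.loft_surface(circle_contours(10.0, n_slices=10), (1.0, 0.3, 0.3), 64)
        ring_pts = mesh.vertices[: 10 * 64]
        r = np.hypot(ring_pts[:, 1] - 20.0, ring_pts[:, 2] - 20.0)
        assert np.all(np.abs(r - 10.0) / 10.0 < 0.01)

    def test_square_prism_is_watertight_with_expected_face_count(self):
        square = np.array([[0.0, 0.0], [0.0, 4.0], [4.0, 4.0], [4.0, 0.0]]) + 10.0
        cs = ContourSet("s", [SliceContour(0, square), SliceContour(1, square)])
        m = 16
        mesh = vq.loft_surface(cs, (1.0, 0.3, 0.3), m)
        assert mesh.is_watertight
        assert len(mesh.triangles) == 2 * m + 2 * m  # side strip + two cap fans

    def test_rotated_ring_start_does_not_change_area(self):
        """Cyclic alignment: oracle = same loft from rotated vertex lists."""
        base = circle_contours(10.0, n_slices=6)
        area0 = vq.mesh_surface_area(vq.loft_surface(base, (1.0, 0.3, 0.3), 32))
        rotated = ContourSet(
            "surface",
            [SliceContour(c.z_index, np.roll(c.polygon, 7 * (i + 1), axis=0))
             for i, c in enumerate(base.contours)],
        )
        area1 = vq.mesh_surface_area(vq.loft_surface(rotated, (1.0, 0.3, 0.3), 32))
        assert area1 == pytest.approx(area0, rel=0.001)

    def test_single_slice_is_rejected(self):
        with pytest.raises(ValueError):
            ContourSet("s", [SliceContour(0, np.array([[0, 0], [0, 4], [4, 4], [4, 0.0]]))])

    def test_area_converges_monotonically_with_ring_vertices(self):
        contours = circle_contours(10.0, n_slices=61, n_pts=512)
        analytic = vq.cylinder_area(10.0, 60.0)
        areas = [
            vq.mesh_surface_area(vq.loft_surface(contours, (1.0, 0.3, 0.3), m))
            for m in (16, 32, 64, 128)
        ]
        assert all(a < analytic for a in areas)
        assert areas == sorted(areas)
        assert areas[-1] == pytest.approx(analytic, rel=0.002)


class TestAreaAndInside:
    def test_lofted_cylinder_area_near_closed_form(self, cylinder_mesh):
        assert vq.mesh_surface_area(cylinder_mesh) == pytest.approx(4398.2297, rel=0.02)

    def test_unit_cube_area_is_six(self):
        verts = np.array(
            [[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1],
             [1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]], dtype=float
        )
        faces = np.array(
            [[0, 1, 3], [0, 3, 2], [4, 6, 7], [4, 7, 5], [0, 4, 5], [0, 5, 1],
             [2, 3, 7], [2, 7, 6], [0, 2, 6], [0, 6, 4], [1, 5, 7], [1, 7, 3]]
        )
        cube = vq.SurfaceMesh(verts, faces, "cube")
        assert cube.is_watertight
        assert vq.mesh_surface_area(cube) == pytest.approx(6.0)
        # doubling all coordinates scales area by exactly 4
        double = vq.SurfaceMesh(verts * 2, faces, "cube2")
        assert vq.mesh_surface_area(double) == pytest.approx(24.0)

    def test_area_agrees_with_independent_mesh_library(self, cylinder_mesh):
        assert vq.mesh_surface_area(cylinder_mesh) == pytest.approx(
            cylinder_mesh.as_trimesh().area, rel=1e-9
        )

    def test_non_watertight_mesh_warns_but_returns_area(self):
        verts = np.array([[0, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        open_mesh = vq.SurfaceMesh(verts, np.array([[0, 1, 2]]), "open")
        with pytest.warns(UserWarning, match="watertight"):
            area = vq.mesh_surface_area(open_mesh)
        assert area == pytest.approx(0.5)

    def test_point_inside_cylinder_examples(self, cylinder_mesh):
        assert vq.point_inside(cylinder_mesh, (30.0, 25.0, 20.0))  # 5 μm off axis
        assert not vq.point_inside(cylinder_mesh, (30.0, 35.0, 20.0))  # 15 μm off axis
        assert vq.point_inside(cylinder_mesh, (30.0, 20.0, 20.0))  # on axis

    def test_point_inside_agrees_with_analytic_membership(self, cylinder_mesh):
        rng = np.random.default_rng(42)
        pts = np.column_stack(
            [rng.uniform(0, 60, 3000), rng.uniform(5, 35, 3000), rng.uniform(5, 35, 3000)]
        )
        inside = vq.points_inside(cylinder_mesh, pts)
        analytic = (
            (np.hypot(pts[:, 1] - 20, pts[:, 2] - 20) <= 10.0)
            & (pts[:, 0] >= 0.5) & (pts[:, 0] <= 60.5)
        )
        assert (inside == analytic).mean() >= 0.995

    def test_voxel_mask_matches_ray_parity(self, cylinder_mesh):
        """Dual route: ring rasterization vs generic ray casting."""
        shape, spacing = (10, 40, 40), (2.0, 1.1, 1.1)
        mask = vq.mesh_voxel_mask(cylinder_mesh, shape, spacing)
        generic = vq.SurfaceMesh(cylinder_mesh.vertices, cylinder_mesh.triangles, "g")
        mask2 = vq.mesh_voxel_mask(generic, shape, spacing)
        assert (mask == mask2).mean() > 0.99


def test_phantom_meshes_are_nested(wt_phantom, wt_report):
    stack, _ = wt_phantom
    endo = vq.loft_surface(
        vq.extract_slice_contours(stack, "CD31", surface_name="endo"), stack.voxel_spacing, 64
    )
    par = vq.loft_surface(
        vq.extract_slice_contours(stack, "Lam1", surface_name="par"), stack.voxel_spacing, 64
    )
    assert endo.is_watertight and par.is_watertight
    assert vq.points_inside(par, endo.vertices).all()


def test_contour_json_roundtrip(tmp_path):
    cs = circle_contours(8.0, n_slices=4)
    p = vq.write_contours_json(cs, tmp_path / "c.json")
    back = vq.read_contours_json(p)
    assert back.surface_name == cs.surface_name
    assert len(back.contours) == 4
    assert np.allclose(back.contours[2].polygon, cs.contours[2].polygon)
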