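"""Geometry containers, I/O round trips, cleaning, merging, mass
properties, deviation maps and interference checks."""

import numpy as np
import pytest
import trimesh

from rebiom.geometry import (
    DeviationReport,
    GeometryFormatError,
    PointCloud,
    TriangleMesh,
    WatertightError,
    clean_cloud,
    closest_on_surface,
    deviation_map,
    interference_check,
    mass_properties,
    merge_clouds,
    read_geometry,
    repair_mesh,
    write_geometry,
)


@pytest.fixture()
def small_mesh(sphere10):
    return sphere10


class TestIO:
    @pytest.mark.parametrize("fmt", ["ply", "stl", "obj"])
    def test_mesh_round_trip(self, tmp_path, sphere10, fmt):
        path = tmp_path / f"mesh.{fmt}"
        write_geometry(sphere10, path)
        back = read_geometry(path)
        assert isinstance(back, TriangleMesh)
        assert len(back.faces) == len(sphere10.faces)
        # STL exports do not share vertices; compare welded counts
        repaired = repair_mesh(back)
        assert len(repaired.vertices) == len(sphere10.vertices)
        ref = np.sort(sphere10.vertices.round(5), axis=0)
        got = np.sort(repaired.vertices.round(5), axis=0)
        np.testing.assert_allclose(got, ref, atol=1e-4)

    def test_xyz_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        cloud = PointCloud(rng.normal(size=(137, 3)) * 10)
        path = tmp_path / "cloud.xyz"
        write_geometry(cloud, path)
        back = read_geometry(path)
        assert isinstance(back, PointCloud)
        assert len(back) == 137
        np.testing.assert_allclose(back.points, cloud.points, atol=1e-6)

    def test_truncated_stl_raises(self, tmp_path, sphere10):
        path = tmp_path / "mesh.stl"
        write_geometry(sphere10, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(GeometryFormatError):
            read_geometry(path)

    def test_unknown_suffix(self, tmp_path):
        p = tmp_path / "mesh.weird"
        p.write_text("junk")
        with pytest.raises(GeometryFormatError):
            read_geometry(p)


class TestCleanCloud:
    def test_planted_outliers_removed(self):
        rng = np.random.default_rng(7)
        base = rng.random((3000, 3)) * 20.0
        spacing = 20.0 / 3000 ** (1 / 3)
        outliers = rng.random((50, 3)) * 20.0 + np.array([0, 0, 10 * spacing + 40])
        cloud = PointCloud(np.vstack([base, outliers]))
        cleaned = clean_cloud(cloud, k_neighbors=16, sigma_mult=2.5)
        kept = {tuple(p) for p in cleaned.points}
        n_outliers_kept = sum(tuple(p) in kept for p in outliers)
        assert n_outliers_kept == 0
        inliers_lost = len(base) - sum(tuple(p) in kept for p in base)
        assert inliers_lost <= 0.01 * len(base)

    def test_uniform_cloud_unchanged(self):
        g = np.stack(np.meshgrid(*[np.arange(8.0)] * 3), axis=-1).reshape(-1, 3)
        cloud = PointCloud(g)
        out = clean_cloud(cloud, k_neighbors=6, sigma_mult=6.0)
        assert len(out) == len(cloud)
        np.testing.assert_array_equal(out.points, cloud.points)

    def test_idempotent_on_scan_cloud(self, default_bone):
        from rebiom.fixtures import ScanSpec, emulate_scan

        mesh, _ = default_bone
        clouds, _, _ = emulate_scan(
            mesh, ScanSpec(sigma=0.05, n_views=1, points_per_view=4000, seed=3)
        )
        # at thresholds separating true outliers from the bulk, cleaning a
        # cleaned cloud removes nothing further
        once = clean_cloud(clouds[0], sigma_mult=4.5)
        twice = clean_cloud(once, sigma_mult=4.5)
        assert len(twice) == len(once)

    def test_too_few_points_raises(self):
        cloud = PointCloud(np.random.default_rng(0).random((16, 3)))
        with pytest.raises(ValueError, match="k_neighbors"):
            clean_cloud(cloud, k_neighbors=16)


class TestMergeClouds:
    def test_duplicate_cloud_collapses(self):
        rng = np.random.default_rng(1)
        pts = rng.random((400, 3)) * 50
        a = PointCloud(pts)
        merged = merge_clouds([a, PointCloud(pts.copy())], voxel=0.05)
        # brute-force voxel hash oracle
        keys = {tuple(k) for k in np.floor(pts / 0.05).astype(int)}
        assert len(merged) == len(keys)

    def test_huge_voxel_gives_centroid(self):
        pts = np.array([[0.0, 0, 0], [1, 1, 1], [2, 2, 2]])
        merged = merge_clouds([PointCloud(pts)], voxel=1000.0)
        assert len(merged) == 1
        np.testing.assert_allclose(merged.points[0], pts.mean(axis=0))

    def test_disjoint_clouds_sum(self):
        a = PointCloud(np.random.default_rng(0).random((100, 3)))
        b = PointCloud(np.random.default_rng(1).random((80, 3)) + 100.0)
        merged = merge_clouds([a, b], voxel=1e-4)
        assert len(merged) == 180

    def test_order_independent(self):
        rng = np.random.default_rng(5)
        a = PointCloud(rng.random((200, 3)) * 10)
        b = PointCloud(rng.random((150, 3)) * 10)
        m1 = merge_clouds([a, b], voxel=0.5)
        m2 = merge_clouds([b, a], voxel=0.5)
        np.testing.assert_allclose(m1.points, m2.points)

    def test_bad_voxel(self):
        with pytest.raises(ValueError):
            merge_clouds([], voxel=0.0)


class TestMassProperties:
    def test_unit_cube(self):
        box = TriangleMesh.from_trimesh(trimesh.creation.box(extents=[1, 1, 1]))
        vol, mass, centroid, inertia = mass_properties(box, density=2.0)
        assert vol == pytest.approx(1.0, rel=1e-9)
        assert mass == pytest.approx(2.0, rel=1e-9)
        np.testing.assert_allclose(centroid, 0.0, atol=1e-9)

    def test_icosphere_volume(self):
        ico = TriangleMesh.from_trimesh(trimesh.creation.icosphere(4, 10.0))
        vol, *_ = mass_properties(ico)
        assert vol == pytest.approx(4 / 3 * np.pi * 1000.0, rel=5e-3)

    def test_open_mesh_raises(self):
        box = trimesh.creation.box(extents=[1, 1, 1])
        open_mesh = TriangleMesh(np.asarray(box.vertices), np.asarray(box.faces)[:-1])
        with pytest.raises(WatertightError, match="open edge"):
            mass_properties(open_mesh)

    def test_translation_invariant_volume(self, sphere10):
        vol0, *_ = mass_properties(sphere10)
        moved = TriangleMesh(sphere10.vertices + [10, -4, 7], sphere10.faces)
        vol1, *_ = mass_properties(moved)
        assert vol1 == pytest.approx(vol0, rel=1e-12)

    def test_inertia_rotates_correctly(self):
        box = TriangleMesh.from_trimesh(trimesh.creation.box(extents=[30, 10, 8]))
        _, _, _, inertia = mass_properties(box)
        ang = 0.7
        R = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        rot = TriangleMesh(box.vertices @ R.T, box.faces)
        _, _, _, inertia_rot = mass_properties(rot)
        np.testing.assert_allclose(inertia_rot, R @ inertia @ R.T, rtol=1e-9, atol=1e-9)

    def test_inertia_matches_voxel_integration(self):
        # brute-force voxelised solid integration oracle on a box
        box = TriangleMesh.from_trimesh(trimesh.creation.box(extents=[6, 4, 2]))
        _, mass, _, inertia = mass_properties(box, density=1.0)
        n = 40
        xs = (np.arange(n) + 0.5) / n
        gx, gy, gz = np.meshgrid(xs * 6 - 3, xs * 4 - 2, xs * 2 - 1, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        dm = (6 * 4 * 2) / n**3
        r2 = (pts**2).sum(axis=1)
        I = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                if i == j:
                    I[i, i] = dm * (r2 - pts[:, i] ** 2).sum()
                else:
                    I[i, j] = -dm * (pts[:, i] * pts[:, j]).sum()
        np.testing.assert_allclose(inertia, I, rtol=1e-2, atol=1e-9 * np.abs(I).max())


class TestDeviationMap:
    def test_on_surface_points_zero(self, sphere10):
        v = sphere10.vertices[::7]
        rep = deviation_map(sphere10, PointCloud(v))
        assert rep.max < 1e-9

    def test_translated_plane_distance(self, plane_grid):
        d = 0.37
        pts = plane_grid.vertices[::5] + np.array([0, 0, d])
        rep = deviation_map(plane_grid, PointCloud(pts))
        assert rep.max == pytest.approx(d, abs=1e-9)
        assert rep.mean == pytest.approx(d, abs=1e-9)

    def test_matches_exhaustive_oracle(self, default_bone):
        mesh, _ = default_bone
        small = TriangleMesh(mesh.vertices, mesh.faces[::13])  # open but fine
        rng = np.random.default_rng(11)
        pts = rng.normal(scale=15.0, size=(100, 3)) + [0, 20, 0]
        _, dist, _ = closest_on_surface(small, pts)
        # exhaustive all-triangle minimum
        from rebiom.geometry import _closest_point_on_triangles

        tri = small.vertices[small.faces]
        brute = np.empty(len(pts))
        for i, p in enumerate(pts):
            pp = np.broadcast_to(p, (len(tri), 3))
            cp = _closest_point_on_triangles(np.ascontiguousarray(pp), tri)
            brute[i] = np.linalg.norm(cp - p, axis=1).min()
        np.testing.assert_allclose(dist, brute, atol=1e-12)

    def test_report_invariants(self, sphere10):
        pts = sphere10.vertices[::11] * 1.05
        rep = deviation_map(sphere10, PointCloud(pts))
        assert isinstance(rep, DeviationReport)
        assert rep.max >= rep.mean >= 0
        assert len(rep.distances) == len(pts)


class TestInterference:
    def _sphere(self, center, r=1.0):
        tm = trimesh.creation.icosphere(2, r)
        return TriangleMesh(np.asarray(tm.vertices) + center, np.asarray(tm.faces))

    def test_separated_spheres_clean(self):
        a = self._sphere([0, 0, 0])
        b = self._sphere([3, 0, 0])
        assert interference_check([a, b], clearance=0.0) == []

    def test_overlapping_spheres_flagged(self):
        a = self._sphere([0, 0, 0])
        b = self._sphere([1.5, 0, 0])
        assert interference_check([a, b], clearance=0.0) == [(0, 1)]

    def test_clearance_violation(self):
        a = self._sphere([0, 0, 0])
        b = self._sphere([2.2, 0, 0])  # 0.2 mm gap
        assert interference_check([a, b], clearance=0.5) == [(0, 1)]
        assert interference_check([a, b], clearance=0.05) == []

    def test_open_member_raises(self):
        tm = trimesh.creation.icosphere(2, 1.0)
        open_mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces)[:-1])
        with pytest.raises(WatertightError):
            interference_check([open_mesh])


def test_skeleton_rest_pose_interference_free():
    """The generated hand skeleton places bones with guaranteed gaps."""
    from rebiom.fixtures import gen_skeleton

    fx = gen_skeleton(seed=0)
    meshes = [b.mesh for b in fx.bones]
    assert interference_check(meshes, clearance=0.0) == []


class TestContainers:
    def test_normals_validated(self):
        with pytest.raises(ValueError, match="unit"):
            PointCloud(np.zeros((2, 3)), normals=np.ones((2, 3)))

    def test_face_index_range(self):
        with pytest.raises(ValueError):
            TriangleMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))

    def test_nonfinite_points(self):
        with pytest.raises(ValueError, match="finite"):
            PointCloud(np.array([[0.0, np.nan, 0.0]]))
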