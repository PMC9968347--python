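"""Mesh primitives: normals, ball-pivoting reconstruction, volume, distances."""

import numpy as np
import pytest
import trimesh

from foramenvol.mesh import (
    BPAParams,
    EmptyReconstructionError,
    PointCloud,
    _closest_on_triangles,
    cross_section,
    estimate_normals,
    load_point_cloud_ply,
    mesh_volume,
    point_to_surface_distances,
    reconstruct_surface_bpa,
    save_point_cloud_ply,
)


def planar_grid(spacing=0.3, size=10.0):
    g = np.arange(0.0, size + spacing / 2, spacing)
    X, Y = np.meshgrid(g, g)
    return np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])


# ---------------------------------------------------------------------------
# normal estimation
# ---------------------------------------------------------------------------


def test_plane_normals_axis_aligned_and_consistent():
    rng = np.random.default_rng(1)
    pts = np.column_stack([rng.uniform(0, 50, (10_000, 2)), np.zeros(10_000)])
    pc = estimate_normals(pts, 100)
    assert np.allclose(np.abs(pc.normals[:, 2]), 1.0, atol=1e-9)
    assert len(np.unique(np.sign(pc.normals[:, 2]))) == 1  # consistently signed


def test_sphere_normals_near_radial():
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=20.0)
    pc = estimate_normals(sphere.vertices.view(np.ndarray), 100)
    radial = pc.points / np.linalg.norm(pc.points, axis=1, keepdims=True)
    dots = np.abs(np.einsum("ij,ij->i", radial, pc.normals))
    mean_dev = np.degrees(np.arccos(np.clip(dots, -1, 1))).mean()
    assert mean_dev < 2.0


def test_normals_require_enough_points():
    with pytest.raises(ValueError, match="fewer than neighborhood_size"):
        estimate_normals(np.random.default_rng(0).normal(size=(50, 3)), 100)


# ---------------------------------------------------------------------------
# ball pivoting
# ---------------------------------------------------------------------------


def test_bpa_planar_patch_is_single_covering_component():
    pts = planar_grid(0.3, 10.0)
    cloud = PointCloud(pts, np.tile([0.0, 0.0, 1.0], (len(pts), 1)))
    mesh = reconstruct_surface_bpa(cloud)
    components = mesh.split(only_watertight=False)
    assert len(components) == 1
    used = len(np.unique(mesh.faces)) / len(pts)
    assert used >= 0.95
    # reconstruction never invents vertices
    assert np.array_equal(mesh.vertices, pts)


def test_bpa_ball_falls_through_sparse_sampling():
    pts = planar_grid(0.3, 6.0)
    cloud = PointCloud(pts, np.tile([0.0, 0.0, 1.0], (len(pts), 1)))
    params = BPAParams(
        radii_schedule=(0.05, 0.1), final_radius=0.12, enable_final_loop=True
    )
    with pytest.raises(EmptyReconstructionError, match="0.12"):
        reconstruct_surface_bpa(cloud, params)


def test_bpa_requires_normals():
    with pytest.raises(ValueError, match="normals"):
        reconstruct_surface_bpa(PointCloud(planar_grid()))


def test_bpa_closed_sphere_reconstruction():
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=20.0)
    pc = estimate_normals(sphere.vertices.view(np.ndarray), 60)
    mesh = reconstruct_surface_bpa(pc, BPAParams(radii_schedule=(1.5, 2.0, 2.4)))
    assert mesh.is_watertight
    d = point_to_surface_distances(sphere.vertices[::7], mesh)
    assert d.max() < 1e-9  # vertices are preserved verbatim


def test_bpa_params_validation():
    with pytest.raises(ValueError):
        BPAParams(radii_schedule=(1.0, 0.8))
    with pytest.raises(ValueError):
        BPAParams(clustering_fraction_default=0.0)
    with pytest.raises(ValueError):
        BPAParams(angle_threshold=200.0)


# ---------------------------------------------------------------------------
# volume
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "mesh,expected,rel_tol",
    [
        (trimesh.creation.box((1.0, 1.0, 1.0)), 1.0, 1e-9),
        (
            trimesh.creation.cylinder(radius=10.0, height=90.0, sections=720),
            np.pi * 100.0 * 90.0,
            1e-3,
        ),
    ],
    ids=["unit-cube", "cylinder-720"],
)
def test_mesh_volume_closed_forms(mesh, expected, rel_tol):
    assert mesh_volume(mesh) == pytest.approx(expected, rel=rel_tol)


def test_mesh_volume_open_mesh_error_reports_boundary():
    box = trimesh.creation.box((1.0, 1.0, 1.0))
    open_mesh = trimesh.Trimesh(
        vertices=box.vertices, faces=box.faces[:-1], process=False
    )
    with pytest.raises(ValueError, match="boundary edges"):
        mesh_volume(open_mesh)


def test_mesh_volume_rigid_invariance():
    mesh = trimesh.creation.cylinder(radius=4.0, height=11.0, sections=128)
    v0 = mesh_volume(mesh)
    moved = mesh.copy()
    moved.apply_transform(
        trimesh.transformations.rotation_matrix(0.7, (1, 2, 3), (4, 5, 6))
    )
    assert abs(mesh_volume(moved) - v0) / v0 < 1e-6


def test_phantom_vertebra_volume_matches_analytic_oracle(specimen):
    from conftest import analytic_inside

    h = 0.1
    lo, hi = specimen.caudal_mesh.bounds
    xs = np.arange(lo[0] - h, hi[0] + h, h) + h / 3
    ys = np.arange(lo[1] - h, hi[1] + h, h) + h / 3
    zs = np.arange(lo[2] - h, hi[2] + h, h) + h / 3
    # z-slab chunks keep the 0.1 mm lattice within a modest memory budget
    count = 0
    for z_chunk in np.array_split(zs, 16):
        X, Y, Z = np.meshgrid(xs, ys, z_chunk, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        count += int(analytic_inside(specimen, pts, "caudal").sum())
    v_oracle = count * h**3
    assert mesh_volume(specimen.caudal_mesh) == pytest.approx(v_oracle, rel=0.01)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def test_distances_of_own_vertices_are_zero():
    mesh = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
    assert point_to_surface_distances(mesh.vertices.view(np.ndarray), mesh).max() == 0.0


def test_distance_to_plane_patch():
    g = np.arange(-5.0, 5.01, 1.0)
    X, Y = np.meshgrid(g, g)
    pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    pc = PointCloud(pts, np.tile([0.0, 0.0, 1.0], (len(pts), 1)))
    plane = reconstruct_surface_bpa(pc, BPAParams(radii_schedule=(1.2, 1.6)))
    assert point_to_surface_distances([[0.0, 0.0, 5.0]], plane)[0] == pytest.approx(5.0)


def test_distances_match_brute_force_oracle():
    rng = np.random.default_rng(7)
    mesh = trimesh.creation.icosphere(subdivisions=2, radius=5.0)  # 320 faces
    pts = rng.uniform(-8.0, 8.0, size=(100, 3))
    fast = point_to_surface_distances(pts, mesh)
    tri = mesh.triangles.view(np.ndarray)
    brute = np.array(
        [
            np.min(
                np.linalg.norm(
                    _closest_on_triangles(np.broadcast_to(p, (len(tri), 3)).copy(), tri)
                    - p,
                    axis=1,
                )
            )
            for p in pts
        ]
    )
    np.testing.assert_allclose(fast, brute, atol=1e-12)


def test_distances_rigid_motion_symmetry():
    rng = np.random.default_rng(3)
    mesh = trimesh.creation.box((3.0, 4.0, 5.0))
    pts = rng.uniform(-4, 4, size=(50, 3))
    d0 = point_to_surface_distances(pts, mesh)
    M = trimesh.transformations.rotation_matrix(1.1, (1, 0, 2), (0.5, -1, 2))
    moved = mesh.copy()
    moved.apply_transform(M)
    pts_m = pts @ M[:3, :3].T + M[:3, 3]
    d1 = point_to_surface_distances(pts_m, moved)
    np.testing.assert_allclose(d0, d1, atol=1e-9)


# ---------------------------------------------------------------------------
# sections and I/O
# ---------------------------------------------------------------------------


def test_cross_section_box_area_exact():
    box = trimesh.creation.box((4.0, 6.0, 8.0))
    region = cross_section(box, 1.234)
    assert region.area == pytest.approx(24.0, rel=1e-9)
    assert cross_section(box, 5.0).is_empty


def test_cross_section_tube_has_hole():
    tube = trimesh.creation.annulus(r_min=3.0, r_max=5.0, height=10.0)
    region = cross_section(tube, 0.37)
    # inscribed-polygon areas of the tessellated circles
    n = 32  # trimesh default sections
    expected = 0.5 * n * np.sin(2 * np.pi / n) * (25.0 - 9.0)
    assert region.area == pytest.approx(expected, rel=1e-6)


def test_point_cloud_ply_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(20, 3))
    normals = np.tile([0.0, 0.0, 1.0], (20, 1))
    labels = np.array(["caudal"] * 10 + ["cranial"] * 10)
    path = tmp_path / "cloud.ply"
    save_point_cloud_ply(PointCloud(pts, normals, labels), path)
    back = load_point_cloud_ply(path)
    np.testing.assert_allclose(back.points, pts, atol=1e-6)
    np.testing.assert_allclose(back.normals, normals, atol=1e-6)
    assert list(back.labels) == list(labels)
    assert len(back.select("caudal")) == 10
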