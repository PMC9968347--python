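"""Synthetic FSU generator: determinism, poses, patches and CT emulation."""

import numpy as np
import pytest

from conftest import BONE_BAND, CEMENT_BAND, analytic_inside_grid
from foramenvol.mesh import MeshSlicer, mesh_volume, point_to_surface_distances
from foramenvol.phantom import (
    CONDITIONS,
    MOTIONS,
    PhantomParams,
    generate_fsu,
    sample_dic_patch,
    voxelize_ct,
)
from foramenvol.quality import dice
from foramenvol.segmentation import BinaryMask, threshold_mask


def test_generation_is_bitwise_deterministic():
    a = generate_fsu(PhantomParams(seed=7))
    b = generate_fsu(PhantomParams(seed=7))
    assert np.array_equal(a.caudal_mesh.vertices, b.caudal_mesh.vertices)
    assert np.array_equal(a.cranial_mesh.faces, b.cranial_mesh.faces)
    for key in a.true_poses:
        assert np.array_equal(a.true_poses[key].matrix, b.true_poses[key].matrix)


def test_meshes_watertight(specimen):
    for mesh in (specimen.caudal_mesh, specimen.cranial_mesh, specimen.cement_mesh):
        assert mesh.is_watertight


def test_vertebrae_never_intersect_in_any_pose(specimen):
    """Transverse sections of caudal and posed cranial never overlap."""
    caudal = MeshSlicer(
        specimen.caudal_mesh.copy()
    )
    for (cond, motion), pose in specimen.true_poses.items():
        cranial = specimen.posed_cranial(cond, motion)
        sl = MeshSlicer(cranial)
        lo = max(caudal.bounds[0], sl.bounds[0])
        hi = min(caudal.bounds[1], sl.bounds[1])
        if lo >= hi:
            continue
        for z in np.linspace(lo + 0.05, hi - 0.05, 7):
            overlap = caudal.region(z).intersection(sl.region(z)).area
            assert overlap < 1e-9, (cond, motion, z)


def test_foramen_axis_crosses_the_gap(specimen):
    p = specimen.foramen_axis_point
    d = specimen.foramen_axis_direction
    np.testing.assert_allclose(d, [0.0, 1.0, 0.0])
    # axis point clears both vertebrae
    for mesh in (specimen.caudal_mesh, specimen.cranial_mesh):
        assert point_to_surface_distances([p], mesh)[0] > 0.5


def test_zero_distraction_gives_identical_poses():
    spec = generate_fsu(PhantomParams(distraction_discoplasty=0.0))
    for motion in MOTIONS:
        np.testing.assert_allclose(
            spec.true_pose("nucleotomy", motion).matrix,
            spec.true_pose("discoplasty", motion).matrix,
            atol=1e-12,
        )
    m = spec.ground_truth_measurement("flexion", method="exact", voxel_size=0.3)
    assert m.delta_v == pytest.approx(0.0, abs=1e-9)


def test_pure_translation_distraction_matches_voxel_oracle():
    """With no motion angles the pose is a pure 3 mm lift along the disc normal."""
    spec = generate_fsu(
        PhantomParams(distraction_discoplasty=3.0, flexion_angle=1e-9, extension_angle=1e-9)
    )
    pose = spec.true_pose("discoplasty", "flexion")
    assert pose.rotation_angle_deg < 1e-6
    np.testing.assert_allclose(pose.translation, [0.0, 0.0, 0.0], atol=1e-9)
    nuc = spec.true_pose("nucleotomy", "flexion")
    np.testing.assert_allclose(nuc.translation, [0.0, 0.0, -3.0], atol=1e-9)
    exact = spec.ground_truth_measurement("flexion", method="exact")
    voxel = spec.ground_truth_measurement("flexion", method="voxel", voxel_size=0.2)
    assert exact.delta_v == pytest.approx(voxel.delta_v, rel=0.02)
    assert exact.delta_v > 0


def test_ground_truth_volume_monotone_in_distraction():
    volumes = []
    for distraction in (0.5, 2.0, 3.5):
        spec = generate_fsu(PhantomParams(distraction_discoplasty=distraction))
        m = spec.ground_truth_measurement("extension", method="exact", voxel_size=0.3)
        volumes.append((m.v_nucleotomy, m.v_discoplasty))
    # within each specimen discoplasty frees volume; across specimens the
    # discoplasty volume grows with distraction (same nucleotomy geometry)
    for v_n, v_d in volumes:
        assert v_d >= v_n
    assert volumes[0][1] < volumes[1][1] < volumes[2][1]


@pytest.mark.parametrize(
    "kwargs,match",
    [
        (dict(disc_height=-1.0), "positive"),
        (dict(flexion_angle=60.0), "45"),
        (dict(noise_sd=-0.1), "noise_sd"),
        (dict(pedicle_width=23.0), "canal"),
        (dict(arch_height=10.0, pedicle_height=14.0), "arch"),
        (dict(cement_volume=40000.0), "cement_volume"),
        (dict(flexion_angle=20.0), "interpenetrate"),
    ],
)
def test_impossible_parameters_rejected(kwargs, match):
    with pytest.raises(ValueError, match=match):
        PhantomParams(**kwargs)


# ---------------------------------------------------------------------------
# DIC-like patches
# ---------------------------------------------------------------------------


def test_noise_free_patch_lies_on_posed_surfaces(specimen):
    import trimesh

    patch = sample_dic_patch(specimen, "discoplasty", "flexion", noise_sd=0.0, seed=3)
    surfaces = trimesh.util.concatenate(
        specimen.posed_meshes("discoplasty", "flexion")
        + [specimen.disc_surrogate("discoplasty")]
    )
    d = point_to_surface_distances(patch.points, surfaces)
    assert d.max() < 1e-9
    assert set(np.unique(patch.labels)) == {"caudal", "cranial", "disc"}


def test_patch_noise_matches_prescribed_scale(specimen):
    """Isotropic 3D noise of sd 0.002 mm gives RMS offset ~ 0.002*sqrt(3)."""
    noisy = sample_dic_patch(
        specimen, "nucleotomy", "extension", noise_sd=0.002, seed=4
    )
    clean = sample_dic_patch(
        specimen, "nucleotomy", "extension", noise_sd=0.0, seed=4
    )
    assert len(noisy) >= 10_000
    rms = np.sqrt(np.mean(np.sum((noisy.points - clean.points) ** 2, axis=1)))
    assert rms == pytest.approx(0.002 * np.sqrt(3), rel=0.2)


def test_patch_coverage_fraction_thins_points(specimen):
    full = sample_dic_patch(specimen, "discoplasty", "flexion", 1.0, 0.0, seed=3)
    part = sample_dic_patch(specimen, "discoplasty", "flexion", 0.3, 0.0, seed=3)
    assert len(part) / len(full) == pytest.approx(0.3, abs=0.05)


def test_patch_determinism_and_bad_view(specimen):
    a = sample_dic_patch(specimen, "discoplasty", "flexion", seed=9)
    b = sample_dic_patch(specimen, "discoplasty", "flexion", seed=9)
    assert np.array_equal(a.points, b.points)
    with pytest.raises(ValueError, match="coverage_fraction"):
        sample_dic_patch(specimen, "discoplasty", "flexion", coverage_fraction=0.0)


# ---------------------------------------------------------------------------
# CT emulation
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def ct_03(specimen):
    """Noise-free 0.3 mm isotropic image plus the analytic-oracle mask."""
    img = voxelize_ct(
        specimen, spacing=(0.3, 0.3, 0.3), noise_sd_intensity=0.0, margin=2.0
    )
    xs, ys, zs = img.voxel_centers()
    oracle = BinaryMask(
        analytic_inside_grid(specimen, xs, ys, zs), img.spacing, img.origin, tag="oracle"
    )
    return img, oracle


def test_noise_free_threshold_recovers_exact_voxelization(specimen, ct_03):
    img, oracle = ct_03
    bone = threshold_mask(img, 700.0)
    # remove the cement band first: the oracle covers the vertebrae only
    bone.data &= img.data <= 1600.0
    assert dice(bone, oracle) == pytest.approx(1.0, abs=1e-12)


def test_noisy_threshold_dice_stays_high(specimen, ct_03):
    _, oracle = ct_03
    img = voxelize_ct(
        specimen, spacing=(0.3, 0.3, 0.3), noise_sd_intensity=50.0, seed=1, margin=2.0
    )
    bone = threshold_mask(img, 700.0)
    bone.data &= img.data <= 1600.0
    assert dice(bone, oracle) >= 0.98


def test_cement_band_volume_close_to_mesh_volume(ct_image, specimen):
    from foramenvol.segmentation import separate_cement

    _, cement = separate_cement(ct_image, BONE_BAND, CEMENT_BAND)
    assert cement.volume == pytest.approx(mesh_volume(specimen.cement_mesh), rel=0.05)


def test_coarse_spacing_warns(specimen):
    with pytest.warns(UserWarning, match="pedicle"):
        voxelize_ct(specimen, spacing=(5.0, 5.0, 5.0), noise_sd_intensity=0.0, margin=2.0)


def test_export_specimen_writes_manifest(tmp_path, specimen):
    import yaml

    from foramenvol.phantom import export_specimen

    out = export_specimen(specimen, tmp_path / "spec")
    with open(out / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    assert manifest["cylinder_radius"] == pytest.approx(specimen.cylinder_radius)
    assert len(manifest["true_poses"]) == 6
    pose = np.array(manifest["true_poses"]["discoplasty/flexion"]).reshape(4, 4)
    np.testing.assert_allclose(
        pose, specimen.true_pose("discoplasty", "flexion").matrix, atol=1e-12
    )
    assert (out / "caudal.stl").exists()
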