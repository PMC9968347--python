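"""Shared fixtures: phantom specimens, CT chains, and an analytic oracle.

Heavy artifacts (CT images, iso-surfaces, one full pipeline run) are
session-scoped and shared across test modules.  ``analytic_inside`` is an
arithmetic point-in-solid test for the phantom primitives, fully independent
of the package's mesh/slicing code, used as the voxelization oracle.
"""

from __future__ import annotations

import numpy as np
import pytest

from foramenvol.phantom import PhantomParams, generate_fsu, voxelize_ct
from foramenvol.pipeline import PipelineConfig, run_phantom_specimen
from foramenvol.segmentation import mask_to_mesh, separate_cement, split_vertebrae

BONE_BAND = (700.0, 1600.0)
CEMENT_BAND = (1600.0, 4000.0)


@pytest.fixture(scope="session")
def specimen():
    return generate_fsu()


@pytest.fixture(scope="session")
def ct_image(specimen):
    """Noise-free CT-like image at clinical-like grid geometry."""
    return voxelize_ct(specimen, noise_sd_intensity=0.0)


@pytest.fixture(scope="session")
def ct_meshes(ct_image):
    bone, _ = separate_cement(ct_image, BONE_BAND, CEMENT_BAND)
    caudal_mask, cranial_mask = split_vertebrae(bone)
    return mask_to_mesh(caudal_mask), mask_to_mesh(cranial_mask)


@pytest.fixture(scope="session")
def pipeline_result(specimen):
    """One full-fidelity pipeline run (DIC noise at its 2 um default)."""
    return run_phantom_specimen(
        specimen, seed=5, config=PipelineConfig(reconstruct=False)
    )


@pytest.fixture(scope="session")
def fast_config():
    """Scaled-down pipeline configuration for determinism/IO tests."""
    return PipelineConfig(
        method="voxel",
        voxel_size=0.4,
        reconstruct=False,
        points_per_mm2=2.0,
        icp_max_points=1000,
    )


@pytest.fixture(scope="session")
def fast_ct_kwargs():
    return dict(ct_noise_sd=25.0)


def fast_phantom_run(spec, seed, config, **kw):
    return run_phantom_specimen(spec, seed=seed, config=config, **kw)


# ---------------------------------------------------------------------------
# analytic point-in-solid oracle for the phantom primitives
# ---------------------------------------------------------------------------


def _inside_vertebra(params: PhantomParams, pts: np.ndarray, zone: str) -> np.ndarray:
    """Point-in-vertebra by plain arithmetic on the primitive layout."""
    D, W, H = params.vertebra_body_size
    W2 = W / 2
    ch, bh, bi = params.chamfer, params.bevel_height, params.bevel_inset
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]

    # body: chamfered hexagon footprint, linearly inset over the bevels
    inset = np.where(
        z < bh,
        bi * (1.0 - z / bh),
        np.where(z > H - bh, bi * (1.0 - (H - z) / bh), 0.0),
    )
    hw = W2 - inset
    body = (
        (z > 0)
        & (z < H)
        & (x < D)
        & (x > inset)
        & (np.abs(y) < hw)
        & ((x - inset) + (hw - np.abs(y)) > ch)
    )

    pd_, ph_, pw = params.pedicle_depth, params.pedicle_height, params.pedicle_width
    ad, ah = params.arch_depth, params.arch_height
    t = np.radians(params.pedicle_tilt)
    half_y = (pw * np.cos(t) + ph_ * np.sin(t)) / 2
    half_z = (ph_ * np.cos(t) + pw * np.sin(t)) / 2
    if zone == "top":
        pz_c, az0, az1 = H - half_z, H - ah, H
    else:
        pz_c, az0, az1 = half_z, 0.0, ah
    pedicles = np.zeros(len(pts), dtype=bool)
    for sign in (1.0, -1.0):
        dx = x - (D + pd_ / 2)
        dy = y - sign * (W2 - half_y)
        dz = z - pz_c
        # undo the mirrored tilt about x
        a = -sign * t
        dy_r = dy * np.cos(a) - dz * np.sin(a)
        dz_r = dy * np.sin(a) + dz * np.cos(a)
        pedicles |= (
            (np.abs(dx) < pd_ / 2) & (np.abs(dy_r) < pw / 2) & (np.abs(dz_r) < ph_ / 2)
        )
    slope = np.tan(np.radians(params.arch_slope)) * (1.0 if zone == "bottom" else -1.0)
    z_shift = slope * (x - (D + pd_))
    arch = (
        (x > D + pd_)
        & (x < D + pd_ + ad)
        & (np.abs(y) < W2)
        & (z > az0 + z_shift)
        & (z < az1 + z_shift)
    )
    return body | pedicles | arch


def analytic_inside(
    specimen, pts: np.ndarray, part: str, pose=None
) -> np.ndarray:
    """Independent inside test for ``part`` in (caudal, cranial, cement).

    ``pose`` (a RigidTransform) optionally maps the canonical cranial
    vertebra into a true pose; points are pulled back into the canonical
    frame before the arithmetic test.
    """
    params = specimen.params
    pts = np.asarray(pts, dtype=float).reshape(-1, 3)
    if pose is not None:
        pts = pose.inverse().apply(pts)
    D, W, H = params.vertebra_body_size
    if part == "caudal":
        return _inside_vertebra(params, pts, "top")
    if part == "cranial":
        local = pts - np.array([0.0, 0.0, H + params.gap_discoplasty])
        return _inside_vertebra(params, local, "bottom")
    if part == "cement":
        gap = params.gap_discoplasty
        side = np.sqrt(params.cement_volume / gap)
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        return (
            (np.abs(x - D / 2) < side / 2)
            & (np.abs(y) < side / 2)
            & (z > H)
            & (z < H + gap)
        )
    raise ValueError(part)


def analytic_inside_grid(specimen, xs, ys, zs, parts=("caudal", "cranial")) -> np.ndarray:
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    out = np.zeros(len(pts), dtype=bool)
    for part in parts:
        out |= analytic_inside(specimen, pts, part)
    return out.reshape(X.shape)
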