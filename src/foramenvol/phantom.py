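"""Synthetic spine phantoms with known ground truth.

A phantom functional spinal unit (FSU) is built from simple watertight
primitives: each vertebra is a chamfered/beveled prismatic body plus two
pedicle bars and a posterior arch, so that two stacked vertebrae enclose a
genuine transverse tunnel — the neuroforamen — running along +y through both
foramina and the canal.  The disc space is empty (nucleotomy surrogate); the
discoplasty condition is represented by a distracted relative pose and a
cement block filling the disc space.  Loaded flexion/extension poses are
imposed as relative rotations of the cranial vertebra about the medio-lateral
axis through the disc center: the measurement chain works on geometry at peak
load, so pose is the sufficient statistic for the (out-of-scope) loading rig.

Frame convention: one global right-handed frame in mm; +x posterior,
+y medio-lateral (the foramen axis), +z cranial.  The canonical frame is the
CT-like pose: the specimen as scanned after discoplasty (distracted gap,
cement in place, no motion).

Everything is deterministic under (params, seed); DIC-like patches carry
positional Gaussian noise whose default scale matches the ~2 um accuracy of
a validated DIC system.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
import yaml

from .mesh import PointCloud, SurfaceMesh, new_mesh, save_mesh, save_point_cloud_ply
from .registration import RigidTransform
from .segmentation import VolumetricImage, save_image
from .volumetry import ForamenMeasurement, measure_specimen

__all__ = [
    "CONDITIONS",
    "MOTIONS",
    "PhantomParams",
    "SyntheticSpecimen",
    "generate_fsu",
    "sample_dic_patch",
    "voxelize_ct",
    "export_specimen",
]

CONDITIONS = ("nucleotomy", "discoplasty")
MOTIONS = ("flexion", "extension")


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and pose parameters of one synthetic FSU (lengths in mm).

    ``vertebra_body_size`` is (depth x, width y, height z).  The discoplasty
    condition adds ``distraction_discoplasty`` of extra disc height — the
    cement spacer effect.  Motion angles are relative vertebral rotations
    about the medio-lateral axis through the disc center.  The default cement
    volume matches a typical clinically injected amount (~4.6 ml).
    """

    disc_height: float = 8.0
    distraction_discoplasty: float = 3.0
    flexion_angle: float = 5.0
    extension_angle: float = 4.0
    vertebra_body_size: tuple[float, float, float] = (34.0, 44.0, 26.0)
    pedicle_depth: float = 10.0
    pedicle_height: float = 14.0
    pedicle_width: float = 9.0
    pedicle_tilt: float = 12.0
    arch_depth: float = 7.0
    arch_height: float = 18.0
    arch_slope: float = 8.0
    chamfer: float = 6.0
    bevel_height: float = 3.0
    bevel_inset: float = 2.5
    cement_volume: float = 4575.0
    noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        D, W, H = self.vertebra_body_size
        lengths = {
            "disc_height": self.disc_height,
            "vertebra depth": D,
            "vertebra width": W,
            "vertebra height": H,
            "pedicle_depth": self.pedicle_depth,
            "pedicle_height": self.pedicle_height,
            "pedicle_width": self.pedicle_width,
            "arch_depth": self.arch_depth,
            "arch_height": self.arch_height,
            "chamfer": self.chamfer,
            "bevel_height": self.bevel_height,
            "bevel_inset": self.bevel_inset,
            "cement_volume": self.cement_volume,
        }
        for name, v in lengths.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive (got {v})")
        if self.distraction_discoplasty < 0:
            raise ValueError("distraction_discoplasty must be >= 0")
        for name, a in (
            ("flexion_angle", self.flexion_angle),
            ("extension_angle", self.extension_angle),
        ):
            if not 0.0 <= a < 45.0:
                raise ValueError(f"{name} must be in [0, 45) degrees (got {a})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.pedicle_tilt < 30.0:
            raise ValueError("pedicle_tilt must be in [0, 30) degrees")
        if not 0.0 <= self.arch_slope < 30.0:
            raise ValueError("arch_slope must be in [0, 30) degrees")
        # geometric feasibility of the foramen-enclosing arch; the tilted
        # pedicle's bounding extents decide the fit
        t = math.radians(self.pedicle_tilt)
        ped_y = self.pedicle_width * math.cos(t) + self.pedicle_height * math.sin(t)
        ped_z = self.pedicle_height * math.cos(t) + self.pedicle_width * math.sin(t)
        if 2 * ped_y >= W:
            raise ValueError(
                "pedicles leave no canal gap: their lateral extent must be < body width"
            )
        if ped_z >= H:
            raise ValueError("pedicle_height must be smaller than the body height")
        if self.arch_height >= H:
            raise ValueError("arch_height must be smaller than the body height")
        if self.arch_height < self.pedicle_height:
            raise ValueError(
                "arch thinner than the pedicle span: arch_height must be "
                ">= pedicle_height so the arch closes the foramen posteriorly"
            )
        if 2 * self.bevel_height >= H or self.chamfer >= min(D, W) / 2:
            raise ValueError("bevel/chamfer too large for the body size")
        gap_d = self.disc_height + self.distraction_discoplasty
        side = math.sqrt(self.cement_volume / gap_d)
        # the cement block must sit on the (inset, chamfered) endplate face
        if side > min(D - 2 * self.bevel_inset, W - 2 * (self.bevel_inset + self.chamfer)):
            raise ValueError(
                f"cement_volume {self.cement_volume} mm^3 does not fit the disc "
                f"space footprint (needs a {side:.1f} mm square)"
            )
        max_lever = D / 2 + self.pedicle_depth + self.arch_depth
        max_dip = math.sin(math.radians(max(self.flexion_angle, self.extension_angle)))
        if max_dip * max_lever >= self.disc_height:
            raise ValueError(
                "motion angles would make the vertebrae interpenetrate at the "
                "nucleotomy disc height"
            )

    @property
    def gap_nucleotomy(self) -> float:
        return self.disc_height

    @property
    def gap_discoplasty(self) -> float:
        return self.disc_height + self.distraction_discoplasty


# ---------------------------------------------------------------------------
# primitive builders
# ---------------------------------------------------------------------------


def _prismoid(poly_bottom: np.ndarray, z0: float, poly_top: np.ndarray, z1: float) -> SurfaceMesh:
    """Watertight solid between two convex CCW polygons with equal vertex count."""
    nb = len(poly_bottom)
    bot = np.column_stack([poly_bottom, np.full(nb, z0)])
    top = np.column_stack([poly_top, np.full(nb, z1)])
    verts = np.vstack([bot, top])
    faces = []
    for i in range(1, nb - 1):  # caps by fan (convex)
        faces.append([0, i + 1, i])  # bottom, normal -z
        faces.append([nb, nb + i, nb + i + 1])  # top, normal +z
    for i in range(nb):  # sides
        j = (i + 1) % nb
        faces.append([i, j, nb + j])
        faces.append([i, nb + j, nb + i])
    return new_mesh(verts, np.array(faces, dtype=np.int64))


def _yprism(poly_xz: np.ndarray, y0: float, y1: float) -> SurfaceMesh:
    """Watertight solid: convex CCW polygon in the x-z plane extruded along y."""
    n = len(poly_xz)
    near = np.column_stack([poly_xz[:, 0], np.full(n, y0), poly_xz[:, 1]])
    far = np.column_stack([poly_xz[:, 0], np.full(n, y1), poly_xz[:, 1]])
    verts = np.vstack([near, far])
    faces = []
    for i in range(1, n - 1):
        # CCW in (x, z) means the +y side sees the polygon clockwise
        faces.append([0, i, i + 1])  # y0 cap, normal -y
        faces.append([n, n + i + 1, n + i])  # y1 cap, normal +y
    for i in range(n):
        j = (i + 1) % n
        faces.append([i, n + j, j])
        faces.append([i, n + i, n + j])
    return new_mesh(verts, np.array(faces, dtype=np.int64))


def _box(x0, x1, y0, y1, z0, z1) -> SurfaceMesh:
    b = trimesh.creation.box(extents=(x1 - x0, y1 - y0, z1 - z0))
    b.apply_translation(((x0 + x1) / 2, (y0 + y1) / 2, (z0 + z1) / 2))
    return new_mesh(b.vertices.view(np.ndarray), b.faces.view(np.ndarray))


def _body_footprint(x_front: float, x_back: float, halfwidth: float, ch: float) -> np.ndarray:
    """CCW hexagon: rectangle with the two anterior corners chamfered."""
    return np.array(
        [
            (x_front + ch, -halfwidth),
            (x_back, -halfwidth),
            (x_back, halfwidth),
            (x_front + ch, halfwidth),
            (x_front, halfwidth - ch),
            (x_front, -halfwidth + ch),
        ]
    )


def _vertebra(params: PhantomParams, pedicle_zone: str) -> SurfaceMesh:
    """One vertebra at z in [0, H]; pedicles/arch flush with top or bottom."""
    D, W, H = params.vertebra_body_size
    W2 = W / 2
    ch, bh, bi = params.chamfer, params.bevel_height, params.bevel_inset
    outer = _body_footprint(0.0, D, W2, ch)
    inner = _body_footprint(bi, D, W2 - bi, ch)
    parts = [
        _prismoid(inner, 0.0, outer, bh),
        _prismoid(outer, bh, outer, H - bh),
        _prismoid(outer, H - bh, inner, H),
    ]
    pd, ph, pw = params.pedicle_depth, params.pedicle_height, params.pedicle_width
    ad, ah = params.arch_depth, params.arch_height
    # pedicle bars are tilted (mirrored) about the antero-posterior axis so no
    # foramen-bounding face is parallel to a scan grid plane
    t = math.radians(params.pedicle_tilt)
    half_y = (pw * math.cos(t) + ph * math.sin(t)) / 2
    half_z = (ph * math.cos(t) + pw * math.sin(t)) / 2
    if pedicle_zone == "top":
        pz_c = H - half_z
        az0, az1 = H - ah, H
    else:
        pz_c = half_z
        az0, az1 = 0.0, ah
    for sign in (1.0, -1.0):
        bar = trimesh.creation.box(extents=(pd, pw, ph))
        bar.apply_transform(
            trimesh.transformations.rotation_matrix(sign * t, (1.0, 0.0, 0.0))
        )
        bar.apply_translation((D + pd / 2, sign * (W2 - half_y), pz_c))
        parts.append(new_mesh(bar.vertices.view(np.ndarray), bar.faces.view(np.ndarray)))
    # arch: parallelogram cross-section; the roof/floor slope away from the
    # foramen (laminae are not horizontal), again avoiding grid-plane faces
    drop = math.tan(math.radians(params.arch_slope)) * ad
    x0, x1 = D + pd, D + pd + ad
    if pedicle_zone == "top":
        poly = np.array(
            [[x0, az0], [x1, az0 - drop], [x1, az1 - drop], [x0, az1]], dtype=float
        )
    else:
        poly = np.array(
            [[x0, az0], [x1, az0 + drop], [x1, az1 + drop], [x0, az1]], dtype=float
        )
    parts.append(_yprism(poly, -W2, W2))
    return trimesh.util.concatenate(parts)


# ---------------------------------------------------------------------------
# specimen
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpecimen:
    """One phantom FSU in the canonical CT-like frame with known true poses.

    ``true_poses[(condition, motion)]`` maps the canonical cranial vertebra
    into its pose relative to the (anchored) caudal vertebra; motions include
    ``"neutral"``.  The caudal mesh never moves.
    """

    params: PhantomParams
    caudal_mesh: SurfaceMesh
    cranial_mesh: SurfaceMesh
    cement_mesh: SurfaceMesh
    foramen_axis_point: np.ndarray
    foramen_axis_direction: np.ndarray
    cylinder_radius: float
    true_poses: dict[tuple[str, str], RigidTransform]
    true_ct_image: VolumetricImage | None = None

    def true_pose(self, condition: str, motion: str) -> RigidTransform:
        return self.true_poses[(condition, motion)]

    def posed_cranial(self, condition: str, motion: str) -> SurfaceMesh:
        m = self.cranial_mesh.copy()
        m.apply_transform(self.true_pose(condition, motion).matrix)
        return m

    def posed_meshes(self, condition: str, motion: str) -> list[SurfaceMesh]:
        return [self.caudal_mesh.copy(), self.posed_cranial(condition, motion)]

    def disc_surrogate(self, condition: str) -> SurfaceMesh:
        """Annulus stand-in spanning the disc space, attached to the caudal frame."""
        D, W, H = self.params.vertebra_body_size
        gap = (
            self.params.gap_nucleotomy
            if condition == "nucleotomy"
            else self.params.gap_discoplasty
        )
        inset = self.params.chamfer + self.params.bevel_inset
        return _box(inset, D - 2.0, -W / 2 + inset, W / 2 - inset, H, H + gap)

    def ground_truth_measurement(
        self, motion: str, method: str = "exact", voxel_size: float = 0.2
    ) -> ForamenMeasurement:
        """Foramen measurement on the true posed meshes (no registration)."""
        return measure_specimen(
            self.posed_meshes("nucleotomy", motion),
            self.posed_meshes("discoplasty", motion),
            self.foramen_axis_point,
            self.foramen_axis_direction,
            self.cylinder_radius,
            motion,
            method=method,
            voxel_size=voxel_size,
        )


def _true_poses(params: PhantomParams) -> dict[tuple[str, str], RigidTransform]:
    D, _, H = params.vertebra_body_size
    pivot_x = D / 2
    angles = {
        "neutral": 0.0,
        "flexion": -params.flexion_angle,
        "extension": params.extension_angle,
    }
    poses: dict[tuple[str, str], RigidTransform] = {}
    drop = RigidTransform.from_translation(
        (0.0, 0.0, -params.distraction_discoplasty)
    )
    for motion, angle in angles.items():
        pivot_d = np.array([pivot_x, 0.0, H + params.gap_discoplasty / 2])
        poses[("discoplasty", motion)] = RigidTransform.about_axis(
            (0, 1, 0), angle, center=pivot_d
        )
        pivot_n = np.array([pivot_x, 0.0, H + params.gap_nucleotomy / 2])
        rot_n = RigidTransform.about_axis((0, 1, 0), angle, center=pivot_n)
        poses[("nucleotomy", motion)] = rot_n.compose(drop)
    return poses


def generate_fsu(params: PhantomParams | None = None) -> SyntheticSpecimen:
    """Build a synthetic FSU with ground-truth poses, axis and cylinder radius.

    The canonical (CT) frame holds the discoplasty condition at neutral
    motion; the nucleotomy poses remove the distraction.  The foramen axis
    runs along +y through the pedicle channel, centered on the discoplasty
    tunnel; the cylinder radius is set to cover the tunnel in its most open
    pose, so the cylinder fills the foramen in both conditions.
    """
    if params is None:
        params = PhantomParams()
    D, _, H = params.vertebra_body_size
    caudal = _vertebra(params, "top")
    cranial = _vertebra(params, "bottom")
    cranial.apply_translation((0.0, 0.0, H + params.gap_discoplasty))
    gap_d = params.gap_discoplasty
    side = math.sqrt(params.cement_volume / gap_d)
    cx = D / 2
    cement = _box(cx - side / 2, cx + side / 2, -side / 2, side / 2, H, H + gap_d)

    axis_point = np.array([D + params.pedicle_depth / 2, 0.0, H + gap_d / 2])
    max_angle = max(params.flexion_angle, params.extension_angle)
    lever = D / 2 + params.pedicle_depth + params.arch_depth
    opening = math.sin(math.radians(max_angle)) * lever
    radius = 0.5 * (gap_d + opening) + 1.0

    return SyntheticSpecimen(
        params=params,
        caudal_mesh=caudal,
        cranial_mesh=cranial,
        cement_mesh=cement,
        foramen_axis_point=axis_point,
        foramen_axis_direction=np.array([0.0, 1.0, 0.0]),
        cylinder_radius=radius,
        true_poses=_true_poses(params),
    )


# ---------------------------------------------------------------------------
# DIC-like patch sampling
# ---------------------------------------------------------------------------


def sample_dic_patch(
    specimen: SyntheticSpecimen,
    condition: str,
    motion: str,
    coverage_fraction: float = 1.0,
    noise_sd: float | None = None,
    seed: int = 0,
    points_per_mm2: float = 4.0,
    view_direction: np.ndarray = (0.0, 1.0, 0.0),
) -> PointCloud:
    """Sample a lateral DIC-like surface patch of the posed specimen.

    Points are drawn from the lateral-facing portion of the posed caudal and
    cranial surfaces plus a disc-region surrogate (visibility: outward face
    normal within 90 degrees of the view direction), thinned to
    ``coverage_fraction`` and perturbed by isotropic Gaussian noise.  The
    per-point provenance label (caudal/cranial/disc) is retained for patch
    selection and testing but is never consumed by registration itself.
    """
    if not 0.0 < coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must be in (0, 1]")
    if noise_sd is None:
        noise_sd = specimen.params.noise_sd
    view = np.asarray(view_direction, dtype=float)
    view = view / np.linalg.norm(view)
    parts = {
        "caudal": specimen.caudal_mesh,
        "cranial": specimen.posed_cranial(condition, motion),
        "disc": specimen.disc_surrogate(condition),
    }
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    part_seeds = rng.integers(0, 2**31 - 1, size=len(parts) + 1)
    all_pts, all_labels = [], []
    for (name, mesh), s in zip(parts.items(), part_seeds):
        n = max(1, int(round(mesh.area * points_per_mm2)))
        pts, fidx = trimesh.sample.sample_surface(mesh, n, seed=int(s))
        visible = mesh.face_normals[fidx] @ view > 1e-9
        pts = pts[visible]
        if coverage_fraction < 1.0 and len(pts):
            keep = np.random.default_rng(int(s) + 1).random(len(pts)) < coverage_fraction
            pts = pts[keep]
        if name in ("caudal", "cranial") and len(pts) == 0:
            raise ValueError(
                f"no visible {name} surface from view direction {tuple(view)}"
            )
        all_pts.append(pts)
        all_labels.append(np.full(len(pts), name))
    pts = np.vstack(all_pts)
    labels = np.concatenate(all_labels)
    if noise_sd > 0:
        noise_rng = np.random.default_rng(int(part_seeds[-1]))
        pts = pts + noise_rng.normal(0.0, noise_sd, size=pts.shape)
    return PointCloud(pts, None, labels)


# ---------------------------------------------------------------------------
# CT-like voxelization
# ---------------------------------------------------------------------------


def voxelize_ct(
    specimen: SyntheticSpecimen,
    spacing: tuple[float, float, float] = (0.214, 0.214, 0.3),
    bone_intensity: float = 1200.0,
    cement_intensity: float = 2000.0,
    background_intensity: float = 0.0,
    noise_sd_intensity: float = 25.0,
    seed: int = 0,
    margin: float = 4.0,
    include_cement: bool = True,
) -> VolumetricImage:
    """CT-like image of the canonical (discoplasty, neutral) specimen pose.

    Voxels whose centers fall inside a vertebra get ``bone_intensity``, inside
    the cement block ``cement_intensity``, else ``background_intensity``, plus
    additive Gaussian intensity noise.  The default grid geometry mirrors a
    clinical acquisition (0.214 mm in-plane pixels, 0.3 mm slices); intensity
    defaults keep bone and background on opposite sides of the 700 HU
    threshold with many noise SDs of headroom.
    """
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    if specimen.params.pedicle_width < 2 * spacing.max():
        warnings.warn(
            "voxel spacing so coarse that a pedicle spans < 2 voxels; "
            "segmentation fidelity is not guaranteed"
        )
    meshes = [specimen.caudal_mesh, specimen.cranial_mesh]
    if include_cement:
        meshes.append(specimen.cement_mesh)
    lo = np.min([m.bounds[0] for m in meshes], axis=0) - margin
    hi = np.max([m.bounds[1] for m in meshes], axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    # sub-voxel origin shift so voxel centers never coincide with the flat
    # faces of the primitives (removes inside/outside boundary ambiguity)
    origin = lo - 0.1234567 * spacing
    xs, ys, zs = (origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3))
    from .mesh import grid_inside_mesh

    bone = grid_inside_mesh(specimen.caudal_mesh, xs, ys, zs)
    bone |= grid_inside_mesh(specimen.cranial_mesh, xs, ys, zs)
    data = np.full(tuple(shape), float(background_intensity), dtype=np.float32)
    data[bone] = bone_intensity
    if include_cement:
        cem = grid_inside_mesh(specimen.cement_mesh, xs, ys, zs)
        data[cem] = cement_intensity
    if noise_sd_intensity > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd_intensity, size=data.shape).astype(
            np.float32
        )
    return VolumetricImage(data, spacing, origin)


def export_specimen(
    specimen: SyntheticSpecimen,
    directory: str | Path,
    ct_image: VolumetricImage | None = None,
    patches: dict[str, PointCloud] | None = None,
) -> Path:
    """Write meshes (STL), optional image (NIfTI), patches (PLY) and a YAML manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_mesh(specimen.caudal_mesh, directory / "caudal.stl")
    save_mesh(specimen.cranial_mesh, directory / "cranial.stl")
    save_mesh(specimen.cement_mesh, directory / "cement.stl")
    if ct_image is not None:
        save_image(ct_image, directory / "ct.nii.gz")
    if patches:
        for name, cloud in patches.items():
            save_point_cloud_ply(cloud, directory / f"patch_{name}.ply")
    manifest = {
        "foramen_axis": {
            "point": [float(v) for v in specimen.foramen_axis_point],
            "direction": [float(v) for v in specimen.foramen_axis_direction],
        },
        "cylinder_radius": float(specimen.cylinder_radius),
        "seed": int(specimen.params.seed),
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(specimen.params).items()
        },
        "true_poses": {
            f"{cond}/{mot}": [float(x) for x in pose.matrix.ravel()]  # row-major 4x4
            for (cond, mot), pose in sorted(specimen.true_poses.items())
        },
    }
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return directory
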