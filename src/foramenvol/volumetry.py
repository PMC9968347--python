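"""Free neuroforaminal volume by the cylinder-subtraction method.

A measurement cylinder (default 90 mm long) is aligned with the transverse
axis passing through both neuroforamina; its radius is chosen per specimen
and motion so the cylinder fills the foramen in both disc conditions.  The
free volume is the cylinder volume minus the volume of its intersection with
the two vertebrae, computed for the nucleotomy (pre-operative surrogate) and
discoplasty conditions with the *same* cylinder; the discoplasty-induced
change is dV = V_discoplasty - V_nucleotomy.

Two volume back-ends are provided:

``exact``
    Mesh-Boolean volume by slicing: the solid cross sections of the vertebrae
    are intersected with the cylinder disc slice-by-slice along the axis
    (shapely polygon Booleans) and integrated by the midpoint rule.  Requires
    watertight meshes.
``voxel``
    Rasterizes cylinder and vertebrae on a lattice (default 0.2 mm) and
    counts cylinder voxels not inside any vertebra.  Independent of the exact
    path; used as its oracle.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import shapely
import shapely.geometry
from shapely.ops import unary_union
import trimesh

from .mesh import MeshSlicer, SurfaceMesh, grid_inside_mesh, mesh_volume

__all__ = [
    "MeasurementCylinder",
    "ForamenMeasurement",
    "build_cylinder",
    "free_foramen_volume",
    "measure_specimen",
    "suggest_radius",
]

log = logging.getLogger(__name__)


def _axis_frame(axis_point: np.ndarray, axis_direction: np.ndarray) -> np.ndarray:
    """4x4 world -> cylinder-frame transform (axis maps to +z through origin)."""
    d = np.asarray(axis_direction, dtype=float)
    d = d / np.linalg.norm(d)
    # any vector not parallel to d
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, a)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    R = np.vstack([u, v, d])
    m = np.eye(4)
    m[:3, :3] = R
    m[:3, 3] = -R @ np.asarray(axis_point, dtype=float)
    return m


@dataclass
class MeasurementCylinder:
    """Cylinder spanning both foramina along the transverse axis."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius: float
    length: float = 90.0

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, dtype=float).reshape(3)
        d = np.asarray(self.axis_direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis direction must be a non-zero vector")
        self.axis_direction = d / n
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")
        if self.length <= 0:
            raise ValueError("cylinder length must be positive")

    @property
    def volume(self) -> float:
        return math.pi * self.radius**2 * self.length

    def to_mesh(self, segments: int = 256) -> SurfaceMesh:
        return build_cylinder(
            self.axis_point, self.axis_direction, self.radius, self.length, segments
        )

    def world_to_cylinder(self) -> np.ndarray:
        return _axis_frame(self.axis_point, self.axis_direction)


def build_cylinder(
    axis_point: np.ndarray,
    axis_direction: np.ndarray,
    radius: float,
    length: float = 90.0,
    segments: int = 256,
) -> SurfaceMesh:
    """Watertight capped cylinder centered on the axis point."""
    if radius <= 0:
        raise ValueError("cylinder radius must be positive")
    if length <= 0:
        raise ValueError("cylinder length must be positive")
    if segments < 32:
        raise ValueError("at least 32 segments required")
    mesh = trimesh.creation.cylinder(radius=radius, height=length, sections=segments)
    world_from_cyl = np.linalg.inv(_axis_frame(axis_point, axis_direction))
    mesh.apply_transform(world_from_cyl)
    return mesh


@dataclass
class ForamenMeasurement:
    """Free foramen volumes for one specimen x motion and their change."""

    v_nucleotomy: float
    v_discoplasty: float
    delta_v: float
    motion: str
    method: str
    voxel_size: float | None = None

    def __post_init__(self) -> None:
        if not math.isclose(
            self.delta_v, self.v_discoplasty - self.v_nucleotomy, rel_tol=0, abs_tol=1e-9
        ):
            raise ValueError("delta_v must equal v_discoplasty - v_nucleotomy")


def _free_volume_sliced(
    cyl: MeasurementCylinder, meshes: list[SurfaceMesh], slice_step: float
) -> float:
    """Cylinder minus cylinder ∩ union(meshes) by midpoint-rule slicing.

    The cylinder cross section is one high-resolution polygon used both for
    the total volume and for the per-slice occlusions, so a cylinder fully
    enclosed in bone yields exactly zero.
    """
    w2c = cyl.world_to_cylinder()
    slicers = []
    zmin, zmax = cyl.length / 2, -cyl.length / 2
    for m in meshes:
        mm = m.copy()
        mm.apply_transform(w2c)
        slicers.append(MeshSlicer(mm))
        zmin = min(zmin, mm.bounds[0, 2])
        zmax = max(zmax, mm.bounds[1, 2])
    disc = shapely.geometry.Point(0.0, 0.0).buffer(cyl.radius, quad_segs=256)
    total = disc.area * cyl.length
    z0 = max(-cyl.length / 2, zmin)
    z1 = min(cyl.length / 2, zmax)
    if z1 <= z0:
        return total
    n = max(1, int(math.ceil((z1 - z0) / slice_step)))
    dz = (z1 - z0) / n
    occluded = 0.0
    for j in range(n):
        z = z0 + (j + 0.5) * dz
        sections = [s.region(z) for s in slicers]
        solids = [s for s in sections if not s.is_empty]
        if not solids:
            continue
        occluded += unary_union(solids).intersection(disc).area * dz
    return max(0.0, total - occluded)


def _free_volume_voxel(
    cyl: MeasurementCylinder, meshes: list[SurfaceMesh], voxel_size: float
) -> float:
    w2c = cyl.world_to_cylinder()
    h = voxel_size
    r, L = cyl.radius, cyl.length
    # sub-cell lattice shift in the disc plane avoids the systematic counting
    # bias of a circle exactly aligned with the lattice
    xs = np.arange(-r + h / 2, r, h) + 0.1234567 * h
    ys = xs.copy()
    zs = np.arange(-L / 2 + h / 2, L / 2, h)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    in_disc = (X**2 + Y**2) < r**2
    occ = np.zeros((len(xs), len(ys), len(zs)), dtype=bool)
    for m in meshes:
        mm = m.copy()
        mm.apply_transform(w2c)
        occ |= grid_inside_mesh(mm, xs, ys, zs)
    free = in_disc[:, :, None] & ~occ
    return float(np.count_nonzero(free)) * h**3


def free_foramen_volume(
    cylinder: MeasurementCylinder,
    vertebrae: list[SurfaceMesh],
    method: str = "exact",
    voxel_size: float = 0.2,
    slice_step: float = 0.1,
) -> float:
    """Free volume: cylinder minus its intersection with the vertebrae (mm^3).

    The vertebrae are subtracted jointly (their union), so overlapping
    shells are not double-counted.  ``method='exact'`` requires watertight
    meshes and falls back to the voxel method with a logged warning if the
    slice Booleans fail; ``method='voxel'`` counts lattice cells of size
    ``voxel_size``.
    """
    if method not in ("exact", "voxel"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exact":
        for m in vertebrae:
            if not m.is_watertight:
                raise ValueError(
                    "non-watertight vertebra mesh; use method='voxel' instead"
                )
        try:
            return _free_volume_sliced(cylinder, list(vertebrae), slice_step)
        except Exception as exc:  # geometric edge case -> voxel fallback
            log.warning("exact Boolean failed (%s); falling back to voxel method", exc)
            warnings.warn(f"exact Boolean failed ({exc}); using voxel fallback")
    return _free_volume_voxel(cylinder, list(vertebrae), voxel_size)


def measure_specimen(
    nucleotomy_vertebrae: list[SurfaceMesh],
    discoplasty_vertebrae: list[SurfaceMesh],
    axis_point: np.ndarray,
    axis_direction: np.ndarray,
    radius: float,
    motion: str,
    method: str = "exact",
    voxel_size: float = 0.2,
    length: float = 90.0,
    slice_step: float = 0.1,
) -> ForamenMeasurement:
    """Free foramen volume in both conditions and the discoplasty change.

    The same cylinder (axis, radius, length) is used for both conditions of
    the comparison — the radius is a per-specimen, per-motion property shared
    across conditions, never re-fit per condition.
    """
    cyl = MeasurementCylinder(axis_point, axis_direction, radius, length)
    v_n = free_foramen_volume(cyl, nucleotomy_vertebrae, method, voxel_size, slice_step)
    v_d = free_foramen_volume(cyl, discoplasty_vertebrae, method, voxel_size, slice_step)
    return ForamenMeasurement(
        v_nucleotomy=v_n,
        v_discoplasty=v_d,
        delta_v=v_d - v_n,
        motion=motion,
        method=method,
        voxel_size=voxel_size if method == "voxel" else None,
    )


def suggest_radius(
    axis_point: np.ndarray,
    axis_direction: np.ndarray,
    vertebrae_by_condition: dict[str, list[SurfaceMesh]],
    margin: float = 0.0,
) -> float:
    """Heuristic cylinder radius: largest axis-to-bone clearance across conditions.

    For each condition the clearance is the smallest distance from the
    foramen axis line to any vertebra vertex; taking the maximum over
    conditions yields a cylinder that touches bone in the roomier condition
    and overfills the tighter one.  This is a starting point, not an
    anatomical criterion — review per specimen.
    """
    p = np.asarray(axis_point, dtype=float)
    d = np.asarray(axis_direction, dtype=float)
    d = d / np.linalg.norm(d)
    clearances = []
    for meshes in vertebrae_by_condition.values():
        dmin = np.inf
        for m in meshes:
            v = m.vertices.view(np.ndarray) - p
            perp = v - np.outer(v @ d, d)
            dmin = min(dmin, float(np.linalg.norm(perp, axis=1).min()))
        clearances.append(dmin)
    return max(clearances) + margin
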