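"""Rigid registration of DIC surface patches onto CT-derived vertebra surfaces.

The premise of the measurement chain is that each vertebra moves as a rigid
body: a partial surface patch acquired in the loaded experimental pose can
therefore be registered onto the CT-derived surface of the same vertebra by a
proper rotation plus translation, and the inverse of that registration places
the CT geometry into the experimental pose.  The caudal vertebra anchors the
composed pose; the relative cranial-versus-caudal transform is the kinematic
quantity of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mesh import PointCloud, SurfaceMesh, _MeshDistanceQuery

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "PosedPair",
    "landmark_register",
    "icp_register",
    "principal_axes_init",
    "pose_in_experimental_frame",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation between right-handed mm frames."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal (R^T R = I +- 1e-9)")
        if np.linalg.det(R) < 0.0:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        m = np.asarray(matrix, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def about_axis(
        cls, axis: np.ndarray, angle_deg: float, center: np.ndarray | None = None
    ) -> "RigidTransform":
        """Rotation by ``angle_deg`` about a (possibly offset) axis."""
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        a = math.radians(angle_deg)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + math.sin(a) * K + (1.0 - math.cos(a)) * (K @ K)
        t = np.zeros(3)
        if center is not None:
            c = np.asarray(center, dtype=float)
            t = c - R @ c
        return cls(R, t)

    @classmethod
    def from_translation(cls, t: np.ndarray) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    @property
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation (deg)."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))

    def distance_to(self, other: "RigidTransform") -> tuple[float, float]:
        """(rotation angle deg, translation mm) of ``self^-1 @ other``."""
        d = self.inverse().compose(other)
        return d.rotation_angle_deg, float(np.linalg.norm(d.translation))


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rmse: float
    iterations: int
    converged: bool
    rmse_history: list[float] | None = None

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


def landmark_register(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform (no scaling) mapping paired landmarks.

    Kabsch/Umeyama solution minimizing sum ||T(s_i) - t_i||^2; exact (zero
    residual) when the correspondences are exactly rigid.  Requires >= 3
    non-collinear points.
    """
    src = np.asarray(source_points, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target_points, dtype=float).reshape(-1, 3)
    if len(src) != len(tgt):
        raise ValueError("point counts must match")
    if len(src) < 3:
        raise ValueError("at least 3 correspondences required")
    sc = src - src.mean(axis=0)
    sv = np.linalg.svd(sc, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1e-12):
        raise ValueError("source points are collinear; rotation is under-determined")
    tc = tgt - tgt.mean(axis=0)
    H = sc.T @ tc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = tgt.mean(axis=0) - R @ src.mean(axis=0)
    return RigidTransform(R, t)


def _as_points(moving) -> np.ndarray:
    if isinstance(moving, PointCloud):
        return moving.points
    if isinstance(moving, SurfaceMesh):
        return moving.vertices.view(np.ndarray)
    return np.asarray(moving, dtype=float).reshape(-1, 3)


def icp_register(
    moving,
    fixed: SurfaceMesh,
    init: RigidTransform | None = None,
    max_iterations: int = 400,
    convergence_tol: float = 1e-6,
    surface_query: "_MeshDistanceQuery | None" = None,
) -> RegistrationResult:
    """Iterative closest point, point-to-surface, moving cloud onto fixed mesh.

    Each iteration pairs the transformed moving points with their exact
    closest points on the fixed surface and re-solves the rigid least-squares
    problem from the *original* points; the resulting increment is then
    extrapolated (doubled) for as long as the measured point-to-surface RMSE
    keeps improving, which accelerates the slow tangential sliding typical of
    partial patches.  Candidates are only ever accepted when they lower the
    measured RMSE, so the reported RMSE history is non-increasing.
    Convergence is declared when one full iteration improves the RMSE by less
    than ``convergence_tol`` (mm).  ``init`` defaults to the identity;
    callers may supply a coarse alignment such as :func:`principal_axes_init`.
    ``iterations`` counts surface-correspondence evaluations (the unit of
    work), including extrapolation probes.
    """
    P0 = _as_points(moving)
    if len(P0) == 0:
        raise ValueError("moving point set is empty")
    if not np.all(np.isfinite(P0)) or not np.all(np.isfinite(fixed.vertices)):
        raise ValueError("non-finite coordinates in registration input")
    if len(fixed.faces) == 0:
        raise ValueError("fixed mesh has no faces")
    T = init if init is not None else RigidTransform.identity()
    query = surface_query if surface_query is not None else _MeshDistanceQuery(fixed)

    def evaluate(Tc: RigidTransform) -> tuple[float, np.ndarray]:
        dist, footpoints = query.query(Tc.apply(P0))
        return float(np.sqrt(np.mean(dist**2))), footpoints

    def step_vector(step: RigidTransform) -> np.ndarray:
        # small-increment direction in a combined rotation+translation space
        w = np.array(
            [
                step.rotation[2, 1] - step.rotation[1, 2],
                step.rotation[0, 2] - step.rotation[2, 0],
                step.rotation[1, 0] - step.rotation[0, 1],
            ]
        )
        return np.concatenate([w * 50.0, step.translation])  # ~50 mm lever arm

    rmse, Q = evaluate(T)
    history = [rmse]
    evals = 1
    converged = rmse == 0.0
    prev_dir: np.ndarray | None = None
    while not converged and evals < max_iterations:
        T1 = landmark_register(P0, Q)
        step = T1.compose(T.inverse())
        best_r, best_Q = evaluate(T1)
        evals += 1
        best_T = T1
        # extrapolate the increment while it pays off, but only when the
        # iteration is sliding in a consistent direction (not zig-zagging)
        v = step_vector(step)
        vn = float(np.linalg.norm(v))
        aligned = (
            prev_dir is not None
            and vn > 0
            and float(v @ prev_dir) > 0.7 * vn * float(np.linalg.norm(prev_dir))
        )
        prev_dir = v
        while aligned and evals < max_iterations:
            T_try = step.compose(best_T)
            r_try, Q_try = evaluate(T_try)
            evals += 1
            if r_try < best_r:
                best_T, best_r, best_Q = T_try, r_try, Q_try
                step = step.compose(step)
            else:
                break
        if best_r <= rmse:  # Kabsch guarantees this; keep monotone regardless
            improvement = rmse - best_r
            T, rmse, Q = best_T, best_r, best_Q
            history.append(rmse)
        else:
            improvement = 0.0
        if improvement < convergence_tol:
            converged = True
    return RegistrationResult(
        transform=T,
        rmse=rmse,
        iterations=evals,
        converged=converged,
        rmse_history=history,
    )


def principal_axes_init(moving, fixed: SurfaceMesh) -> RigidTransform:
    """Coarse alignment by centroids and principal axes.

    Replaces the interactive rough alignment of a GUI workflow.  The four
    proper sign combinations of the principal axes are tried and the one with
    the lowest median point-to-surface distance wins.
    """
    P = _as_points(moving)
    Q = fixed.vertices.view(np.ndarray)
    pm, qm = P.mean(axis=0), Q.mean(axis=0)
    _, _, Vp = np.linalg.svd(P - pm, full_matrices=False)
    _, _, Vq = np.linalg.svd(Q - qm, full_matrices=False)
    if np.linalg.det(Vp) < 0:
        Vp[2] = -Vp[2]
    if np.linalg.det(Vq) < 0:
        Vq[2] = -Vq[2]
    rng = np.random.default_rng(0)
    sub = P[rng.choice(len(P), size=min(500, len(P)), replace=False)]
    query = _MeshDistanceQuery(fixed)
    # candidates: centroid shift only (for inputs already roughly oriented,
    # where PCA sign ambiguity would do more harm than good) plus the four
    # proper sign combinations of the principal axes
    candidates = [RigidTransform(np.eye(3), qm - pm)]
    for flips in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
        R = Vq.T @ np.diag(flips) @ Vp
        candidates.append(RigidTransform(R, qm - R @ pm))
    # each candidate is polished by a few ICP iterations on the subsample and
    # judged by the refined RMSE — a raw distance score cannot distinguish a
    # good basin from a nearby local minimum
    best: RigidTransform | None = None
    best_rmse = np.inf
    for T in candidates:
        res = icp_register(
            sub,
            fixed,
            init=T,
            max_iterations=15,
            convergence_tol=1e-9,
            surface_query=query,
        )
        if res.rmse < best_rmse:
            best_rmse, best = res.rmse, res.transform
    assert best is not None
    return best


@dataclass
class PosedPair:
    """Both vertebrae mapped into the loaded experimental pose."""

    caudal: SurfaceMesh
    cranial: SurfaceMesh
    ct_to_dic_caudal: RigidTransform
    ct_to_dic_cranial: RigidTransform
    relative_cranial_pose: RigidTransform


def pose_in_experimental_frame(
    reg_caudal: RegistrationResult,
    reg_cranial: RegistrationResult,
    caudal_bone: SurfaceMesh,
    cranial_bone: SurfaceMesh,
    allow_unconverged: bool = False,
) -> PosedPair:
    """Map CT-frame vertebra meshes into the loaded experimental pose.

    Each registration maps a DIC patch (experimental frame) onto the CT
    surface; its inverse therefore carries the CT geometry into the
    experimental pose.  The caudal vertebra is the anchor: the relative
    cranial pose is expressed against the caudal frame and is invariant to
    any global motion common to both patches.
    """
    for name, reg in (("caudal", reg_caudal), ("cranial", reg_cranial)):
        if not reg.converged and not allow_unconverged:
            raise ValueError(
                f"{name} registration did not converge "
                f"(rmse={reg.rmse:.4f} mm after {reg.iterations} iterations); "
                "pass allow_unconverged=True to override"
            )
    T_c = reg_caudal.transform
    T_r = reg_cranial.transform
    posed_caudal = caudal_bone.copy()
    posed_caudal.apply_transform(T_c.inverse().matrix)
    posed_cranial = cranial_bone.copy()
    posed_cranial.apply_transform(T_r.inverse().matrix)
    relative = T_c.compose(T_r.inverse())
    return PosedPair(
        caudal=posed_caudal,
        cranial=posed_cranial,
        ct_to_dic_caudal=T_c.inverse(),
        ct_to_dic_cranial=T_r.inverse(),
        relative_cranial_pose=relative,
    )
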