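"""Triangle-mesh and point-cloud primitives.

The geometry currency of the whole package is the millimetre-scale triangle
surface mesh (a :class:`trimesh.Trimesh`) together with point clouds carrying
optional per-point unit normals.  This module provides

* point-cloud containers and ASCII-PLY I/O preserving normals and labels,
* k-nearest-neighbour normal estimation with consistent orientation,
* ball-pivoting surface reconstruction (the method used to turn DIC-correlated
  surface points into meshes, with the multi-radius schedule exposed),
* watertight mesh volume by the divergence theorem,
* exact point-to-surface distances (KD-tree pruned),
* planar cross sections of closed meshes as shapely polygons, the primitive
  behind voxelization and slice-based Boolean volumetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import shapely.geometry
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, minimum_spanning_tree
from scipy.spatial import cKDTree

SurfaceMesh = trimesh.Trimesh

__all__ = [
    "SurfaceMesh",
    "PointCloud",
    "BPAParams",
    "new_mesh",
    "load_mesh",
    "save_mesh",
    "save_point_cloud_ply",
    "load_point_cloud_ply",
    "estimate_normals",
    "reconstruct_surface_bpa",
    "mesh_volume",
    "point_to_surface_distances",
    "closest_points_on_mesh",
    "cross_section",
    "grid_inside_mesh",
    "EmptyReconstructionError",
]


# ---------------------------------------------------------------------------
# containers and I/O
# ---------------------------------------------------------------------------


@dataclass
class PointCloud:
    """Points in mm with optional unit normals and per-point string labels."""

    points: np.ndarray
    normals: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            if self.normals.shape != self.points.shape:
                raise ValueError("normals shape must match points")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normals must have unit length (+-1e-6)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.points):
                raise ValueError("labels length must match points")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, label: str) -> "PointCloud":
        """Sub-cloud with the given provenance label."""
        if self.labels is None:
            raise ValueError("cloud has no labels")
        m = self.labels == label
        return PointCloud(
            self.points[m],
            None if self.normals is None else self.normals[m],
            self.labels[m],
        )

    def transformed(self, matrix: np.ndarray) -> "PointCloud":
        R, t = np.asarray(matrix)[:3, :3], np.asarray(matrix)[:3, 3]
        pts = self.points @ R.T + t
        nrm = None if self.normals is None else self.normals @ R.T
        return PointCloud(pts, nrm, self.labels)


def new_mesh(vertices: np.ndarray, faces: np.ndarray) -> SurfaceMesh:
    """Build a mesh without any automatic processing (vertices kept verbatim)."""
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def load_mesh(path: str | Path) -> SurfaceMesh:
    """Read STL/PLY/OFF; duplicate vertices are merged (STL is a facet soup)."""
    mesh = trimesh.load_mesh(str(path), process=True)
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a triangle mesh")
    return mesh


def save_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    mesh.export(str(path))


def save_point_cloud_ply(cloud: PointCloud, path: str | Path) -> None:
    """ASCII PLY with optional nx/ny/nz and a per-point `label` property."""
    n = len(cloud)
    labels = None
    header = ["ply", "format ascii 1.0", f"element vertex {n}"]
    header += [f"property float {c}" for c in ("x", "y", "z")]
    if cloud.normals is not None:
        header += [f"property float {c}" for c in ("nx", "ny", "nz")]
    if cloud.labels is not None:
        uniq = sorted(set(map(str, cloud.labels)))
        lut = {name: i for i, name in enumerate(uniq)}
        labels = np.array([lut[str(v)] for v in cloud.labels])
        header += [f"comment label {i} {name}" for name, i in lut.items()]
        header.append("property int label")
    header.append("end_header")
    cols = [cloud.points]
    if cloud.normals is not None:
        cols.append(cloud.normals)
    body = np.hstack(cols)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for i in range(n):
            row = " ".join(f"{v:.9g}" for v in body[i])
            if labels is not None:
                row += f" {labels[i]}"
            fh.write(row + "\n")


def load_point_cloud_ply(path: str | Path) -> PointCloud:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if lines[0] != "ply":
        raise ValueError(f"{path} is not a PLY file")
    props: list[str] = []
    lut: dict[int, str] = {}
    n = 0
    start = 0
    for i, line in enumerate(lines):
        tok = line.split()
        if tok[:2] == ["element", "vertex"]:
            n = int(tok[2])
        elif tok and tok[0] == "property":
            props.append(tok[-1])
        elif tok[:2] == ["comment", "label"]:
            lut[int(tok[2])] = tok[3]
        elif tok == ["end_header"]:
            start = i + 1
            break
    data = np.array([lines[start + j].split() for j in range(n)], dtype=float)
    get = {p: data[:, k] for k, p in enumerate(props)}
    pts = np.column_stack([get["x"], get["y"], get["z"]])
    nrm = None
    if "nx" in get:
        nrm = np.column_stack([get["nx"], get["ny"], get["nz"]])
    labels = None
    if "label" in get:
        labels = np.array([lut[int(v)] for v in get["label"]])
    return PointCloud(pts, nrm, labels)


# ---------------------------------------------------------------------------
# normal estimation
# ---------------------------------------------------------------------------


def estimate_normals(cloud: PointCloud | np.ndarray, neighborhood_size: int = 100) -> PointCloud:
    """Per-point unit normals from the best-fit plane of the k nearest points.

    Orientation is made consistent by propagating along a minimum-spanning
    tree of the neighbour graph (flipping when a normal disagrees with its
    parent) and then globally flipped, if needed, so that normals point away
    from the cloud centroid on average.
    """
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, float)
    labels = cloud.labels if isinstance(cloud, PointCloud) else None
    n = len(pts)
    if n < neighborhood_size:
        raise ValueError(
            f"cloud has {n} points, fewer than neighborhood_size={neighborhood_size}"
        )
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=neighborhood_size)
    nbrs = pts[idx]  # (n, k, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    # smallest eigenvector of each neighbourhood covariance = plane normal
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]

    # orientation propagation over an MST of the kNN graph
    k_graph = min(12, n - 1)
    _, gidx = tree.query(pts, k=k_graph + 1)
    rows = np.repeat(np.arange(n), k_graph)
    cols = gidx[:, 1:].ravel()
    d = np.linalg.norm(pts[rows] - pts[cols], axis=1)
    graph = coo_matrix((d + 1e-12, (rows, cols)), shape=(n, n))
    mst = minimum_spanning_tree(graph)
    sym = mst + mst.T
    order, pred = breadth_first_order(sym, i_start=0, directed=False)
    for node in order[1:]:
        parent = pred[node]
        if np.dot(normals[node], normals[parent]) < 0.0:
            normals[node] = -normals[node]
    outward = pts - pts.mean(axis=0)
    if np.sum(np.einsum("ij,ij->i", outward, normals)) < 0.0:
        normals = -normals
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(pts, normals, labels)


# ---------------------------------------------------------------------------
# ball-pivoting surface reconstruction
# ---------------------------------------------------------------------------


@dataclass
class BPAParams:
    """Ball-pivoting schedule.

    Defaults follow the multi-pass schedule used for DIC surface
    reconstruction: radii 0.8, 1.0 and 1.1 mm with a clustering radius of 20%
    of the ball radius and a 90 deg angle threshold, plus an optional final
    1.25 mm pass at 10% clustering that only adds triangles which do not
    superpose existing ones.
    """

    radii_schedule: tuple[float, ...] = (0.8, 1.0, 1.1)
    clustering_fraction_default: float = 0.2
    clustering_fraction_final: float = 0.1
    angle_threshold: float = 90.0
    final_radius: float = 1.25
    enable_final_loop: bool = True

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii_schedule)
        if any(r <= 0 for r in radii) or list(radii) != sorted(set(radii)):
            raise ValueError("radii_schedule must be strictly increasing and positive")
        for f in (self.clustering_fraction_default, self.clustering_fraction_final):
            if not 0.0 < f <= 1.0:
                raise ValueError("clustering fractions must be in (0, 1]")
        if not 0.0 < self.angle_threshold <= 180.0:
            raise ValueError("angle_threshold must be in (0, 180]")


class EmptyReconstructionError(RuntimeError):
    pass


def _tri_normal(p1, p2, p3):
    n = np.cross(p2 - p1, p3 - p1)
    nn = np.linalg.norm(n)
    return None if nn < 1e-12 else n / nn


def _ball_centers(p1, p2, p3, r):
    """Vectorized centers of radius-``r`` balls through triangles (p1, p2, p3).

    Inputs broadcast to (k, 3).  The center lies on the positive side of the
    triangle normal ``cross(p2 - p1, p3 - p1)``.  Returns (centers, unit
    normals, valid) where ``valid`` is False for degenerate triangles or
    circumradius > r.
    """
    p1, p2, p3 = np.broadcast_arrays(
        np.atleast_2d(p1), np.atleast_2d(p2), np.atleast_2d(p3)
    )
    e1 = p2 - p1
    e2 = p3 - p1
    n = np.cross(e1, e2)
    n2 = np.einsum("ij,ij->i", n, n)
    d11 = np.einsum("ij,ij->i", e1, e1)
    d22 = np.einsum("ij,ij->i", e2, e2)
    d12 = np.einsum("ij,ij->i", e1, e2)
    denom = 2.0 * (d11 * d22 - d12 * d12)
    valid = (n2 > 1e-24) & (np.abs(denom) > 1e-24)
    safe = np.where(valid, denom, 1.0)
    u = d22 * (d11 - d12) / safe
    v = d11 * (d22 - d12) / safe
    cc = p1 + u[:, None] * e1 + v[:, None] * e2
    rc2 = np.einsum("ij,ij->i", cc - p1, cc - p1)
    h2 = r * r - rc2
    valid &= h2 > 0.0
    n_unit = n / np.sqrt(np.where(n2 > 0, n2, 1.0))[:, None]
    h = np.sqrt(np.where(valid, h2, 0.0))
    centers = cc + h[:, None] * n_unit
    return centers, n_unit, valid


class _BPAState:
    """Mutable reconstruction state shared across the radius passes.

    Triangles are stored with outward orientation (normal = cross(b-a, c-a));
    directed boundary edges of triangle (a, b, c) are (a,b), (b,c), (c,a).
    """

    def __init__(self, pts: np.ndarray, nrm: np.ndarray):
        self.pts = pts
        self.nrm = nrm
        self.tree = cKDTree(pts)
        self.triangles: list[tuple[int, int, int]] = []
        self.tri_set: set[frozenset] = set()
        self.edge_count: dict[tuple[int, int], int] = {}
        self.edge_tri: dict[tuple[int, int], tuple[int, int, int]] = {}
        self.used = np.zeros(len(pts), dtype=bool)

    @staticmethod
    def _ekey(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    def edge_open(self, a: int, b: int) -> bool:
        return self.edge_count.get(self._ekey(a, b), 0) < 2

    def add_triangle(self, a: int, b: int, c: int) -> None:
        self.triangles.append((a, b, c))
        self.tri_set.add(frozenset((a, b, c)))
        for e in ((a, b), (b, c), (c, a)):
            k = self._ekey(*e)
            self.edge_count[k] = self.edge_count.get(k, 0) + 1
            self.edge_tri.setdefault(k, (a, b, c))
        self.used[[a, b, c]] = True


def _bpa_pass(
    state: _BPAState,
    r: float,
    cluster_frac: float,
    cos_angle_min: float,
    guard_superposition: bool,
) -> None:
    pts, nrm, tree = state.pts, state.nrm, state.tree
    n_pts = len(pts)
    cluster_r = cluster_frac * r
    front: list[tuple[int, int, int, np.ndarray]] = []  # (u, v, opposite, center)
    in_front: set[tuple[int, int]] = set()

    def push_edge(u: int, v: int, w: int, center: np.ndarray) -> None:
        k = state._ekey(u, v)
        if state.edge_count.get(k, 0) == 1 and k not in in_front:
            front.append((u, v, w, center))
            in_front.add(k)

    def push_triangle(a: int, b: int, c: int, center: np.ndarray) -> None:
        state.add_triangle(a, b, c)
        push_edge(a, b, c, center)
        push_edge(b, c, a, center)
        push_edge(c, a, b, center)

    # boundary edges left over from earlier (smaller-radius) passes are
    # re-tried at this radius
    for k in list(state.edge_count):
        if state.edge_count[k] != 1:
            continue
        a, b, c = state.edge_tri[k]
        for e0, e1, w in ((a, b, c), (b, c, a), (c, a, b)):
            if state._ekey(e0, e1) != k:
                continue
            centers, _, valid = _ball_centers(pts[a], pts[b], pts[c], r)
            if valid[0]:
                push_edge(e0, e1, w, centers[0])
            break

    def pivot(u: int, v: int, w: int, c_prev: np.ndarray):
        """Roll the ball around directed boundary edge (u, v) of tri (u,v,w)."""
        pu, pv, pw = pts[u], pts[v], pts[w]
        m = 0.5 * (pu + pv)
        axis = pv - pu
        an = np.linalg.norm(axis)
        if an < 1e-12:
            return None
        axis = axis / an
        uperp = c_prev - m
        uperp = uperp - (uperp @ axis) * axis
        un = np.linalg.norm(uperp)
        if un < 1e-12:
            return None
        uperp = uperp / un
        wperp = pw - m
        wperp = wperp - (wperp @ axis) * axis
        # rolling direction: center initially moves away from the w side
        s = -1.0 if float(np.cross(axis, uperp) @ wperp) > 0.0 else 1.0
        n_old = _tri_normal(pu, pv, pw)

        cand = np.array(sorted(tree.query_ball_point(m, 2.0 * r)), dtype=int)
        cand = cand[(cand != u) & (cand != v) & (cand != w)]
        if len(cand) and cluster_r > 0.0:
            keep = state.used[cand].copy()
            du = np.linalg.norm(pts[cand] - pu, axis=1)
            dv = np.linalg.norm(pts[cand] - pv, axis=1)
            keep |= (du >= cluster_r) & (dv >= cluster_r)
            cand = cand[keep]
        if len(cand) == 0:
            return None
        # new triangle (v, u, x): outward normal = cross(u - v, x - v)
        centers, n_new, valid = _ball_centers(pts[v], pts[u], pts[cand], r)
        if n_old is not None:
            dots = n_new @ n_old
            valid &= dots >= cos_angle_min
            if guard_superposition:
                vperp = pts[cand] - m
                vperp = vperp - np.outer(vperp @ axis, axis)
                flat_same_side = (dots > 0.999) & (vperp @ wperp > 0.0)
                valid &= ~flat_same_side
        if not valid.any():
            return None
        cperp = centers - m
        cperp = cperp - np.outer(cperp @ axis, axis)
        cn = np.linalg.norm(cperp, axis=1)
        valid &= cn > 1e-12
        with np.errstate(invalid="ignore"):
            theta = np.arctan2(
                s * (np.cross(np.broadcast_to(uperp, cperp.shape), cperp) @ axis),
                np.einsum("ij,j->i", cperp, uperp),
            )
        theta = np.where(theta <= 1e-9, theta + 2.0 * math.pi, theta)
        theta = np.where(valid, theta, np.inf)
        for oi in np.argsort(theta, kind="stable"):
            if not np.isfinite(theta[oi]):
                break
            x = int(cand[oi])
            if frozenset((u, v, x)) in state.tri_set:
                continue
            if not (state.edge_open(u, x) and state.edge_open(x, v)):
                continue
            c_x = centers[oi]
            inside = tree.query_ball_point(c_x, r * (1.0 - 1e-7))
            if any(q not in (u, v, x) for q in inside):
                continue
            return x, c_x
        return None

    def try_seed(i: int) -> bool:
        dists, nbr = tree.query(pts[i], k=min(25, n_pts))
        nbr = [
            int(q)
            for q, dq in zip(np.atleast_1d(nbr), np.atleast_1d(dists))
            if int(q) != i and dq <= 2.0 * r
        ]
        for a_i, j in enumerate(nbr):
            if cluster_r > 0.0 and np.linalg.norm(pts[j] - pts[i]) < cluster_r:
                continue
            for x in nbr[a_i + 1 :]:
                if cluster_r > 0.0 and (
                    np.linalg.norm(pts[x] - pts[i]) < cluster_r
                    or np.linalg.norm(pts[x] - pts[j]) < cluster_r
                ):
                    continue
                tn = _tri_normal(pts[i], pts[j], pts[x])
                if tn is None:
                    continue
                vote = nrm[i] + nrm[j] + nrm[x]
                a, b, c = (i, j, x) if float(tn @ vote) >= 0.0 else (i, x, j)
                if frozenset((a, b, c)) in state.tri_set:
                    continue
                if not (
                    state.edge_open(a, b)
                    and state.edge_open(b, c)
                    and state.edge_open(c, a)
                ):
                    continue
                centers, _, valid = _ball_centers(pts[a], pts[b], pts[c], r)
                if not valid[0]:
                    continue
                center = centers[0]
                inside = tree.query_ball_point(center, r * (1.0 - 1e-7))
                if any(q not in (a, b, c) for q in inside):
                    continue
                push_triangle(a, b, c, center)
                return True
        return False

    seed_scan = 0
    while True:
        while front:
            u, v, w, center = front.pop()
            k = state._ekey(u, v)
            in_front.discard(k)
            if state.edge_count.get(k, 0) != 1:
                continue
            res = pivot(u, v, w, center)
            if res is None:
                continue
            x, c_x = res
            state.add_triangle(v, u, x)
            # remaining directed edges of (v, u, x): (u, x) and (x, v)
            push_edge(u, x, v, c_x)
            push_edge(x, v, u, c_x)
        rest = np.flatnonzero(~state.used[seed_scan:])
        if len(rest) == 0:
            break
        i = seed_scan + int(rest[0])
        seed_scan = i + 1
        try_seed(i)


def reconstruct_surface_bpa(cloud: PointCloud, params: BPAParams | None = None) -> SurfaceMesh:
    """Ball-pivoting surface reconstruction of a point cloud with normals.

    Triangles are added by successive pivoting passes at each radius of the
    schedule (smaller radii capture detail, larger ones bridge sparser gaps
    and fill smaller holes); boundary edges of each pass are re-tried at the
    next radius.  The optional final pass adds triangles only where they do
    not superpose existing ones.  Output vertices are exactly the input
    points — the algorithm interpolates nothing.
    """
    if params is None:
        params = BPAParams()
    if cloud.normals is None:
        raise ValueError(
            "reconstruction requires a cloud with normals; run estimate_normals first"
        )
    pts = np.ascontiguousarray(cloud.points, dtype=float)
    nrm = np.ascontiguousarray(cloud.normals, dtype=float)
    state = _BPAState(pts, nrm)
    cos_min = math.cos(math.radians(params.angle_threshold))
    for r in params.radii_schedule:
        _bpa_pass(state, r, params.clustering_fraction_default, cos_min, False)
    if params.enable_final_loop:
        _bpa_pass(
            state, params.final_radius, params.clustering_fraction_final, cos_min, True
        )
    if not state.triangles:
        radii = list(params.radii_schedule)
        if params.enable_final_loop:
            radii.append(params.final_radius)
        raise EmptyReconstructionError(
            f"no triangle could be created at any ball radius (max tried: "
            f"{max(radii)} mm); the sampling is probably sparser than the schedule"
        )
    return new_mesh(pts, np.array(state.triangles, dtype=np.int64))


# ---------------------------------------------------------------------------
# volume and distances
# ---------------------------------------------------------------------------


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume (mm^3) of a watertight mesh by the divergence theorem."""
    if not mesh.is_watertight:
        edges = mesh.edges_sorted
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        n_boundary = int(np.sum(counts == 1))
        raise ValueError(
            f"mesh is not watertight ({n_boundary} boundary edges); "
            "volume is undefined"
        )
    return float(abs(mesh.volume))


def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle for each (point, triangle) pair.

    Vectorized barycentric-region algorithm; ``p`` is (m, 3), ``tri`` is
    (m, 3, 3), returns (m, 3).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex A
    out[m] = a[m]
    done |= m
    m = ~done & (d3 >= 0) & (d4 <= d3)  # vertex B
    out[m] = b[m]
    done |= m
    m = ~done & (d6 >= 0) & (d5 <= d6)  # vertex C
    out[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge AB
    denom = d1[m] - d3[m]
    denom[denom == 0] = 1.0
    v = d1[m] / denom
    out[m] = a[m] + v[:, None] * ab[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge AC
    denom = d2[m] - d6[m]
    denom[denom == 0] = 1.0
    w = d2[m] / denom
    out[m] = a[m] + w[:, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge BC
    denom = (d4[m] - d3[m]) + (d5[m] - d6[m])
    denom[denom == 0] = 1.0
    w = (d4[m] - d3[m]) / denom
    out[m] = b[m] + w[:, None] * (c[m] - b[m])
    done |= m

    m = ~done  # interior
    denom = va[m] + vb[m] + vc[m]
    denom[denom == 0] = 1.0
    v = vb[m] / denom
    w = vc[m] / denom
    out[m] = a[m] + v[:, None] * ab[m] + w[:, None] * ac[m]
    return out


class _MeshDistanceQuery:
    """Reusable exact point-to-surface query against one mesh."""

    def __init__(self, mesh: SurfaceMesh):
        self.tri = mesh.triangles.view(np.ndarray)
        centroids = self.tri.mean(axis=1)
        self.c_tree = cKDTree(centroids)
        self.v_tree = cKDTree(mesh.vertices.view(np.ndarray))
        # farthest vertex-to-centroid distance bounds the pruning radius
        self.slack = float(
            np.max(np.linalg.norm(self.tri - centroids[:, None, :], axis=2))
        )

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        ub, _ = self.v_tree.query(points)
        cand_lists = self.c_tree.query_ball_point(
            points, ub + self.slack + 1e-12
        )
        # flatten all (point, candidate-triangle) pairs into one vectorized call
        counts = np.array([len(c) for c in cand_lists])
        flat_tri = np.concatenate([np.asarray(c, dtype=int) for c in cand_lists])
        flat_pts = np.repeat(points, counts, axis=0)
        cp = _closest_on_triangles(flat_pts, self.tri[flat_tri])
        d2 = np.einsum("ij,ij->i", cp - flat_pts, cp - flat_pts)
        # segment argmin: best candidate per query point
        seg = np.repeat(np.arange(len(points)), counts)
        order = np.lexsort((d2, seg))
        firsts = np.searchsorted(seg[order], np.arange(len(points)))
        best = order[firsts]
        return np.sqrt(d2[best]), cp[best]


def closest_points_on_mesh(points: np.ndarray, mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-point (unsigned distance, closest surface point) against a mesh."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) == 0 or len(mesh.faces) == 0:
        raise ValueError("points and mesh must be non-empty")
    return _MeshDistanceQuery(mesh).query(points)


def point_to_surface_distances(points: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Exact minimum point-to-triangle distance (mm) for every query point."""
    return closest_points_on_mesh(points, mesh)[0]


# ---------------------------------------------------------------------------
# planar cross sections
# ---------------------------------------------------------------------------


class MeshSlicer:
    """Repeated z-plane cross sections of one mesh with triangle bucketing.

    Precomputes per-triangle z-ranges so each slice only touches the
    triangles actually crossing its plane — the difference between O(all
    triangles) and O(local band) per slice on marching-cubes meshes.
    """

    def __init__(self, mesh: SurfaceMesh):
        self.tri = mesh.triangles.view(np.ndarray)
        tz = self.tri[:, :, 2]
        self.zmin = tz.min(axis=1)
        self.zmax = tz.max(axis=1)
        order = np.argsort(self.zmin)
        self.zmin_sorted = self.zmin[order]
        self.order = order
        self.zmax_by_order = self.zmax[order]
        self.bounds = (float(self.zmin.min()), float(self.zmax.max()))
        # closed shells are sectioned independently: loops of abutting shells
        # can share nodes, which would derail a joint loop traversal
        self.body = trimesh.graph.connected_component_labels(
            mesh.face_adjacency, node_count=len(mesh.faces)
        )

    def _segments(self, z: float) -> tuple[np.ndarray, np.ndarray]:
        """xy intersection segments (m, 2, 2) with plane z and their body ids."""
        hi = np.searchsorted(self.zmin_sorted, z, side="right")
        cand = np.sort(self.order[:hi][self.zmax_by_order[:hi] > z])
        if len(cand) == 0:
            return np.empty((0, 2, 2)), np.empty(0, dtype=int)
        tri = self.tri[cand]
        d = tri[:, :, 2] - z  # signed distance of each vertex to the plane
        a_idx = np.array([0, 1, 2])
        b_idx = np.array([1, 2, 0])
        da, db = d[:, a_idx], d[:, b_idx]  # (n, 3) per-edge endpoints
        cross = (da > 0) != (db > 0)
        denom = np.where(da - db == 0, 1.0, da - db)
        t = np.where(cross, da / denom, 0.0)
        pa = tri[:, a_idx, :2]
        pb = tri[:, b_idx, :2]
        pts = pa + t[..., None] * (pb - pa)  # (n, 3, 2) crossing point per edge
        two = cross.sum(axis=1) == 2
        if not two.any():
            return np.empty((0, 2, 2)), np.empty(0, dtype=int)
        cross = cross[two]
        pts = pts[two]
        e1 = cross.argmax(axis=1)
        tmp = cross.copy()
        tmp[np.arange(len(tmp)), e1] = False
        e2 = tmp.argmax(axis=1)
        rows = np.arange(len(pts))
        segs = np.stack([pts[rows, e1], pts[rows, e2]], axis=1)
        return segs, self.body[cand[two]]

    def region(self, z: float, snap: float = 1e-6):
        segs, bodies = self._segments(z)
        if len(segs) == 0:
            return shapely.geometry.Polygon()
        region = shapely.geometry.Polygon()
        for b in np.unique(bodies):
            region = region.symmetric_difference(
                _assemble_region(segs[bodies == b], snap)
            )
        return region


def cross_section(
    mesh: SurfaceMesh, z: float, snap: float = 1e-6
) -> shapely.geometry.base.BaseGeometry:
    """Solid cross section of a closed mesh with the plane ``z = const``.

    Intersection segments are chained into closed loops (endpoints snapped to
    ``snap`` mm) and composed under the even-odd rule, so nested loops become
    holes.  Returns a (possibly empty) shapely polygon in world x-y
    coordinates.
    """
    return MeshSlicer(mesh).region(z, snap)


def _assemble_region(segs: np.ndarray, snap: float = 1e-6):
    empty = shapely.geometry.Polygon()
    if len(segs) == 0:
        return empty
    pts2 = segs
    keys = np.round(pts2 / snap).astype(np.int64)
    adj: dict[tuple[int, int], list[tuple[tuple[int, int], int]]] = {}
    seg_used = np.zeros(len(segs), dtype=bool)
    coords: dict[tuple[int, int], np.ndarray] = {}
    for si in range(len(segs)):
        k0, k1 = tuple(keys[si, 0]), tuple(keys[si, 1])
        if k0 == k1:
            seg_used[si] = True  # degenerate sliver
            continue
        coords.setdefault(k0, pts2[si, 0])
        coords.setdefault(k1, pts2[si, 1])
        adj.setdefault(k0, []).append((k1, si))
        adj.setdefault(k1, []).append((k0, si))
    loops = []
    for si in range(len(segs)):
        if seg_used[si]:
            continue
        start = tuple(keys[si, 0])
        cur = tuple(keys[si, 1])
        seg_used[si] = True
        loop = [start, cur]
        ok = False
        while True:
            nxt = None
            for node, sj in adj.get(cur, ()):  # first unused continuation
                if not seg_used[sj]:
                    nxt = (node, sj)
                    break
            if nxt is None:
                break
            seg_used[nxt[1]] = True
            cur = nxt[0]
            if cur == start:
                ok = True
                break
            loop.append(cur)
        if ok and len(loop) >= 3:
            loops.append(np.array([coords[k] for k in loop]))
    region = empty
    for loop in loops:
        poly = shapely.geometry.Polygon(loop)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            continue
        region = region.symmetric_difference(poly)
    return region


def grid_inside_mesh(
    mesh: SurfaceMesh, xs: np.ndarray, ys: np.ndarray, zs: np.ndarray
) -> np.ndarray:
    """Boolean (nx, ny, nz) array marking lattice points inside a closed mesh.

    Works slice-by-slice: the solid cross section at each ``zs`` level is
    tested against the x-y lattice with shapely's vectorized point-in-polygon.
    Lattice levels coinciding with flat mesh facets are nudged by a
    deterministic epsilon to avoid degenerate sections.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    zs = np.asarray(zs, dtype=float)
    out = np.zeros((len(xs), len(ys), len(zs)), dtype=bool)
    zmin, zmax = mesh.bounds[:, 2]
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    xf, yf = X.ravel(), Y.ravel()
    eps = 1e-6 * max(1.0, abs(zmax - zmin))
    slicer = MeshSlicer(mesh)
    for k, z in enumerate(zs):
        if z <= zmin or z >= zmax:
            continue
        region = slicer.region(z + eps)
        if region.is_empty:
            continue
        inside = shapely.contains_xy(region, xf, yf)
        out[:, :, k] = inside.reshape(len(xs), len(ys))
    return out
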