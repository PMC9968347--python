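"""Repeatability and registration-quality metrics.

Dice similarity between segmentation masks, point-to-surface RMSE of a
registration, Metro-style Hausdorff distance summaries between meshes
(area-weighted sampling of one surface, exact distances to the other), the
percentile criterion on the retained per-sample distances, and leave-one-out
flagging of unreliable registrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .mesh import SurfaceMesh, _MeshDistanceQuery, point_to_surface_distances
from .segmentation import BinaryMask

__all__ = [
    "HDSummary",
    "dice",
    "hausdorff_metro",
    "hd_percentile",
    "flag_outlier_registrations",
    "registration_rmse",
]


@dataclass
class HDSummary:
    """Summary statistics of sampled surface-to-surface distances (mm).

    Per-sample distances are retained so percentile criteria (e.g. the
    fraction of nodes below 1 mm) can be queried afterwards.
    """

    minimum: float
    mean: float
    maximum: float
    rms: float
    distances: np.ndarray
    direction: str = "one_sided"

    def __post_init__(self) -> None:
        if not (0 <= self.minimum <= self.mean <= self.maximum):
            raise ValueError("need 0 <= min <= mean <= max")
        if self.rms < self.mean - 1e-12:
            raise ValueError("rms < mean is impossible for non-negative distances")

    @classmethod
    def from_distances(cls, d: np.ndarray, direction: str = "one_sided") -> "HDSummary":
        d = np.asarray(d, dtype=float)
        return cls(
            minimum=float(d.min()),
            mean=float(d.mean()),
            maximum=float(d.max()),
            rms=float(np.sqrt(np.mean(d**2))),
            distances=d,
            direction=direction,
        )


def dice(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Dice similarity index 2|A∩B| / (|A|+|B|) of two masks on the same grid.

    Defined as 1.0 when both masks are empty (identical nothing).
    """
    if not mask_a.same_grid(mask_b):
        raise ValueError("masks live on different grids; Dice is undefined")
    a, b = mask_a.data, mask_b.data
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _one_sided(mesh_a: SurfaceMesh, mesh_b: SurfaceMesh, n_samples: int,
               seed: int, sampling: str) -> np.ndarray:
    if sampling == "vertex":
        pts = mesh_a.vertices.view(np.ndarray)
    else:
        pts, _ = trimesh.sample.sample_surface(mesh_a, n_samples, seed=seed)
    return point_to_surface_distances(pts, mesh_b)


def hausdorff_metro(
    mesh_a: SurfaceMesh,
    mesh_b: SurfaceMesh,
    n_samples: int = 100_000,
    seed: int = 0,
    symmetric: bool = False,
    sampling: str = "area",
) -> HDSummary:
    """Metro-style Hausdorff distance summary between two meshes.

    Samples points on ``mesh_a`` (area-weighted, seeded; or its vertices with
    ``sampling='vertex'``, appropriate for same-topology comparisons such as
    two registrations of one surface) and measures exact distances to
    ``mesh_b``.  The symmetric variant runs both directions and takes, per
    summary statistic, the maximum of the two one-sided values; its retained
    distances are the concatenation of both directions.
    """
    if sampling not in ("area", "vertex"):
        raise ValueError("sampling must be 'area' or 'vertex'")
    if sampling == "area" and n_samples < 1000:
        raise ValueError("n_samples must be >= 1000 for stable summaries")
    d_ab = _one_sided(mesh_a, mesh_b, n_samples, seed, sampling)
    if not symmetric:
        return HDSummary.from_distances(d_ab)
    d_ba = _one_sided(mesh_b, mesh_a, n_samples, seed + 1, sampling)
    a = HDSummary.from_distances(d_ab)
    b = HDSummary.from_distances(d_ba)
    return HDSummary(
        minimum=max(a.minimum, b.minimum),
        mean=max(a.mean, b.mean),
        maximum=max(a.maximum, b.maximum),
        rms=max(a.rms, b.rms),
        distances=np.concatenate([d_ab, d_ba]),
        direction="symmetric",
    )


def hd_percentile(summary: HDSummary, q: float) -> float:
    """Empirical q-quantile (linear interpolation) of the retained distances."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    return float(np.quantile(summary.distances, q, method="linear"))


def flag_outlier_registrations(mean_hds, k_sd: float = 3.0) -> np.ndarray:
    """Leave-one-out outlier flags on per-registration mean Hausdorff distances.

    Entry i is flagged iff its mean HD exceeds mean(others) + k_sd * sd(others).
    The default multiplier is a conventional 3 SD; a grossly failed
    registration typically stands many SDs above the rest.
    """
    values = np.asarray(mean_hds, dtype=float)
    if values.ndim != 1 or len(values) < 3:
        raise ValueError("need at least 3 registrations for leave-one-out statistics")
    flags = np.zeros(len(values), dtype=bool)
    for i in range(len(values)):
        others = np.delete(values, i)
        flags[i] = values[i] > others.mean() + k_sd * others.std(ddof=1)
    return flags


def registration_rmse(registered_points: np.ndarray, target_surface: SurfaceMesh) -> float:
    """Root-mean-square point-to-surface distance (mm) of a registered cloud."""
    d = point_to_surface_distances(registered_points, target_surface)
    return float(np.sqrt(np.mean(d**2)))
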