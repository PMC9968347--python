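"""CT-like volumetric images, threshold segmentation and iso-surfacing.

Reproduces the imaging side of the measurement chain: intensity images in
Hounsfield-like units are thresholded into BONE / BONE-ST masks (bone and
bone-plus-soft-tissue, the latter defined by the > 700 HU rule), cement is
separated from bone by intensity banding, touching vertebrae are split, and
binary masks are converted back to world-coordinate surface meshes by
marching cubes.

Grid convention: ``data[i, j, k]`` lives at world coordinate
``origin + (i, j, k) * spacing`` (axis-aligned, right-handed, mm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes

from .mesh import SurfaceMesh, new_mesh

__all__ = [
    "VolumetricImage",
    "BinaryMask",
    "threshold_mask",
    "separate_cement",
    "split_vertebrae",
    "mask_to_mesh",
    "load_image",
    "save_image",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VolumetricImage:
    """3D scalar grid with voxel spacing and origin (axis-aligned, mm)."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("image data must be 3D")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def same_grid(self, other: "VolumetricImage | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask(VolumetricImage):
    """Boolean grid on the geometry of its source image, with a provenance tag."""

    tag: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(bool)

    @property
    def volume(self) -> float:
        """Summed voxel volume (mm^3)."""
        return float(np.count_nonzero(self.data)) * self.voxel_volume


def threshold_mask(image: VolumetricImage, lower_bound: float, tag: str = "BONE-ST") -> BinaryMask:
    """Voxels with intensity strictly above ``lower_bound`` (the > 700 HU rule)."""
    if not np.isfinite(lower_bound):
        raise ValueError("threshold must be finite")
    return BinaryMask(
        image.data > lower_bound, image.spacing, image.origin, tag=tag
    )


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def separate_cement(
    image: VolumetricImage,
    bone_band: tuple[float, float],
    cement_band: tuple[float, float],
) -> tuple[BinaryMask, BinaryMask]:
    """Split bone from injected cement by disjoint intensity bands.

    Each band keeps only its largest 26-connected component (an automated
    surrogate for the manual edits that separate vertebrae from cement);
    voxels in neither band are excluded.  Band intervals are half-open
    ``(lo, hi]``-style: ``lo < value <= hi``.
    """
    (b_lo, b_hi), (c_lo, c_hi) = bone_band, cement_band
    if b_lo >= b_hi or c_lo >= c_hi:
        raise ValueError("bands must be non-empty intervals")
    if max(b_lo, c_lo) < min(b_hi, c_hi):
        raise ValueError(f"bone band {bone_band} and cement band {cement_band} overlap")
    bone = (image.data > b_lo) & (image.data <= b_hi)
    cement = (image.data > c_lo) & (image.data <= c_hi)
    # bone keeps the two vertebrae: retain all components within 1% of the
    # largest two; cement is a single blob
    if bone.any():
        labels, n = ndimage.label(bone, structure=_CONN26)
        if n > 2:
            sizes = ndimage.sum_labels(
                np.ones_like(labels), labels, index=np.arange(1, n + 1)
            )
            keep = np.argsort(sizes)[::-1][:2] + 1
            bone = np.isin(labels, keep)
    if cement.any():
        cement = _largest_component(cement)
    return (
        BinaryMask(bone, image.spacing, image.origin, tag="BONE"),
        BinaryMask(cement, image.spacing, image.origin, tag="CEMENT"),
    )


def split_vertebrae(
    mask: BinaryMask,
    plane_point: np.ndarray | None = None,
    plane_normal: np.ndarray | None = None,
    axial_axis: int = 2,
) -> tuple[BinaryMask, BinaryMask]:
    """Split a bone mask into caudal and cranial vertebrae.

    Default method: the two largest 26-connected components.  When the
    vertebrae touch (single component), a separating world plane must be
    supplied; voxels are then assigned by plane side.  Caudal/cranial labels
    come from the component centroid position along ``axial_axis``.
    """
    data = mask.data
    if plane_point is not None and plane_normal is not None:
        xs, ys, zs = mask.voxel_centers()
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        side = (
            (X - plane_point[0]) * plane_normal[0]
            + (Y - plane_point[1]) * plane_normal[1]
            + (Z - plane_point[2]) * plane_normal[2]
        ) > 0
        parts = [data & ~side, data & side]
    else:
        labels, n = ndimage.label(data, structure=_CONN26)
        if n < 2:
            raise ValueError(
                "mask has a single connected component; supply a separating "
                "plane (plane_point, plane_normal) to split touching vertebrae"
            )
        sizes = ndimage.sum_labels(
            np.ones_like(labels), labels, index=np.arange(1, n + 1)
        )
        keep = np.argsort(sizes)[::-1][:2] + 1
        parts = [labels == keep[0], labels == keep[1]]
    centroids = []
    for p in parts:
        if not p.any():
            raise ValueError("plane split produced an empty side")
        idx = np.argwhere(p).mean(axis=0)
        centroids.append(mask.origin + idx * mask.spacing)
    if centroids[0][axial_axis] > centroids[1][axial_axis]:
        parts = parts[::-1]
    caudal = BinaryMask(parts[0], mask.spacing, mask.origin, tag=f"{mask.tag}-caudal")
    cranial = BinaryMask(parts[1], mask.spacing, mask.origin, tag=f"{mask.tag}-cranial")
    return caudal, cranial


def mask_to_mesh(mask: BinaryMask, iso_level: float = 0.5) -> SurfaceMesh:
    """Marching-cubes iso-surface of a binary mask in world coordinates.

    The iso-level sits on the binary mask (default 0.5), decoupling surface
    extraction from the HU threshold choice.  The grid is zero-padded so the
    output is watertight even when the mask touches the grid boundary.
    """
    if not mask.data.any():
        raise ValueError("cannot extract a surface from an empty mask")
    vol = np.pad(mask.data.astype(np.float32), 1)
    verts, faces, _, _ = marching_cubes(vol, level=iso_level)
    verts = (verts - 1.0) * mask.spacing + mask.origin
    return new_mesh(verts, faces.astype(np.int64))


def save_image(image: VolumetricImage, path: str | Path) -> None:
    """Write NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    path = Path(path)
    data = image.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    if path.suffix in {".mha", ".mhd"}:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
        img.SetSpacing(tuple(image.spacing))
        img.SetOrigin(tuple(image.origin))
        sitk.WriteImage(img, str(path))
    else:
        nib.save(nib.Nifti1Image(data, image.affine), str(path))


def load_image(path: str | Path) -> VolumetricImage:
    path = Path(path)
    if path.suffix in {".mha", ".mhd"}:
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).T
        return VolumetricImage(
            np.ascontiguousarray(data),
            np.asarray(img.GetSpacing()),
            np.asarray(img.GetOrigin()),
        )
    img = nib.load(str(path))
    aff = img.affine
    spacing = np.diag(aff)[:3].copy()
    if np.any(spacing <= 0) or not np.allclose(aff[:3, :3], np.diag(spacing)):
        raise ValueError("only axis-aligned images with positive spacing are supported")
    return VolumetricImage(np.asarray(img.dataobj), spacing, aff[:3, 3].copy())
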