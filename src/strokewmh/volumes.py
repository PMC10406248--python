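"""3D volume and mask primitives.

In-memory containers for scalar MRI volumes (:class:`Volume3D`) and binary
masks (:class:`LabelMask`) on a voxel grid with a NIfTI-style 4x4
voxel-to-world affine, plus the geometric operations the segmentation
pipeline needs: NIfTI I/O, application of given linear transforms,
millimetre-radius morphological dilation, connected components, and
Euclidean distance transforms.

Conventions
-----------
* Voxel indices are 0-based; world coordinates are millimetres obtained by
  applying the affine to homogeneous voxel indices.
* Masks are resampled with nearest-neighbour interpolation (binarity is
  preserved); intensity volumes with trilinear.
* Two images are grid-compatible when their shapes match and their affines
  agree within an absolute tolerance of 1e-4.
* Cluster connectivity defaults to 26 (vertex adjacency), the usual choice
  for lesion clusters; 6 and 18 are available everywhere a connectivity is
  taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume3D",
    "LabelMask",
    "AffineTransform",
    "GridError",
    "read_volume",
    "read_mask",
    "write_volume",
    "read_affine_matrix",
    "write_affine_matrix",
    "resample_affine",
    "dilate_mask",
    "connected_components",
    "distance_to_mask",
    "check_same_grid",
]

#: supported modality tags for Volume3D
MODALITIES = ("FLAIR", "T1", "T2", "PROB", "OTHER")
#: supported role tags for LabelMask
MASK_ROLES = ("WMH_GOLD", "STROKE", "BRAIN", "VENTRICLE", "WMH_AUTO")

GRID_ATOL = 1e-4


class GridError(ValueError):
    """Raised when two images that must share a grid do not."""


def _voxel_size_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


@dataclass
class Volume3D:
    """A scalar 3D image with its voxel-to-world geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities in arbitrary units.
    affine : ndarray, shape (4, 4)
        Voxel-to-world matrix (mm). Must be invertible.
    modality : str
        One of ``FLAIR, T1, T2, PROB, OTHER``.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    modality: str = "OTHER"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return _voxel_size_from_affine(self.affine)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def world_coordinates(self, voxel_index: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(voxel_index, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class LabelMask:
    """A binary 3D mask sharing the Volume3D grid conventions."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    role: str = "WMH_AUTO"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={arr.ndim}")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask values must be 0/1")
            arr = arr.astype(bool)
        self.data = arr
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}")

    shape = Volume3D.shape
    voxel_size = Volume3D.voxel_size
    voxel_volume_mm3 = Volume3D.voxel_volume_mm3
    world_coordinates = Volume3D.world_coordinates

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    def empty(self) -> bool:
        return not self.data.any()


@dataclass
class AffineTransform:
    """A linear world-to-world map with its interpolation policy.

    ``matrix`` maps source-space world coordinates to target-space world
    coordinates, the convention of FSL FLIRT ``.mat`` files after
    conversion to world coordinates. Only application is supported here;
    estimating transforms is out of scope.
    """

    matrix: np.ndarray
    interpolation: str = "trilinear"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("transform matrix is singular")
        if self.interpolation not in ("trilinear", "nearest"):
            raise ValueError("interpolation must be 'trilinear' or 'nearest'")

    @classmethod
    def identity(cls, interpolation: str = "trilinear") -> "AffineTransform":
        return cls(np.eye(4), interpolation)


# ---------------------------------------------------------------------------
# I/O


def read_volume(path: str | Path, modality: str = "OTHER") -> Volume3D:
    """Read a NIfTI-1 file as a :class:`Volume3D`.

    Raises
    ------
    ValueError
        If the image is not 3D.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    return Volume3D(np.asarray(data, dtype=np.float64), np.asarray(img.affine), modality)


def read_mask(path: str | Path, role: str = "WMH_AUTO") -> LabelMask:
    """Read a NIfTI-1 binary mask; values must be exactly {0, 1}."""
    vol = read_volume(path)
    return LabelMask(vol.data, vol.affine, role)


def write_volume(vol: Volume3D | LabelMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI-1 (.nii / .nii.gz)."""
    data = vol.data.astype(np.uint8) if isinstance(vol, LabelMask) else vol.data
    nib.Nifti1Image(data, vol.affine).to_filename(str(path))


def read_affine_matrix(path: str | Path) -> np.ndarray:
    """Read a plain-text 4-line whitespace-separated 4x4 matrix (FLIRT .mat dialect)."""
    mat = np.loadtxt(str(path))
    if mat.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got {mat.shape}")
    return mat


def write_affine_matrix(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(str(path), np.asarray(matrix, dtype=float), fmt="%.10f")


# ---------------------------------------------------------------------------
# Geometry


def check_same_grid(*images: Volume3D | LabelMask) -> None:
    """Raise :class:`GridError` unless all images share shape and affine.

    Affines must agree within 1e-4 absolute tolerance; a mismatch is an
    error, never a silent resample.
    """
    ref = images[0]
    for im in images[1:]:
        if im.shape != ref.shape:
            raise GridError(f"shape mismatch: {im.shape} vs {ref.shape}")
        if not np.allclose(im.affine, ref.affine, atol=GRID_ATOL, rtol=0):
            raise GridError("affine mismatch beyond 1e-4 tolerance")


def resample_affine(
    vol: Volume3D | LabelMask,
    transform: AffineTransform,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
) -> Volume3D | LabelMask:
    """Resample ``vol`` through a world-to-world linear transform onto a target grid.

    The value at target voxel ``v`` is sampled from the source at voxel
    ``A_src^-1 M^-1 A_tgt v`` where ``M`` is the transform matrix and
    ``A_src``, ``A_tgt`` the voxel-to-world affines. Masks always use
    nearest-neighbour interpolation regardless of the transform's policy,
    so binarity is preserved.
    """
    target_affine = np.asarray(target_affine, dtype=float)
    is_mask = isinstance(vol, LabelMask)
    order = 0 if (is_mask or transform.interpolation == "nearest") else 1

    full = np.linalg.inv(vol.affine) @ np.linalg.inv(transform.matrix) @ target_affine
    matrix, offset = full[:3, :3], full[:3, 3]

    src = vol.data.astype(np.float64)
    out = ndimage.affine_transform(
        src, matrix, offset=offset, output_shape=tuple(target_shape),
        order=order, mode="constant", cval=0.0,
    )
    if is_mask:
        return LabelMask(out > 0.5, target_affine, vol.role)
    return Volume3D(out, target_affine, vol.modality)


def _ball_footprint(radius_mm: float, voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Voxel offsets whose centre lies within ``radius_mm`` (anisotropy honoured)."""
    half = [int(np.floor(radius_mm / v)) for v in voxel_size]
    grids = np.ogrid[tuple(slice(-h, h + 1) for h in half)]
    dist2 = sum((g * v) ** 2 for g, v in zip(grids, voxel_size))
    return dist2 <= radius_mm**2 + 1e-9


def dilate_mask(mask: LabelMask, radius_mm: float) -> LabelMask:
    """Morphological dilation with a physical-millimetre ball.

    The structuring element contains every voxel-centre offset within
    Euclidean distance ``radius_mm`` of the origin, scaled per axis by the
    voxel size, so anisotropic grids dilate by the same physical distance
    in all directions.
    """
    if radius_mm < 0:
        raise ValueError("dilation radius must be >= 0")
    if radius_mm == 0 or mask.empty():
        return LabelMask(mask.data.copy(), mask.affine, mask.role)
    foot = _ball_footprint(radius_mm, mask.voxel_size)
    out = ndimage.binary_dilation(mask.data, structure=foot)
    return LabelMask(out, mask.affine, mask.role)


def _structure(connectivity: int) -> np.ndarray:
    try:
        rank = {6: 1, 18: 2, 26: 3}[int(connectivity)]
    except KeyError:
        raise ValueError("connectivity must be one of 6, 18, 26") from None
    return ndimage.generate_binary_structure(3, rank)


def connected_components(mask: LabelMask, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Label connected components under 6/18/26 adjacency.

    Returns
    -------
    labels : ndarray of int
        0 outside the mask, 1..n inside.
    n : int
        Component count.
    """
    labels, n = ndimage.label(mask.data, structure=_structure(connectivity))
    return labels, int(n)


def distance_to_mask(mask: LabelMask) -> Volume3D:
    """Exact Euclidean distance (mm) from each voxel centre to the nearest mask voxel centre.

    Zero inside the mask. Raises on an empty mask, for which the distance
    field is undefined.
    """
    if mask.empty():
        raise ValueError("distance_to_mask requires a non-empty mask")
    dist = ndimage.distance_transform_edt(~mask.data, sampling=mask.voxel_size)
    return Volume3D(dist, mask.affine, "OTHER")
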