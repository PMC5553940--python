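"""Volumes, voxel grids, segment masks, NIfTI I/O and grid resampling.

Conventions used throughout the package:

* world coordinates are in millimetres, axes right-handed and aligned with
  the voxel index axes (PET and CT are assumed pre-aligned, as on a PET/CT);
* ``origin`` is the world coordinate of the *center* of voxel ``(0, 0, 0)``;
* indices are 0-based; axial slices are constant-``z``-index planes;
* points resampled from outside the source extent get 0 (images) or
  ``False`` (masks) — conservative for max statistics.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .segments import validate_segment

__all__ = [
    "Units",
    "Interp",
    "VoxelGrid",
    "Image3D",
    "SegmentVOI",
    "read_volume",
    "write_volume",
    "read_voi_labels",
    "write_voi_labels",
    "resample",
    "transfer_voi",
]


class Units(enum.Enum):
    BQ_PER_ML = "Bq/ml"
    SUV = "SUV"
    DIMENSIONLESS = "1"


class Interp(enum.Enum):
    NEAREST = "nearest"
    TRILINEAR = "trilinear"


@dataclass(frozen=True)
class VoxelGrid:
    """Regular axis-aligned voxel lattice in world (mm) coordinates."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index-to-world affine (diagonal, voxel-center)."""
        aff = np.diag([*self.spacing, 1.0])
        aff[:3, 3] = self.origin
        return aff

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) world coordinates of the outermost voxel centers."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel index of world point(s)."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def overlaps(self, other: "VoxelGrid") -> bool:
        alo, ahi = self.world_extent()
        blo, bhi = other.world_extent()
        return bool(np.all(ahi >= blo) and np.all(bhi >= alo))


@dataclass
class Image3D:
    """Scalar volume on a :class:`VoxelGrid` with physical units."""

    grid: VoxelGrid
    values: np.ndarray
    units: Units = Units.BQ_PER_ML

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite voxels")
        if self.units is Units.BQ_PER_ML and np.any(self.values < 0):
            raise ValueError("activity concentration (Bq/ml) cannot be negative")

    def with_values(self, values: np.ndarray, units: Units | None = None) -> "Image3D":
        return Image3D(self.grid, values, self.units if units is None else units)


@dataclass
class SegmentVOI:
    """Named vascular-segment mask, decomposable into per-slice ROIs."""

    segment: str
    grid: VoxelGrid
    mask: np.ndarray

    def __post_init__(self) -> None:
        validate_segment(self.segment)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != grid shape {self.grid.shape}"
            )
        if not self.mask.any():
            raise ValueError(f"mask for segment {self.segment!r} is empty")

    @property
    def z_indices(self) -> np.ndarray:
        """Sorted axial slice indices on which the VOI has voxels."""
        return np.flatnonzero(self.mask.any(axis=(0, 1)))

    @property
    def slice_rois(self) -> list[tuple[int, np.ndarray]]:
        """(z-index, 2-D boolean ROI) pairs partitioning the mask by slice."""
        return [(int(z), self.mask[:, :, z]) for z in self.z_indices]

    @property
    def n_slices(self) -> int:
        return len(self.z_indices)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _grid_from_nifti(img: nib.Nifti1Image) -> VoxelGrid:
    aff = img.affine
    lin = aff[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-6):
        raise ValueError(
            "oblique/rotated NIfTI affines are not supported; "
            "volumes are assumed axis-aligned"
        )
    spacing = np.abs(np.diag(lin))
    # normalise negative-spacing (flipped) axes to the positive convention
    origin = aff[:3, 3].copy()
    return VoxelGrid(tuple(img.shape[:3]), tuple(spacing), tuple(origin))


def read_volume(path: str | Path, units: Units = Units.BQ_PER_ML) -> Image3D:
    """Read a 3-D NIfTI-1 volume.

    Grid spacing and origin come from the header; units are caller metadata
    (PET emission volumes default to Bq/ml). Non-finite voxels are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return Image3D(_grid_from_nifti(img), np.asarray(data, dtype=np.float64), units)


def write_volume(img: Image3D, path: str | Path) -> Path:
    """Write an :class:`Image3D` as NIfTI-1 (float64, lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nii = nib.Nifti1Image(img.values.astype(np.float64), img.grid.affine)
    nii.header.set_xyzt_units("mm")
    nib.save(nii, str(path))
    return path


def write_voi_labels(
    vois: list[SegmentVOI], path: str | Path
) -> tuple[Path, Path]:
    """Write VOIs as one integer label volume + sidecar JSON label map.

    All VOIs must share a grid. Label 0 is background; overlapping masks are
    rejected (segments are disjoint by construction).
    """
    if not vois:
        raise ValueError("no VOIs to write")
    grid = vois[0].grid
    labels = np.zeros(grid.shape, dtype=np.int16)
    mapping: dict[str, str] = {}
    for i, voi in enumerate(vois, start=1):
        if voi.grid != grid:
            raise ValueError("all VOIs must share one grid")
        if np.any(labels[voi.mask] != 0):
            raise ValueError(f"segment {voi.segment!r} overlaps another mask")
        labels[voi.mask] = i
        mapping[str(i)] = voi.segment
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nii = nib.Nifti1Image(labels, grid.affine)
    nib.save(nii, str(path))
    side = path.with_name(path.name.split(".")[0] + "_labels.json")
    side.write_text(json.dumps(mapping, indent=2))
    return path, side


def read_voi_labels(path: str | Path, sidecar: str | Path | None = None) -> list[SegmentVOI]:
    """Read a label volume + JSON label→segment map back into VOIs."""
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_name(path.name.split(".")[0] + "_labels.json")
    mapping = json.loads(Path(sidecar).read_text())
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj)
    grid = _grid_from_nifti(img)
    vois = []
    for lab, segment in sorted(mapping.items(), key=lambda kv: int(kv[0])):
        vois.append(SegmentVOI(segment, grid, labels == int(lab)))
    return vois


# ---------------------------------------------------------------------------
# Resampling


def _source_index_coords(source: VoxelGrid, target: VoxelGrid) -> np.ndarray:
    """Fractional source indices of every target voxel center, shape (3, *target)."""
    axes = [
        (np.asarray(target.origin[d])
         + np.arange(target.shape[d]) * target.spacing[d]
         - source.origin[d]) / source.spacing[d]
        for d in range(3)
    ]
    return np.stack(np.meshgrid(*axes, indexing="ij"))


def resample(img: Image3D, target: VoxelGrid, method: Interp = Interp.TRILINEAR) -> Image3D:
    """Rebin *img* onto *target* (the PET↔CT voxel-size experiment).

    NEAREST copies the value of the nearest source voxel center; TRILINEAR
    interpolates between the 8 neighbouring centers. Target voxels whose
    world point falls outside the source extent get 0.
    """
    if target == img.grid:
        return Image3D(img.grid, img.values.copy(), img.units)
    if not img.grid.overlaps(target):
        raise ValueError("target grid does not overlap the source physical extent")
    coords = _source_index_coords(img.grid, target)
    order = 0 if method is Interp.NEAREST else 1
    out = ndimage.map_coordinates(
        img.values, coords, order=order, mode="constant", cval=0.0, prefilter=False
    )
    return Image3D(target, out, img.units)


def transfer_voi(voi: SegmentVOI, target: VoxelGrid) -> SegmentVOI:
    """Transfer a segment mask to another grid (always nearest-neighbour).

    Raises if the transfer empties the mask (segment thinner than the target
    voxel), rather than returning a silently empty VOI.
    """
    if target == voi.grid:
        return SegmentVOI(voi.segment, voi.grid, voi.mask.copy())
    if not voi.grid.overlaps(target):
        raise ValueError("target grid does not overlap the VOI grid extent")
    coords = _source_index_coords(voi.grid, target)
    out = ndimage.map_coordinates(
        voi.mask.astype(np.uint8), coords, order=0, mode="constant", cval=0,
        prefilter=False,
    ).astype(bool)
    if not out.any():
        raise ValueError(
            f"transferring segment {voi.segment!r} to grid {target.spacing} mm "
            "emptied the mask (segment thinner than the target voxel)"
        )
    return SegmentVOI(voi.segment, target, out)
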