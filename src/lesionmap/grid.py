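"""Voxel grids and the core containers for binary lesion cohorts.

Everything downstream (simulation, labelling, inference, error fields) lives
on a single shared :class:`VoxelGrid`.  World coordinates are millimetres;
voxel indices are 0-based and row-major (the "canonical order" used wherever
a flat voxel ordering is needed, e.g. design-matrix columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid",
    "LesionMask",
    "LesionDataset",
    "Parcellation",
    "MaskBelowMinimumVolume",
    "GridMismatchError",
    "DEFAULT_MIN_LESION_MM3",
]

#: Minimum lesion volume in cubic millimetres applied at load time.
#: 216 mm^3 corresponds to 27 voxels at 2 mm isotropic resolution.
DEFAULT_MIN_LESION_MM3 = 216.0


class GridMismatchError(ValueError):
    """Raised when a volume does not live on the expected reference grid."""


class MaskBelowMinimumVolume(ValueError):
    """Signals that a lesion is below the configured minimum volume.

    Distinct from a hard failure: callers building cohorts typically catch
    this and *exclude* the subject rather than abort.
    """

    def __init__(self, subject_id: str, volume_mm3: float, minimum_mm3: float):
        self.subject_id = subject_id
        self.volume_mm3 = volume_mm3
        self.minimum_mm3 = minimum_mm3
        super().__init__(
            f"lesion {subject_id!r} has volume {volume_mm3:g} mm^3 "
            f"< minimum {minimum_mm3:g} mm^3"
        )


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel grid with an affine world mapping.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along each axis; all >= 1.
    spacing : tuple of float
        Voxel size in mm along each axis; all > 0.  Default 2 mm isotropic.
    origin : tuple of float
        World (mm) coordinate of the centre of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (diagonal spacing, translation = origin)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def world(self, voxels: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates (..., 3)."""
        voxels = np.asarray(voxels, dtype=float)
        return self.origin + voxels * np.asarray(self.spacing)

    def voxel(self, world_mm: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`world`: nearest voxel index for world coordinates."""
        world_mm = np.asarray(world_mm, dtype=float)
        idx = (world_mm - np.asarray(self.origin)) / np.asarray(self.spacing)
        return np.rint(idx).astype(int)

    def contains(self, voxel: tuple[int, int, int]) -> bool:
        return all(0 <= int(v) < d for v, d in zip(voxel, self.dims))

    def matches(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


def _as_binary(voxels: np.ndarray) -> np.ndarray:
    """Binarize an arbitrary volume: nonzero -> 1, zero/NaN -> 0."""
    arr = np.asarray(voxels)
    if arr.dtype == np.uint8 and arr.max(initial=0) <= 1:
        return arr.astype(np.uint8)
    arr = np.nan_to_num(np.asarray(arr, dtype=float), nan=0.0)
    return (arr != 0).astype(np.uint8)


@dataclass(frozen=True)
class LesionMask:
    """A single subject's binary lesion mask on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    voxels: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        vox = _as_binary(self.voxels)
        if tuple(vox.shape) != self.grid.dims:
            raise GridMismatchError(
                f"mask shape {vox.shape} does not match grid dims {self.grid.dims}"
            )
        vox.setflags(write=False)
        object.__setattr__(self, "voxels", vox)

    @property
    def n_lesion_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_lesion_voxels * self.grid.voxel_volume_mm3

    def check_minimum_volume(self, minimum_mm3: float = DEFAULT_MIN_LESION_MM3) -> "LesionMask":
        if self.volume_mm3 < minimum_mm3:
            raise MaskBelowMinimumVolume(self.subject_id, self.volume_mm3, minimum_mm3)
        return self


@dataclass
class LesionDataset:
    """An ordered cohort of co-registered binary lesion masks.

    ``hit_count`` (per-voxel number of subjects damaged there) is computed on
    construction and kept consistent with the masks.
    """

    grid: VoxelGrid
    masks: list[LesionMask]
    hit_count: np.ndarray = field(init=False)

    def __post_init__(self):
        if not self.masks:
            raise ValueError("a LesionDataset requires at least one mask")
        for m in self.masks:
            if not m.grid.matches(self.grid):
                raise GridMismatchError(
                    f"mask {m.subject_id!r} grid differs from dataset grid"
                )
        self.hit_count = self.stack().sum(axis=0, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.masks)

    def stack(self) -> np.ndarray:
        """(N, *dims) uint8 array of all masks in cohort order."""
        return np.stack([m.voxels for m in self.masks])

    @property
    def subject_ids(self) -> list[str]:
        return [m.subject_id for m in self.masks]


@dataclass(frozen=True)
class Parcellation:
    """Integer-labelled candidate critical areas on a grid (0 = unassigned)."""

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if tuple(lab.shape) != self.grid.dims:
            raise GridMismatchError(
                f"label volume shape {lab.shape} does not match grid dims {self.grid.dims}"
            )
        if lab.min(initial=0) < 0 or not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("parcellation labels must be non-negative integers")
        lab = lab.astype(np.int32)
        lab.setflags(write=False)
        object.__setattr__(self, "labels", lab)

    @property
    def area_ids(self) -> set[int]:
        ids = np.unique(self.labels)
        return {int(i) for i in ids if i > 0}

    def area_voxels(self, area_id: int) -> np.ndarray:
        """(M, 3) voxel indices of one area, in canonical (row-major) order."""
        vox = np.argwhere(self.labels == area_id)
        if vox.size == 0:
            raise ValueError(f"area {area_id} labels no voxels")
        return vox

    def area_mask(self, area_ids) -> np.ndarray:
        """Boolean volume covering the union of the given areas."""
        if np.isscalar(area_ids):
            area_ids = [area_ids]
        return np.isin(self.labels, list(area_ids))

    def area_centre_mm(self, area_id: int) -> np.ndarray:
        """Unweighted centre of mass of an area, in world mm."""
        return self.grid.world(self.area_voxels(area_id)).mean(axis=0)


def warn_hemisphere_tie(subject_id: str) -> None:
    warnings.warn(
        f"lesion {subject_id!r} has exactly equal volume in both hemispheres; "
        "retaining the canonical hemisphere without flipping",
        stacklevel=3,
    )
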