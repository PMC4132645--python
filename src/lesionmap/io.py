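"""NIfTI / TSV input-output and spatial normalization of lesion masks.

The package starts from co-registered binary masks: reading binarizes
(nonzero -> damaged, NaN -> undamaged), checks the grid against an optional
reference, and applies the minimum-lesion-volume exclusion (default 216 mm^3).
Hemisphere collapsing mirrors each lesion onto one canonical half of the
first axis, as done before group analysis of unilateral stroke.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

from .fields import ErrorVectorField
from .grid import (
    DEFAULT_MIN_LESION_MM3,
    GridMismatchError,
    LesionDataset,
    LesionMask,
    Parcellation,
    VoxelGrid,
    warn_hemisphere_tie,
)

__all__ = [
    "grid_from_image",
    "read_mask_volume",
    "read_parcellation",
    "write_volume",
    "write_mask",
    "write_dataset",
    "read_dataset",
    "collapse_to_hemisphere",
    "overlap_map",
    "export_vector_field",
    "read_vector_field_nifti",
]


def grid_from_image(img: nib.Nifti1Image) -> VoxelGrid:
    """Extract a :class:`VoxelGrid` from a NIfTI header/affine.

    Only the diagonal (zoom) part of the affine defines spacing; the
    translation column defines the origin.  Obliquely rotated volumes are
    rejected: the pipeline assumes axis-aligned, co-registered data.
    """
    aff = np.asarray(img.affine, dtype=float)
    rot = aff[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-4):
        raise GridMismatchError("only axis-aligned (diagonal-affine) volumes are supported")
    spacing = tuple(float(abs(z)) for z in np.diag(rot))
    return VoxelGrid(dims=tuple(int(d) for d in img.shape[:3]),
                     spacing=spacing,
                     origin=tuple(float(t) for t in aff[:3, 3]))


def read_mask_volume(
    path: str | os.PathLike,
    reference_grid: VoxelGrid | None = None,
    min_volume_mm3: float = DEFAULT_MIN_LESION_MM3,
    subject_id: str | None = None,
) -> LesionMask:
    """Read one binary lesion mask from a NIfTI file.

    Nonzero voxels map to 1, zero/NaN to 0.  Raises
    :class:`~lesionmap.grid.GridMismatchError` if the volume does not live on
    ``reference_grid`` (resampling is never attempted), and
    :class:`~lesionmap.grid.MaskBelowMinimumVolume` if the lesion is smaller
    than ``min_volume_mm3`` — an exclusion signal, not a hard failure.
    """
    img = nib.load(os.fspath(path))
    grid = grid_from_image(img)
    if reference_grid is not None and not grid.matches(reference_grid):
        raise GridMismatchError(f"{path}: grid differs from the reference grid")
    if subject_id is None:
        subject_id = os.path.basename(os.fspath(path)).split(".")[0]
    mask = LesionMask(grid=grid, voxels=np.asanyarray(img.dataobj), subject_id=subject_id)
    return mask.check_minimum_volume(min_volume_mm3)


def read_parcellation(path: str | os.PathLike,
                      reference_grid: VoxelGrid | None = None) -> Parcellation:
    img = nib.load(os.fspath(path))
    grid = grid_from_image(img)
    if reference_grid is not None and not grid.matches(reference_grid):
        raise GridMismatchError(f"{path}: grid differs from the reference grid")
    labels = np.rint(np.nan_to_num(np.asanyarray(img.dataobj), nan=0.0)).astype(np.int32)
    return Parcellation(grid=grid, labels=labels)


def write_volume(data: np.ndarray, grid: VoxelGrid, path: str | os.PathLike,
                 dtype=None) -> None:
    """Write a scalar volume on ``grid`` to NIfTI."""
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    nib.save(nib.Nifti1Image(arr, grid.affine), os.fspath(path))


def write_mask(mask: LesionMask, path: str | os.PathLike) -> None:
    write_volume(mask.voxels, mask.grid, path, dtype=np.uint8)


def write_dataset(dataset: LesionDataset, out_dir: str | os.PathLike,
                  manifest_extra: dict | None = None) -> pd.DataFrame:
    """Write a cohort as one NIfTI per subject plus a TSV manifest."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, mask in enumerate(dataset.masks):
        sid = mask.subject_id or f"sub-{i:04d}"
        fname = f"{sid}.nii"
        write_mask(mask, os.path.join(out_dir, fname))
        row = {"subject_id": sid, "file": fname,
               "n_voxels": mask.n_lesion_voxels, "volume_mm3": mask.volume_mm3}
        if manifest_extra:
            row.update(manifest_extra)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    return manifest


def read_dataset(in_dir: str | os.PathLike,
                 min_volume_mm3: float = DEFAULT_MIN_LESION_MM3) -> LesionDataset:
    """Read a cohort written by :func:`write_dataset` (manifest order)."""
    in_dir = os.fspath(in_dir)
    manifest = pd.read_csv(os.path.join(in_dir, "manifest.tsv"), sep="\t")
    masks, grid = [], None
    for _, row in manifest.iterrows():
        m = read_mask_volume(os.path.join(in_dir, row["file"]), reference_grid=grid,
                             min_volume_mm3=min_volume_mm3,
                             subject_id=str(row["subject_id"]))
        grid = grid or m.grid
        masks.append(m)
    return LesionDataset(grid=grid, masks=masks)


def collapse_to_hemisphere(mask: LesionMask, midline_index: int) -> LesionMask:
    """Project a lesion onto the canonical hemisphere of the first axis.

    The canonical hemisphere is ``i < midline_index``.  The hemisphere holding
    the larger share of the lesion is retained; if that is the non-canonical
    side the volume is mirrored about the inter-voxel midplane
    (``i <-> dims[0]-1-i``), which preserves the grid without interpolation.
    An exact volume tie keeps the canonical side unflipped (with a warning).
    Applying the operation twice equals applying it once.
    """
    d = mask.grid.dims[0]
    if not 0 < midline_index < d:
        raise ValueError(f"midline_index must split the first axis, got {midline_index}")
    vox = mask.voxels
    n_left = int(vox[:midline_index].sum())
    n_right = int(vox[midline_index:].sum())
    if n_left == 0 and n_right == 0:
        raise ValueError(f"lesion {mask.subject_id!r} is empty; cannot collapse")
    if n_right > n_left:
        vox = vox[::-1]
    elif n_right == n_left and n_right > 0 and n_left > 0:
        warn_hemisphere_tie(mask.subject_id)
    out = np.array(vox)
    out[midline_index:] = 0
    return LesionMask(grid=mask.grid, voxels=out, subject_id=mask.subject_id)


def overlap_map(dataset: LesionDataset) -> np.ndarray:
    """Per-voxel count of subjects lesioned there (the cohort overlap map)."""
    return dataset.stack().sum(axis=0, dtype=np.int64)


def export_vector_field(field: ErrorVectorField, path: str | os.PathLike,
                        format: str = "tsv") -> None:
    """Write an error vector field to disk.

    ``tsv`` writes one row per evaluated voxel with indices, world mm
    coordinates, the displacement vector in mm and its magnitude.
    ``nifti-triplet`` writes four volumes next to ``path``: dx/dy/dz (mm)
    plus a magnitude volume, NaN outside the evaluated set.
    """
    path = os.fspath(path)
    if format == "tsv":
        pos = field.grid.world(field.voxels) if len(field) else np.empty((0, 3))
        df = pd.DataFrame({
            "i": field.voxels[:, 0], "j": field.voxels[:, 1], "k": field.voxels[:, 2],
            "x_mm": pos[:, 0], "y_mm": pos[:, 1], "z_mm": pos[:, 2],
            "dx_mm": field.vectors[:, 0], "dy_mm": field.vectors[:, 1],
            "dz_mm": field.vectors[:, 2],
            "magnitude_mm": field.magnitudes,
        })
        df.to_csv(path, sep="\t", index=False)
    elif format == "nifti-triplet":
        base = path
        for suffix in (".nii.gz", ".nii"):
            if base.endswith(suffix):
                base = base[: -len(suffix)]
        comps = np.full((4,) + field.grid.dims, np.nan, dtype=np.float64)
        idx = tuple(field.voxels.T)
        for c in range(3):
            comps[c][idx] = field.vectors[:, c]
        comps[3][idx] = field.magnitudes
        for c, name in enumerate(("dx", "dy", "dz", "magnitude")):
            write_volume(comps[c], field.grid, f"{base}_{name}.nii")
    else:
        raise ValueError(f"unknown vector-field format {format!r}")


def read_vector_field_nifti(base_path: str | os.PathLike) -> ErrorVectorField:
    """Read back a ``nifti-triplet`` written by :func:`export_vector_field`."""
    base = os.fspath(base_path)
    imgs = [nib.load(f"{base}_{name}.nii") for name in ("dx", "dy", "dz")]
    grid = grid_from_image(imgs[0])
    comps = np.stack([np.asanyarray(img.dataobj) for img in imgs])
    defined = ~np.isnan(comps[0])
    voxels = np.argwhere(defined)
    vectors = comps[:, defined].T
    return ErrorVectorField(grid=grid, voxels=voxels, vectors=vectors)
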