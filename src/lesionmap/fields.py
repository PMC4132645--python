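"""Displacement (error) vector fields on a voxel grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VoxelGrid

__all__ = ["ErrorVectorField"]


@dataclass
class ErrorVectorField:
    """Per-voxel displacement vectors from a true locus to an inferred one.

    ``voxels`` holds the evaluated voxel indices (M, 3) whose models produced
    a non-empty significant set; ``vectors`` the matching (M, 3) displacement
    in mm (inferred minus true).  ``failures`` (F, 3) lists evaluated voxels
    whose models produced an empty significant set; the two sets are disjoint
    and together cover every evaluated voxel.
    """

    grid: VoxelGrid
    voxels: np.ndarray
    vectors: np.ndarray
    failures: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=int))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=int).reshape(-1, 3)
        self.vectors = np.asarray(self.vectors, dtype=float).reshape(-1, 3)
        self.failures = np.asarray(self.failures, dtype=int).reshape(-1, 3)
        if len(self.voxels) != len(self.vectors):
            raise ValueError("voxels and vectors must have equal length")
        if len(self.voxels) and len(self.failures):
            both = set(map(tuple, self.voxels)) & set(map(tuple, self.failures))
            if both:
                raise ValueError(f"voxels and failures overlap at {sorted(both)[:3]}")

    def __len__(self) -> int:
        return len(self.voxels)

    @property
    def magnitudes(self) -> np.ndarray:
        """Euclidean norm (mm) of each displacement vector."""
        return np.linalg.norm(self.vectors, axis=1)

    @property
    def mean_magnitude_mm(self) -> float:
        return float(self.magnitudes.mean()) if len(self) else float("nan")

    @property
    def mean_vector_mm(self) -> np.ndarray:
        return self.vectors.mean(axis=0) if len(self) else np.full(3, np.nan)

    def plot_slice(self, axis: int = 2, index: int | None = None, ax=None):
        """Quiver plot of the in-plane error vectors on one grid slice."""
        import matplotlib.pyplot as plt

        if index is None:
            index = self.grid.dims[axis] // 2
        keep = self.voxels[:, axis] == index
        plane = [a for a in range(3) if a != axis]
        if ax is None:
            _, ax = plt.subplots()
        pos = self.grid.world(self.voxels[keep])
        vec = self.vectors[keep]
        ax.quiver(pos[:, plane[0]], pos[:, plane[1]], vec[:, plane[0]], vec[:, plane[1]],
                  self.magnitudes[keep], angles="xy")
        ax.set_xlabel(f"axis {plane[0]} (mm)")
        ax.set_ylabel(f"axis {plane[1]} (mm)")
        ax.set_title(f"mislocalization vectors, axis {axis} = {index}")
        return ax
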