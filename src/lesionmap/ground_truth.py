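"""Hypothetical lesion-deficit models and subject labelling.

A ground-truth model posits which tissue is critical — a single voxel, or a
set of parcellation areas with a damage-fraction criterion — and labels each
subject 'affected' (1) or 'unaffected' (0) from their lesion alone.  The
area criterion may be made stochastic: a subject meeting the damage
criterion expresses the deficit only with ``deficit_probability`` (default
0.9), while subjects failing the criterion are *never* labelled affected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np

from ._seeds import spawn_rng
from .grid import LesionDataset, Parcellation

__all__ = [
    "GroundTruthSpec",
    "LabelVector",
    "label_single_voxel",
    "label_area_model",
    "tested_voxels",
    "DEFAULT_MIN_HITS",
]

#: A voxel must be hit at least this many times to be tested / modelled.
DEFAULT_MIN_HITS = 4


@dataclass(frozen=True)
class GroundTruthSpec:
    """A hypothetical lesion-deficit model.

    kind
        ``single-voxel`` (target = one voxel index) or ``area-set``
        (target = one or more parcellation area ids; a subject meets the
        criterion if *any* target area has at least ``damage_fraction`` of
        its voxels lesioned — union semantics).
    damage_fraction
        Fraction in (0, 1] of an area's voxels that must be damaged
        (inclusive threshold; compared with exact rational arithmetic).
        Default 0.20.
    deficit_probability
        Probability in (0, 1] that a criterion-meeting subject expresses the
        deficit.  Default 0.90; single-voxel models are deterministic
        (probability forced to 1) unless overridden.
    """

    kind: str
    target: tuple
    damage_fraction: float = 0.20
    deficit_probability: float = 0.90
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("single-voxel", "area-set"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "single-voxel":
            object.__setattr__(self, "deficit_probability", 1.0)
            target = tuple(int(t) for t in self.target)
            if len(target) != 3:
                raise ValueError("single-voxel target must be an (i, j, k) triple")
        else:
            target = tuple(int(t) for t in np.atleast_1d(np.asarray(self.target)).ravel())
            if not target:
                raise ValueError("area-set target must name at least one area")
        object.__setattr__(self, "target", target)
        if not 0 < self.damage_fraction <= 1:
            raise ValueError("damage_fraction must be in (0, 1]")
        if not 0 < self.deficit_probability <= 1:
            raise ValueError("deficit_probability must be in (0, 1]")

    def noiseless(self) -> "GroundTruthSpec":
        """The same model with the deficit made deterministic."""
        return replace(self, deficit_probability=1.0)


@dataclass(frozen=True)
class LabelVector:
    """Binary affected/unaffected labels aligned with a cohort's masks."""

    labels: np.ndarray
    spec: GroundTruthSpec | None = None

    def __post_init__(self):
        lab = np.asarray(self.labels).astype(np.int8)
        if lab.ndim != 1 or not np.isin(lab, (0, 1)).all():
            raise ValueError("labels must be a 1-D binary vector")
        lab.setflags(write=False)
        object.__setattr__(self, "labels", lab)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_affected(self) -> int:
        return int(self.labels.sum())

    @property
    def single_class(self) -> bool:
        return self.n_affected in (0, len(self))

    def to_tsv(self, path, subject_ids=None) -> None:
        import pandas as pd

        ids = subject_ids if subject_ids is not None else range(len(self))
        with open(path, "w") as fh:
            if self.spec is not None:
                fh.write(f"# ground truth: {self.spec}\n")
            pd.DataFrame({"subject_id": list(ids), "label": self.labels}).to_csv(
                fh, sep="\t", index=False
            )


def label_single_voxel(dataset: LesionDataset, voxel) -> LabelVector:
    """Label subjects by damage at one voxel: affected iff it is lesioned."""
    voxel = tuple(int(v) for v in voxel)
    if not dataset.grid.contains(voxel):
        raise ValueError(f"voxel {voxel} outside grid {dataset.grid.dims}")
    labels = np.array([m.voxels[voxel] for m in dataset.masks], dtype=np.int8)
    spec = GroundTruthSpec(kind="single-voxel", target=voxel)
    return LabelVector(labels=labels, spec=spec)


def _meets_fraction(damaged: int, area_size: int, fraction: float) -> bool:
    # exact rational comparison so 2/10 >= 0.20 is inclusive, never a float miss
    q = Fraction(str(fraction))
    return damaged * q.denominator >= q.numerator * area_size


def label_area_model(
    dataset: LesionDataset,
    parcellation: Parcellation,
    spec: GroundTruthSpec,
) -> LabelVector:
    """Label subjects by the area-damage criterion of ``spec``.

    A subject meets the criterion if any target area has at least
    ``spec.damage_fraction`` of its voxels lesioned; the label is then drawn
    once per subject as Bernoulli(``deficit_probability``) with the spec
    seed.  Subjects failing the criterion are always unaffected.
    """
    if spec.kind != "area-set":
        raise ValueError("label_area_model requires an area-set spec")
    missing = [a for a in spec.target if a not in parcellation.area_ids]
    if missing:
        raise ValueError(f"target areas {missing} absent from the parcellation")
    area_masks = [parcellation.labels == a for a in spec.target]
    sizes = [int(am.sum()) for am in area_masks]
    stack = dataset.stack()
    criterion = np.zeros(len(dataset), dtype=bool)
    for am, size in zip(area_masks, sizes):
        damaged = stack[:, am].sum(axis=1)
        criterion |= np.array(
            [_meets_fraction(int(d), size, spec.damage_fraction) for d in damaged]
        )
    if spec.deficit_probability < 1.0:
        rng = spawn_rng(spec.seed, "deficit-coin", spec.target, spec.damage_fraction)
        coins = rng.random(len(dataset)) < spec.deficit_probability
        labels = criterion & coins
    else:
        labels = criterion
    return LabelVector(labels=labels.astype(np.int8), spec=spec)


def tested_voxels(dataset: LesionDataset, min_hits: int = DEFAULT_MIN_HITS) -> np.ndarray:
    """Voxels hit at least ``min_hits`` times, in canonical (row-major) order.

    Returns an (M, 3) integer array; this ordering is the canonical flat
    voxel order used for p-maps and design-matrix columns.
    """
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    return np.argwhere(dataset.hit_count >= min_hits)
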