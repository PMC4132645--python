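"""Model sweeps quantifying systematic mislocalization of VLSM.

The central object is the error vector field: for every adequately sampled
voxel, posit that voxel as the critical locus, label the cohort from it,
run the mass-univariate analysis, and record the displacement (mm) from the
true locus to the inferred one (centre of mass or peak of the significant
set).  Area-model sweeps do the same with parcellation areas under the
damage-fraction criterion, including a sweep of that fraction and
two-distant-areas models where the union of two areas is critical.

All sweeps are pure functions of their inputs: per-model computation uses
only counts, so results are invariant to subject ordering, and every model
is evaluated in the canonical voxel/area order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .fields import ErrorVectorField
from .grid import LesionDataset, Parcellation
from .ground_truth import (
    DEFAULT_MIN_HITS,
    GroundTruthSpec,
    label_area_model,
    tested_voxels,
)
from .mass_univariate import (
    PMap,
    SignificanceResult,
    bonferroni_threshold,
    displacement,
    fisher_p_vector,
    significance,
    top_k_voxels,
)
from .metrics import dice_coefficient

__all__ = [
    "SweepSummary",
    "ThresholdSweepResult",
    "MultiAreaResult",
    "single_voxel_sweep",
    "area_model_sweep",
    "threshold_sweep",
    "multi_area_model",
    "DEFAULT_FRACTIONS",
]

#: Damage-fraction grid for the threshold sweep: 5% to 60% in 5% bins.
DEFAULT_FRACTIONS = tuple(np.round(np.arange(1, 13) * 0.05, 2))


@dataclass(frozen=True)
class SweepSummary:
    """Aggregate displacement statistics over a family of models.

    ``mean_mm``/``sd_mm`` are computed over models that produced a
    non-empty significant set (failures are recorded, not averaged); the
    standard deviation is population-style (denominator n) by default.
    """

    mean_mm: float
    sd_mm: float
    n_models: int
    n_failures: int
    per_model: pd.DataFrame
    locus_mode: str = "com"

    @property
    def n_successes(self) -> int:
        return self.n_models - self.n_failures

    @property
    def mean_vector_mm(self) -> np.ndarray:
        ok = self.per_model[~self.per_model["failed"]]
        if len(ok) == 0:
            return np.full(3, np.nan)
        return ok[["dx_mm", "dy_mm", "dz_mm"]].to_numpy().mean(axis=0)


def _summarize(rows: list[dict], locus_mode: str, ddof: int = 0) -> SweepSummary:
    cols = ["model_id", "n_significant", "dx_mm", "dy_mm", "dz_mm",
            "magnitude_mm", "failed"]
    if rows and "true_p" in rows[0]:
        cols += ["true_p", "true_significant"]
    per_model = pd.DataFrame(rows, columns=cols)
    mags = per_model.loc[~per_model["failed"], "magnitude_mm"].to_numpy(dtype=float)
    if len(mags):
        mean = float(mags.mean())
        sd = float(mags.std(ddof=ddof)) if len(mags) > ddof else 0.0
    else:
        mean, sd = float("nan"), float("nan")
    return SweepSummary(
        mean_mm=mean, sd_mm=sd, n_models=len(per_model),
        n_failures=int(per_model["failed"].sum()), per_model=per_model,
        locus_mode=locus_mode,
    )


class _SweepEngine:
    """Shared per-cohort state: the tested-voxel design and margin groups."""

    def __init__(self, dataset: LesionDataset, min_hits: int):
        self.dataset = dataset
        self.grid = dataset.grid
        self.tested = tested_voxels(dataset, min_hits)
        if len(self.tested) == 0:
            raise ValueError("no voxel reaches min_hits; nothing to sweep")
        stack = dataset.stack()
        self.X = stack[:, self.tested[:, 0], self.tested[:, 1], self.tested[:, 2]]
        self.Xf = self.X.astype(np.float32)
        self.m = self.X.sum(axis=0, dtype=np.int64)
        self.n = len(dataset)
        self.world = self.grid.world(self.tested)

    def pmap_for(self, y: np.ndarray, mode: str = "exact") -> PMap:
        a = np.rint(y.astype(np.float32) @ self.Xf).astype(np.int64)
        p = fisher_p_vector(a, self.m, int(y.sum()), self.n, mode=mode)
        return PMap(grid=self.grid, voxels=self.tested, p=p)

    def significance_for_counts(
        self, a: np.ndarray, k: int, threshold: float, mode: str
    ) -> SignificanceResult:
        p = fisher_p_vector(a, self.m, k, self.n, mode=mode)
        return significance(
            PMap(grid=self.grid, voxels=self.tested, p=p), threshold
        )


def single_voxel_sweep(
    dataset: LesionDataset,
    min_hits: int = DEFAULT_MIN_HITS,
    alpha: float = 0.01,
    locus_mode: str = "com",
    mode: str = "exact",
    chunk: int = 256,
) -> tuple[ErrorVectorField, SweepSummary]:
    """Build the error vector field over every adequately sampled voxel.

    For each tested voxel: label the cohort by damage at that voxel, compute
    the Fisher p-map over all tested voxels, threshold at the
    Bonferroni-corrected ``alpha``, and record the displacement from the
    true voxel to the significant set's centre of mass (or peak).  Models
    with an empty significant set are recorded as failures.
    """
    eng = _SweepEngine(dataset, min_hits)
    V = len(eng.tested)
    thr = bonferroni_threshold(alpha, V)
    vectors, ok_vox, fail_vox, rows = [], [], [], []
    for start in range(0, V, chunk):
        idx = np.arange(start, min(start + chunk, V))
        # overlap counts between each model voxel and every tested voxel
        A = np.rint(eng.Xf[:, idx].T @ eng.Xf).astype(np.int64)
        for row, v in zip(A, idx):
            k = int(eng.m[v])
            p = fisher_p_vector(row, eng.m, k, eng.n, mode=mode)
            sig = p < thr
            model_id = f"voxel-{tuple(eng.tested[v])}"
            true_p = float(p[v])
            true_sig = bool(sig[v])
            if not sig.any():
                fail_vox.append(eng.tested[v])
                rows.append(dict(model_id=model_id, n_significant=0,
                                 dx_mm=np.nan, dy_mm=np.nan, dz_mm=np.nan,
                                 magnitude_mm=np.nan, failed=True,
                                 true_p=true_p, true_significant=true_sig))
                continue
            if locus_mode == "com":
                locus = eng.world[sig].mean(axis=0)
            elif locus_mode == "peak":
                psig = p[sig]
                peak = eng.world[sig][psig <= psig.min() * (1 + 1e-12)]
                locus = peak.mean(axis=0)
            else:
                raise ValueError(f"unknown locus_mode {locus_mode!r}")
            vec, mag = displacement(eng.world[v], locus)
            ok_vox.append(eng.tested[v])
            vectors.append(vec)
            rows.append(dict(model_id=model_id, n_significant=int(sig.sum()),
                             dx_mm=vec[0], dy_mm=vec[1], dz_mm=vec[2],
                             magnitude_mm=mag, failed=False,
                             true_p=true_p, true_significant=true_sig))
    field = ErrorVectorField(
        grid=eng.grid,
        voxels=np.array(ok_vox).reshape(-1, 3),
        vectors=np.array(vectors).reshape(-1, 3),
        failures=np.array(fail_vox).reshape(-1, 3),
    )
    return field, _summarize(rows, locus_mode)


def area_model_sweep(
    dataset: LesionDataset,
    parcellation: Parcellation,
    spec_template: GroundTruthSpec | None = None,
    areas: list[int] | None = None,
    locus_mode: str = "com",
    alpha: float = 0.01,
    min_hits: int = DEFAULT_MIN_HITS,
    mode: str = "exact",
) -> SweepSummary:
    """One area-criterion model per area; displacement from the area's
    centre of mass to the inferred locus."""
    eng = _SweepEngine(dataset, min_hits)
    thr = bonferroni_threshold(alpha, len(eng.tested))
    areas = sorted(parcellation.area_ids) if areas is None else list(areas)
    if spec_template is None:
        spec_template = GroundTruthSpec(kind="area-set", target=tuple(areas))
    rows = []
    for area in areas:
        spec = replace(spec_template, kind="area-set", target=(int(area),))
        labels = label_area_model(dataset, parcellation, spec)
        model_id = f"area-{area}"
        if labels.single_class:
            rows.append(dict(model_id=model_id, n_significant=0,
                             dx_mm=np.nan, dy_mm=np.nan, dz_mm=np.nan,
                             magnitude_mm=np.nan, failed=True))
            continue
        pmap = eng.pmap_for(labels.labels)
        sig = significance(pmap, thr)
        if sig.empty:
            rows.append(dict(model_id=model_id, n_significant=0,
                             dx_mm=np.nan, dy_mm=np.nan, dz_mm=np.nan,
                             magnitude_mm=np.nan, failed=True))
            continue
        true_mm = parcellation.area_centre_mm(int(area))
        vec, mag = displacement(true_mm, sig.locus_mm(locus_mode))
        rows.append(dict(model_id=model_id, n_significant=sig.n_significant,
                         dx_mm=vec[0], dy_mm=vec[1], dz_mm=vec[2],
                         magnitude_mm=mag, failed=False))
    return _summarize(rows, locus_mode)


@dataclass(frozen=True)
class ThresholdSweepResult:
    """Area-model sweeps across a grid of damage fractions."""

    fractions: tuple[float, ...]
    summaries: list[SweepSummary]
    mean_of_means_mm: float
    sd_across_fractions_mm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "mean_mm": [s.mean_mm for s in self.summaries],
                "sd_mm": [s.sd_mm for s in self.summaries],
                "n_models": [s.n_models for s in self.summaries],
                "n_failures": [s.n_failures for s in self.summaries],
            }
        )


def threshold_sweep(
    dataset: LesionDataset,
    parcellation: Parcellation,
    areas: list[int] | None = None,
    fractions=DEFAULT_FRACTIONS,
    spec_template: GroundTruthSpec | None = None,
    **kwargs,
) -> ThresholdSweepResult:
    """Repeat the area-model sweep across damage-fraction bins (default
    5%..60% in 5% steps, 12 bins)."""
    fractions = tuple(float(f) for f in fractions)
    if not fractions or any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must be non-empty, each in (0, 1]")
    areas = sorted(parcellation.area_ids) if areas is None else list(areas)
    if spec_template is None:
        spec_template = GroundTruthSpec(kind="area-set", target=tuple(areas))
    summaries = [
        area_model_sweep(
            dataset, parcellation,
            spec_template=replace(spec_template, damage_fraction=f),
            areas=areas, **kwargs,
        )
        for f in fractions
    ]
    means = np.array([s.mean_mm for s in summaries], dtype=float)
    ok = ~np.isnan(means)
    mean_of_means = float(means[ok].mean()) if ok.any() else float("nan")
    sd_across = float(means[ok].std(ddof=0)) if ok.any() else float("nan")
    return ThresholdSweepResult(
        fractions=fractions, summaries=summaries,
        mean_of_means_mm=mean_of_means, sd_across_fractions_mm=sd_across,
    )


@dataclass(frozen=True)
class MultiAreaResult:
    """Mass-univariate analysis of a two-distant-areas ground truth."""

    spec: GroundTruthSpec
    significance: SignificanceResult
    retained: np.ndarray  # (k, 3) most-significant voxels (display-matched)
    k: int
    dice_retained: float  # Dice(retained, union of true areas)
    retained_com_mm: np.ndarray
    displacements: pd.DataFrame  # per true area + union com offsets


def multi_area_model(
    dataset: LesionDataset,
    parcellation: Parcellation,
    area_pair,
    spec: GroundTruthSpec | None = None,
    k: int | None = None,
    alpha: float = 0.01,
    min_hits: int = DEFAULT_MIN_HITS,
    mode: str = "exact",
) -> MultiAreaResult:
    """Model a deficit critical on *either* of two areas (union rule).

    Besides the Bonferroni significance result, a display-matched retained
    set of exactly ``k`` most-significant voxels is extracted (default
    ``k`` = number of voxels in the union of the true areas), its Dice
    overlap with the true union computed, and the centre-of-mass offsets
    from each true area and from the union reported.
    """
    area_pair = tuple(int(a) for a in area_pair)
    if spec is None:
        spec = GroundTruthSpec(kind="area-set", target=area_pair)
    else:
        spec = replace(spec, kind="area-set", target=area_pair)
    labels = label_area_model(dataset, parcellation, spec)
    if labels.single_class:
        raise ValueError("area pair produces a single-class label vector")
    eng = _SweepEngine(dataset, min_hits)
    pmap = eng.pmap_for(labels.labels, mode=mode)
    thr = bonferroni_threshold(alpha, len(eng.tested))
    sig = significance(pmap, thr)

    truth_vox = np.argwhere(parcellation.area_mask(area_pair))
    if k is None:
        k = len(truth_vox)
    retained = top_k_voxels(pmap, k)
    dice = dice_coefficient(retained, truth_vox)

    grid = dataset.grid
    retained_com = grid.world(retained).mean(axis=0)
    rows = []
    for name, target_vox in (
        [(f"area-{a}", parcellation.area_voxels(a)) for a in area_pair]
        + [("union", truth_vox)]
    ):
        true_mm = grid.world(target_vox).mean(axis=0)
        vec, mag = displacement(true_mm, retained_com)
        row = dict(target=name, dx_mm=vec[0], dy_mm=vec[1], dz_mm=vec[2],
                   magnitude_mm=mag)
        if not sig.empty:
            vec_c, mag_c = displacement(true_mm, sig.com_mm)
            row.update(com_dx_mm=vec_c[0], com_dy_mm=vec_c[1],
                       com_dz_mm=vec_c[2], com_magnitude_mm=mag_c)
        rows.append(row)
    return MultiAreaResult(
        spec=spec, significance=sig, retained=retained, k=int(k),
        dice_retained=float(dice), retained_com_mm=retained_com,
        displacements=pd.DataFrame(rows),
    )
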