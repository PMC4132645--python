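# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and what the test suite does and does not establish
about real data.

## Data model

All analysis operates on stacks of co-registered binary lesion masks on a
shared regular grid (`VoxelGrid`: dims, mm spacing, mm origin; voxel
(i,j,k) maps to world coordinate origin + (i,j,k)·spacing, 0-based,
row-major canonical order). Reading a NIfTI volume binarizes it (nonzero →
damaged; NaN → undamaged), refuses any grid mismatch with a reference
(resampling is never attempted), and excludes lesions below a minimum
volume of 216 mm³ (27 voxels at 2 mm isotropic) — an exclusion signal
distinct from a hard error. Unilateral analysis collapses each lesion onto
the canonical hemisphere (first-axis index below the declared midline):
the hemisphere with the larger lesion share is kept, mirrored about the
inter-voxel midplane i ↔ d−1−i when needed (no interpolation); an exact
volume tie keeps the canonical side and warns. Synthetic grids carry no
anatomical template, so the midline index is explicit (generators use
dims[0]//2).

## Synthetic cohorts

The real multivariate distribution of stroke damage is empirical and
unknown; the generators reproduce the one property the mislocalization
argument needs — stereotypy with a low-variance proximal core — as a
*model*, not as a claim about vascular anatomy.

**Territory tree.** One hemisphere is partitioned into n contiguous
territories by seeded Voronoi growth; territories are organised as a
rooted tree (trunk plus branches, each new node attached to a random
existing node, its Voronoi seed drawn near its parent's seed, so branches
are spatially coherent). Territories are disjoint, non-empty, and cover
the hemisphere exactly.

**Stereotyped lesions.** A lesion damages the union of territories on the
path from the trunk to a randomly chosen endpoint node, then each damaged
voxel is spared independently with an erosion (noise) probability,
optionally graded by tree depth. Consequences, by construction: proximal
territories are damaged more often and with lower voxel-level variability
than distal ones; territories on the same branch are positively
correlated, across branches much less. Defaults: uniform erosion 0.1,
endpoint uniform over all nodes, resampling until the volume floor is met
(100 draws budget).

**Independent null.** I.i.d. Bernoulli damage per hemisphere voxel
(default p = 0.05, giving ≈ 100-voxel ≈ 800 mm³ lesions on the 16³ grid —
small-to-medium strokes), with the same volume floor. This realises the
counterfactual of damage with no covariance structure: any systematic
error vanishes on it.

**Two-region toy.** The analytically transparent fixture: an extended
12-voxel strip A (the true critical region), a compact 27-voxel block B
damaged in *every* affected-type lesion (zero spatial variability — pure
collateral), and a separate region C hosting the unaffected-type lesions.
Affected-type lesions cover a contiguous sub-segment of A plus all of B;
sub-segments are drawn from a balanced four-member family (two long
segments each sparing one end, two half-segments) so that every A voxel is
covered often enough to be tested and strictly less often than B. With 40
affected / 40 unaffected subjects every A-voxel model makes all of B
significant and displaces the centre of mass toward B; under the
area-criterion ground truth ("deficit iff any part of A damaged") B's
damage coincides exactly with the label, so B attains the global minimum
p, strictly below every A voxel — the canonical displacement mechanism.
Note that under a *single-voxel* ground truth the defining voxel itself
always attains the global minimum p for its own label (its table is
(k, 0, 0, N−k)); only the area-criterion version makes B the overall
winner. Both facts are asserted in the tests.

**Two-critical-area cohort.** The fixture for the univariate/multivariate
contrast: a fixed-topology tree in which an intermediate territory M feeds
three distal leaves — the two critical areas A1 and A2 plus a non-critical
sibling D — and three further leaves branch from the trunk elsewhere.
Lesions run trunk→leaf with depth-graded erosion (0.05 proximal, 0.2 at
the leaves), so M is damaged with low variability in every lesion that
reaches A1, A2 *or* D. Under the ground truth "damage to ≥ 20 % of A1 or
A2", M is damaged in all affected subjects while each critical voxel is
damaged in only the half of them whose lesion took its branch: M's
association outranks both true areas and the mass-univariate retained set
lands almost entirely in M (Dice with the true union ≈ 0.02), while the
SVM weight map suppresses M (damage to M without A1/A2 occurs in the
unaffected D-lesions) and recovers the true areas (Dice ≈ 0.82).

All generators are pure functions of (parameters, seed): per-stage
Generators are derived from the seed via a CRC-namespaced SeedSequence; no
global RNG state is touched anywhere.

## Ground-truth models

A hypothetical lesion-deficit model is either **single-voxel** (affected
iff that voxel is lesioned; deterministic) or **area-set**: affected-able
iff any target area has at least `damage_fraction` (default 0.20,
inclusive) of its voxels lesioned — union semantics across areas — then
labelled affected with `deficit_probability` (default 0.90). The fraction
comparison uses exact rational arithmetic on counts, so 2/10 ≥ 0.20 never
falls to floating-point error. The stochastic coin is flipped once per
subject per model from the model seed, and is one-sided: a subject failing
the damage criterion is never labelled affected. Evaluation labels can be
regenerated noiselessly (probability forced to 1). Only voxels hit at
least `min_hits` = 4 times are ever tested or used as features.

## Mass-univariate inference

Per tested voxel, the 2×2 damage × label table is tested two-sided.
The default is the exact Fisher p under the point-probability convention:
the sum of hypergeometric point probabilities not exceeding the observed
table's, with a relative tie guard of 1 + 1e-7 (distinct hypergeometric
point masses at the cohort sizes used differ by far more, so the guard can
only rescue exact ties lost to floating point). Degenerate margins give
p = 1. A 1-df chi-square approximation without continuity correction is
available as an `asymptotic` mode for sensitivity analyses; the
displacement phenomenon is mode-independent. Because sweeps need ~V²
tables, p-values are computed by a vectorised routine that caches the full
p-vector per (margin, class size, N); the scalar entry point shares the
same code path and is cross-checked in the tests against both an
exact-rational enumeration oracle and an independent library
implementation.

Significance uses the strict inequality p < α/V with α = 0.01 and V = the
number of *tested* voxels (models are only fitted there). The
"significant cluster" is the full suprathreshold set — no connectivity
step is applied by default, since thresholding followed by centre of mass
requires none; a largest-6-connected-component mode exists for sensitivity
analysis. The centre of mass is the unweighted mean of the significant
voxels' world coordinates; the peak is the voxel of minimal p, ties
resolved as the centre of mass of all tying voxels (deterministic and
orientation-unbiased). An empty significant set is a valid, flagged
outcome. Displacements are reported in mm; the summary SD over model
magnitudes is population-style (denominator n) and failures (empty sets,
single-class labels) are counted but excluded from mean/SD.

The display-matched thresholding for two-area models retains exactly the k
most-significant voxels (ties by canonical voxel order); k defaults to the
size of the union of the true areas. (An alternative convention — k equal
to 20 % of that volume — is equally expressible by passing k explicitly.)

## Multivariate inference

The design matrix is subjects × tested voxels, binary, in canonical
column order, with the label vector as target. The classifier is libsvm's
C-SVC with a linear kernel (tolerance 1e-6, iteration cap 1e7;
non-convergence raises, never returns silently). Inputs being binary, no
feature scaling is applied; classes are unweighted.

C is selected over integer powers of two, 2⁻²⁰ … 2²⁰ (41 candidates), by
mean held-out accuracy over 17 random splits holding out round(N·25/581)
subjects (≥ 1); the splits are drawn once and reused across all candidates
(paired comparison), and each training split must contain both classes
(resampled under a bounded retry budget). During the search the Gram
matrix is precomputed once and fits use the precomputed kernel. Ties in
mean accuracy break toward the **larger** C: on a linearly separable
cohort every sufficiently large C yields the identical maximum-margin
classifier, which is the canonical solution, whereas the smallest
accuracy-tied C sits at the ridge limit, where the weights collapse onto
the class-mean difference and inherit exactly the collateral covariance
the multivariate approach is meant to see past.

The final model is refit on the full cohort at the chosen C; the primal
weight vector is reported with the sign convention that positive weights
push toward 'affected'. Weight thresholding keeps the k largest *signed*
weights by default (damage → deficit being the direction of interest;
absolute-value ranking is available), ties by canonical order. Noiseless
evaluation retrains per split on the (possibly noisy) training labels and
scores the held-out subjects against the deterministic criterion labels;
sensitivity/specificity are summarised by mean and sample SD (ddof 1)
across splits, with undefined splits (empty class in the held-out set)
excluded via NaN-aware means.

## Problem sizes and determinism

The shipped analyses run at desk scale, chosen so every property is
exercised comfortably on one CPU: 16³ grids (2 mm) with 8 territories and
cohorts of 120–200 for the error-field analyses; the default 32³ grid with
cohorts of 300 for the SVM contrast; the 12-bin damage-fraction sweep
(5 %–60 %) on the 8-area fixture. All properties asserted are scale-free;
real-data dimensions (e.g. 91×109×91 MNI grids) are supported by the same
code paths. Every pipeline stage is bit-identical across runs with the
same configuration and seed, which the test suite asserts end to end, and
the CLI records config, seeds and artifact SHA-256s in a run manifest.

## What passing tests do and do not show

The generators reproduce the statistical *skeleton* of real stroke
cohorts — unilateral binary masks, a volume floor, tree-structured
covariance with a low-variance core, plus matched independence nulls —
but none of the anatomy: no grey/white classes, no perfusion physics, no
realistic lesion-frequency gradients, and no behavioural measurement
error. Passing tests therefore demonstrate that the inferential machinery
behaves as specified and that stereotypy alone is sufficient to produce
systematic, direction-consistent mislocalization that multivariate
inference can undo in the two-area setting; they do not certify the
magnitude of the bias in any real cohort, nor that a linear SVM recovers
truth for more than two critical areas or under graded deficits.

## Known limitations

- Mirroring assumes an axis-aligned grid and an even split about the
  declared midline; oblique affines are rejected rather than resampled.
- The error field inherits the failure convention: models with empty
  significant sets contribute no vector (they are counted and flagged).
- The SVM weight map has no significance calibration; only matched-size
  set comparisons are offered.
- Lesion-volume covariate corrections are deliberately out of scope: under
  stereotyped damage such reductive corrections add distortion of their
  own rather than removing the bias.
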