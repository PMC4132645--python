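# lesionmap

Lesion-deficit mapping with mislocalization diagnostics: mass-univariate
VLSM, error vector fields, and high-dimensional multivariate (linear SVM)
inference on binary stroke-lesion cohorts.

## The problem

Voxel-based lesion-symptom mapping (VLSM) infers which brain regions are
necessary for a function by testing, independently at every voxel, whether
damage there is associated with a behavioural deficit across a patient
cohort. This mass-univariate approach silently assumes that damage at one
voxel is independent of damage at every other. Real lesions violate that
assumption badly: stroke damage follows the branching architecture of the
vascular tree, so functionally irrelevant tissue is *stereotypically*
co-damaged with the critical tissue. A collaterally damaged region whose
damage varies less across patients than damage to the truly critical region
can reach a *smaller* p-value than the critical region itself — and the
inferred locus is systematically displaced. Because the bias is anatomical,
not statistical, replication with more patients only entrenches it.

`lesionmap` makes this failure mode measurable and testable:

1. **Simulate** lesion cohorts with controllable spatial stereotypy
   (territory-tree generators) alongside independent-damage null cohorts.
2. **Posit** hypothetical ground truths — a critical voxel, or damage to
   ≥ 20 % of one or more atlas areas, optionally expressed stochastically
   (deficit probability 0.9) — and label each subject affected/unaffected.
3. **Infer** with the conventional pipeline: per-voxel Fisher's exact test
   over all voxels hit ≥ 4 times, Bonferroni-corrected threshold
   (p < 0.01), centre of mass / peak of the significant cluster.
4. **Quantify** the mislocalization as an *error vector field*: at every
   tested voxel, the mm displacement from the true locus to the inferred
   one.
5. **Compare** against high-dimensional multivariate inference — a linear
   support-vector classifier over the whole damage pattern, with C chosen
   by repeated random splits (2⁻²⁰ … 2²⁰, 17 splits) and its per-voxel
   weights thresholded at a matched set size.

## The statistics at the core

At voxel *v* with damage indicator *x<sub>v</sub>* and label *y*, the 2×2
table (a, b; c, d) of damage × deficit is tested with the two-sided Fisher
exact p: the sum of hypergeometric point probabilities, over all tables
sharing the observed margins, that do not exceed the observed table's
point probability. Significance is declared at p < α/V (Bonferroni over
the V tested voxels, α = 0.01). The error vector at a true locus *t* is
**e**(t) = **x̂** − **t** where **x̂** is the unweighted centre of mass (or
the peak) of the significant set, with ‖**e**‖ summarised by its mean and
SD across models. The multivariate model is a linear C-SVC over the V
binary voxel features; the primal weight per voxel indexes its
contribution toward the 'affected' side, and Dice overlap of the top-k
weighted voxels with the true critical set scores localization.

## Worked example

```python
import lesionmap as lm
from lesionmap.synthetic import CohortSpec, generate_cohort

grid = lm.VoxelGrid(dims=(16, 16, 16))          # 2 mm isotropic desk-scale grid
cohort, _ = generate_cohort(CohortSpec(n_subjects=200, generator="stereotyped",
                                       seed=11, params={"n_branches": 8}), grid)
field, summary = lm.single_voxel_sweep(cohort)
print(f"{summary.n_models} single-voxel models, mean error "
      f"{summary.mean_mm:.1f} mm (SD {summary.sd_mm:.1f} mm)")

null, _ = generate_cohort(CohortSpec(n_subjects=200, generator="independent",
                                     seed=11, params={"per_voxel_p": 0.05}), grid)
_, null_summary = lm.single_voxel_sweep(null)
print(f"independent-damage null: mean error {null_summary.mean_mm:.3f} mm")
```

prints

```
2048 single-voxel models, mean error 11.5 mm (SD 4.7 mm)
independent-damage null: mean error 0.009 mm
```

On the stereotyped cohort every single-voxel ground truth is recovered
*inside* the significant cluster, yet the cluster's centre of mass sits on
average 11.5 mm away from it — several territories' worth of displacement —
while on the matched independent-damage cohort the error is essentially
zero: the bias is created entirely by the correlation structure of the
lesions, not by the test.

The statsmodels-style model interface exposes the same machinery for a
single hypothesis:

```python
dataset, parcellation = lm.make_two_region_toy(40, 40, seed=1)
labels = lm.label_single_voxel(dataset, (2, 6, 6))
print(lm.MassUnivariateVLSM(dataset, labels).fit().summary())
```

```
Mass-univariate lesion-deficit mapping
==============================================
subjects:            80
affected:            20
tested voxels:       86 (min hits 4)
test:                Fisher exact (exact), two-sided
threshold:           p < 1.163e-04 (alpha 0.01 Bonferroni / 86)
significant voxels:  33
min p:               2.829e-19
centre of mass (mm): (29.5, 12.0, 12.0)
peak (mm):           (4.0, 12.0, 12.0)
```

The true voxel sits at x = 4 mm, but the centre of mass (29.5 mm) is
dragged to the doorstep of the compact collateral region B (centred at
34 mm): the toy reproduces the displacement mechanism analytically.

A command-line interface mirrors the library
(`lesionmap simulate / map-univariate / map-multivariate / sweep /
compare`); every run writes a `run_manifest.json` with the effective
config, seeds and artifact hashes for bit-identical re-runs.

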