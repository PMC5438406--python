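# Methods

`neomorph` implements a two-stage analysis for preterm neonatal brain MRI:
(1) quantitative morphometry of 8-class tissue segmentations, and
(2) prediction of low neurodevelopmental outcome from those descriptors
with a linear SVM evaluated by repeated random subsampling. Because no
clinical images or outcome scores ship with the package, a synthetic
module generates geometric phantoms and simulated cohorts with
closed-form ground truth; this note states exactly what those synthetic
inputs do and do not establish.

## Descriptors

From one label volume (codes 1–8: uWM, mWM, cGM, vCSF, eCSF, CB, BGT,
BS; 0 = background) the pipeline computes 14 descriptors per subject:

* **Eight relative tissue volumes** — per-class voxel count × voxel
  volume, divided by total intracranial volume (the sum over all eight
  classes). Computed on the native acquisition grid, where counting is
  unbiased regardless of slice thickness.
* **BV** — total intracranial volume, mm³. (The table abbreviation
  "brain volume" is treated as an alias of intracranial volume; the
  sum-of-eight-classes definition is the one implemented.)
* **ISA** — inner cortical surface area, mm²: area of the closed
  boundary of the cerebral interior (largest connected component of
  uWM ∪ mWM ∪ BGT ∪ vCSF, holes filled). Ventricles and deep grey are
  part of the interior so they cannot puncture the surface; cerebellum
  and brain stem are excluded.
* **GI** — gyrification index: ISA divided by the area of the convex
  hull of the inner surface (3-D hull ratio; 1 for a convex brain).
* **MC** — global mean curvature, mm⁻¹: area-weighted mean of |H| over
  inner-surface vertices, H from the cotangent-Laplacian mean-curvature
  normal with barycentric vertex areas.
* **MT** — median cortical thickness, mm: median over inner-surface
  vertices of the distance to the outer cortical surface (boundary of
  interior ∪ cGM). One-sided by default; the nearest-point search is a
  k-d-tree vertex query refined by exact point-to-triangle distances
  over the faces incident to the nearest vertex.
* **GA** — gestational age at birth, weeks, taken from the subject
  record.

### Surface extraction and numerical choices

Surfaces are computed in physical mm coordinates. Label volumes are
nearest-neighbour resampled to an isotropic grid (default 0.5 mm) first,
since 2-mm slices otherwise produce severe staircase bias; the
*effective* rational spacing of the resampled grid is used so no scale
error is introduced. The binary mask is then smoothed with a Gaussian of
fixed **physical** scale (σ = 0.5 mm) and the surface is the 0.5 level
set (marching cubes). Two reasons: marching cubes on a raw binary mask
overestimates smooth-boundary areas by several percent and does not
converge under refinement, and a voxel-denominated smoothing scale would
make the operator resolution-dependent. With the physical scale-space
definition, every surface descriptor changes by <1% when the sphere
phantom's grid is refined from 0.5 mm to 0.25 mm (this is asserted in
the test suite).

Meshes are cleaned (duplicate vertices merged, degenerate faces removed,
largest body kept) and must be watertight with positive signed volume.
For curvature only, the mesh is additionally Laplacian-smoothed
(10 iterations, λ = 0.5, volume-preserving), since discrete curvature is
noise-dominated on voxelized surfaces; area and GI use the unsmoothed
cleaned mesh.

On the 0.5 mm sphere phantom the recovered values are within 0.2% (ISA,
MT), 1.4% (MC) and 0.0004 (GI) of the closed forms. On the emulated
30-week acquisition geometry (0.34 × 0.34 × 2.0 mm) residual staircase
bias remains after resampling: ISA is ~8% high and MC is overestimated.
This is a property of 2-mm slices, not of the implementation, and is the
reason measurements from different acquisition geometries should not be
mixed within one arm without checking.

## Cohort assembly and scaling

Three arms: descriptors at 30 weeks PMA, at 40 weeks PMA, and the serial
change (40-week minus 30-week per subject; GA is passed through
unchanged, since differencing a birth constant would zero it). Subjects
missing a required scan or the relevant Bayley score are dropped, never
imputed. Low outcome is a composite score strictly below 85; a score of
exactly 85 is favourable.

Features are min-max scaled to [0, 1] with parameters estimated on the
**training split of every repeat** (the only leakage-free reading of
"estimated on the training set"). Out-of-range test values are not
clipped — clipping would discard rank information for a linear
classifier. Constant training columns map to 0 (any constant is
equivalent for a linear SVM with a bias).

## Classifier and evaluation

The classifier is a linear-kernel hinge-loss SVM, C = 1 (configurable;
unspecified in the study, so the era's library default is used), no
class weighting. Probabilities come from Platt's sigmoid fitted on
held-out decision values from 3 stratified internal folds of the
training split, after which the SVM is refit on the whole split (the
pooled-decision-value variant of cross-validated Platt scaling; when a
class has fewer than 3 training members the sigmoid falls back to
in-sample decision values).

Evaluation draws 500 (default) random splits, each holding out
ceil(0.05 n) subjects, unstratified, independently per repeat; repeat r
uses the seed stream (seed, r) so results are independent of execution
order. A training split that ends up single-class is redrawn once from a
derived stream, then skipped with a logged count. All test predictions
are pooled into a single ROC; the pooled AUC equals the tie-aware
Mann–Whitney statistic (asserted exactly against pair enumeration).
Pooling is used instead of averaging per-repeat AUCs because 5% test
sets of cohorts of 66–153 subjects hold 4–8 subjects and are frequently
single-class; per-repeat AUCs are additionally reported where defined.

### SVM solver

The exhaustive subset search needs millions of small SVM fits, so the
package ships its own solver: dual coordinate descent with shrinking
(the liblinear algorithm), stopping when the projected-gradient spread
falls below 0.01 (liblinear's own dual default is 0.1), with the bias
handled as an augmented regularized feature. Internally the solver runs
on train-mean-centred features and maps the intercept back — centring
decorrelates the bias from all-positive min-max-scaled columns and
speeds convergence by roughly an order of magnitude. The test suite
cross-checks decision orderings, AUCs and calibrated probabilities
against scikit-learn's `SVC` and `CalibratedClassifierCV` on informative
data, and verifies the duplication ≡ doubled-C identity against a direct
refit. On weak-signal data the exact optimum is the majority solution
(w = 0); the solver finds it where libsvm returns tolerance-level noise
weights — both yield chance-level ranking there.

### A known bias of the pooled protocol under the null

With zero signal the fitted SVM collapses to the majority solution, so
within a repeat all calibrated probabilities are equal and the only
pooled ranking signal is the Platt intercept, which tracks each repeat's
training base rate. Training and test composition are hypergeometrically
anti-correlated, so pooled null AUC sits systematically *below* 0.5:
about 0.42 here (n = 500, prevalence 0.25, 100 repeats), and about 0.38
for the scikit-learn reference stack under the identical protocol. This
pessimism is a property of pooling per-repeat-calibrated probabilities,
not of the solver; it shrinks once genuine signal dominates the
between-repeat intercept jitter (the δ = 1.19 recovery below is within
0.01–0.03 of theory). Interpret pooled AUCs near or below 0.5 as "no
usable signal", not as anti-prediction.

## Subset search

All 2¹⁴ − 1 = 16383 non-empty descriptor subsets are evaluated on one
**shared** split list per (table, design) — identical draws for every
subset — so the ranking reflects subset quality, not split noise.
Subsets are ranked by pooled AUC, ties broken by the mask's binary value
for determinism. The report contains the top-k (default 10) subsets with
per-descriptor inclusion flags, per-descriptor presence counts over the
top k, and the seven predefined subsets (all image descriptors, volumes
+ BV, morphology — each with and without GA — plus GA alone), which are
members of the enumeration and therefore can never beat the full-search
optimum on the same splits. A reduced-repeat design (e.g. 50) makes the
full search a minutes-scale run; the 500-repeat default is for final
analyses.

## Synthetic data

**Phantoms.** Concentric spheres carry all eight classes with
closed-form volumes (BGT core r = 6 mm; vCSF shell to 8; uWM shell to
20 with an embedded mWM sphere r = 3; cGM ribbon 20–23; eCSF to 26;
cerebellum r = 6 and brain stem r = 2.5 below, where the brain stem
wins its small overlap lens by voxelization precedence). The sphere
truth is ISA = 4π·20², GI = 1, MC = 1/20, MT = 3 mm. A radial fold
a·sin(kθ)·sin(kφ) applied to both cortical boundaries makes the cortex
non-convex at constant radial ribbon width; an independent parametric
triangulation of r(θ, φ) serves as the brute-force oracle for folded
area and GI. Voxelization assigns near-interface voxels by
partial-volume majority (3×3×3 stratified sub-samples), and the lattice
is deliberately registered off the phantom's symmetry axis by fixed
irrational voxel fractions — symmetric registration produces correlated
ring-shaped discretization errors that do not self-average (worst
per-class volume error at 0.5 mm: ~1%, versus ~5% for centre-point
sampling of the smallest structure). The default field of view is 90 mm
(180³ voxels at 0.5 mm), the smallest cube containing all structures.
An anisotropic preset (0.34 × 0.34 × 2.0 mm) exercises the resampling
path. The phantoms validate geometry; they do not emulate cortical
folding patterns, lesions, segmentation errors or MR intensities.

**Cohorts.** Class labels are drawn with an exact positive count (to
mirror printed prevalences, e.g. 37/153 = 24%, 9/66 = 14%); descriptors
come from class-conditional Gaussians with configurable standardized
shifts δ and optional correlation, so the theoretical single-descriptor
AUC is Φ(δ/√(σ₀² + σ₁²)). GA is truncated-normal (location 26.5, SD
1.0, window 24–28 weeks; the truncated mean is ≈26.38). Bayley scores
are generated as 85 ∓ (0.1 + |N(0, 10)|) conditioned on the label, so
thresholding at 85 reproduces the drawn labels with zero mismatches.
These cohorts establish that the harness recovers known effect sizes
and ranks informative descriptors; they say nothing about how well real
MRI descriptors predict outcome, and they have no descriptor
correlations unless requested.

## Problem sizes used in the checks

The packaged checks run the sphere phantom at 0.5 mm (180³ voxels, with
a 0.25 mm refinement for convergence), folded phantoms at amplitudes 1
and 2 mm, AUC recovery at n = 2000 with 100 repeats, the null at
n = 500, and the full 16383-subset search on an n = 400 cohort with a
50-repeat design — the reduced-repeat mode of the search, chosen so the
whole validation is a desk-scale run while every subset of the full
enumeration is still evaluated.

## Limitations

* Segmentation itself is out of scope; label volumes are input.
* The GI uses the 3-D convex-hull definition; slice-wise protocols from
  the older literature will give different absolute values.
* Thickness is a one-sided nearest-point median; symmetric variants can
  be assembled from the exposed operations.
* Pooled AUC under the null is pessimistically biased (see above).
* At 2-mm slice thickness, surface measures retain residual staircase
  bias after resampling; volumes do not.
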