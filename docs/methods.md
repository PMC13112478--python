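# Methods

This note documents the models and procedures implemented in `cardiac4d`, the
parameter choices that matter, and what the synthetic experiments do and do
not demonstrate.

## Synthetic beating-heart phantom

The phantom emulates the geometry of an isotropic whole-heart cine
acquisition: a 96³ grid at 1.4 mm isotropic spacing (134 mm field of view),
20 cardiac frames of 50 ms. The anatomy is deliberately minimal but
functionally faithful:

* **LV blood pool** — a prolate ellipsoid (long axis = 1.6 × short axis,
  long axis along z so short-axis planes are xy slices), truncated by a basal
  plane at 0.7 of the long semi-axis. The truncated-ellipsoid volume is closed
  form, `V = π·a·b·c·(2/3 + f − f³/3)`, so the blood-pool volume at every
  phase is known exactly before voxelisation.
* **Contraction** — the endocardial semi-axes scale uniformly so that the
  blood-pool volume follows `V(p) = EDV·(1 − s(p)·EF/100)`, with a
  raised-cosine phase profile `s(p)` rising from end-diastole (phase 0) to
  end-systole (phase `round(0.4·n_phases)`) and relaxing back. This gives
  smooth, periodic motion with a single volume minimum.
* **Myocardium** — a shell between the endocardium and an epicardial
  ellipsoid. The epicardial scale is re-solved at every phase so myocardial
  volume is conserved over the cycle. The closed-form solve (Brent on the
  truncated-ellipsoid volume) initialises the scale; the final threshold is
  then chosen as an order statistic of the epicardial quadratic form so that
  the *voxelised* shell count matches end-diastole exactly. Conservation in
  the discrete domain is what the ε_LVM consistency metric measures, so the
  generator enforces it there rather than only in the continuum limit.
* **RV blood pool** — a crescent: a larger lateral ellipsoid minus the LV
  epicardium, restricted to the septal side and below the basal plane,
  contracting in phase with the LV. Its truth volume is taken from voxel
  counts (the crescent has no convenient closed form).
* **Intensities** — class-wise plateaus (bSSFP-like: blood 1.0, myocardium
  0.5, background 0.15; GRE-like: 1.0/0.3/0.22), softened by a 0.7-voxel
  Gaussian to avoid unphysically sharp edges, plus additive Gaussian noise
  with σ = 0.05 × myocardium intensity by default. Noise is additive Gaussian
  rather than Rician: the phantom tests pipelines, not MR physics.

Default volumes (EDV 150 mL, EF 60%, wall 10 mm giving ≈160 mL myocardium,
RV EDV ≈130 mL) sit in the normal adult range. Everything is seeded and
bit-reproducible.

Key-slice annotations are simulated by sampling the most basal and most
apical foreground slices plus every k-th slice between them. Inter-observer
variability is emulated by randomly dilating or eroding each structure by up
to a configurable radius (default experiments use 1 voxel, which produces
slice-set Dice ≈ 0.9 against the exact contours); no quantitative observer
model was available to calibrate this, so the jitter magnitude is an
uncalibrated free parameter.

### What the phantom does not model

No papillary muscles or trabeculae, no valve anatomy (the basal cut mimics
basal-slice ambiguity only), no respiratory motion, no coil shading, banding
or inflow artefacts. Consequences: segmentation and propagation scores on
phantoms are upper bounds; passing tests demonstrate the *pipeline logic*
(geometry handling, conservation, fold/metric/statistics correctness), not
clinical-grade accuracy on patient data.

## Diffeomorphic registration and label propagation

Pairwise registration is a multiresolution log-domain demons: a stationary
velocity field is updated by symmetric intensity forces
(`u = 2·diff·∇ / (|∇|² + diff²)`, Gaussian-smoothed at 2.0 mm), accumulated
additively, diffusion-regularised at 1.0 mm per iteration, and exponentiated
by scaling-and-squaring — which makes the resulting displacement the flow of
a smooth velocity field and hence guarantees a positive Jacobian determinant.
Three pyramid levels with (60, 30, 10) iterations; images are jointly min-max
normalised; a local-normalisation variant (`metric="local_cc"`) is available
for multi-contrast pairs. The step scale of 2 and the 1.0 mm field smoothing
were chosen on chained-registration experiments: demons equilibrium
systematically under-recovers deformation amplitude, and with the default
values a four-step chained warp of the phantom's contraction keeps the
myocardial volume drift below 1% while weaker settings plateaued near 3.5%
regardless of iteration count. Divergence (three consecutive SSD increases at
a level) returns the best field so far with a warning. The module is
entirely deterministic.

**3D propagation** fills the slices between fully-labelled key slices: for
each gap, adjacent-slice 2D registrations are chained from both flanking
keys, both key label sets are carried to each intermediate slice as one-hot
channels, and the channels are fused with inverse-distance weights before the
argmax. Bidirectional fusion was chosen over one-way chaining because
interpolation between two anchors bounds the error growth mid-gap. Slices
outside the key span stay background.

**4D propagation** carries the ED and ES label volumes to all other phases by
composing registrations between temporally adjacent phases outward from each
source; each target phase takes the cyclically nearer source (ties to ED).
Adjacent-phase chaining keeps every individual registration small-deformation;
cyclic distance respects the periodicity of the cardiac cycle.

Labels are always warped as one-hot probability channels with linear
interpolation and a priority argmax (LVB > LVM > RVB > background on exact
ties) — nearest-neighbour warping aliases the thin myocardial shell.

## Segmentation stage

The trainable stage keeps the standard training contract of volumetric
cardiac segmentation — four output classes, soft Dice loss averaged over the
three foreground classes (background excluded so the thin myocardium keeps
weight), stratified 5-fold cross-validation, seeded end-to-end, per-phase 3D
inference, largest-connected-component post-processing — around a compact
backbone: each voxel is described by 11 features (normalised intensity,
Gaussian-smoothed intensity at σ = 1, 2, 4, 8 voxels, gradient magnitude at
σ = 1.5, three normalised coordinates and the radius) and classified by a
fully-connected network (64 and 48 hidden units, ~4k parameters) trained with
Adam (lr 3·10⁻³) on 30 000 class-balanced voxels per volume per epoch. The
smoothed-intensity pyramid gives centimetre-scale context cheaply, which is
what makes the stage trainable in minutes on one CPU. The backbone sits
behind a serialisable `ModelState` seam, so a heavier volumetric CNN can be
swapped in without touching folds, loss, inference or evaluation.

Fold assignment shuffles subjects within each cohort-by-group stratum
(seeded) and deals them round-robin, so a 35-subject cohort of 15 + 10 + 5 + 5
yields five folds of seven with composition (3, 2, 1, 1); each fold serves
three times for training, once for validation, once for testing.

Post-processing keeps the largest 26-connected component per foreground class
per phase (26-connectivity chosen as the permissive 3D default; size ties keep
the component whose seed voxel comes first in scan order). It is idempotent
and never grows a class.

## Validation metrics and statistics

Volumes are voxel counts × voxel volume. Geometric metrics operate on
masks: Dice 2|A∩B|/(|A|+|B|) (both-empty defined as 1 with a warning, so
degenerate phases don't crash batch evaluation); surfaces are face-adjacent
boundary voxel centres, distances Euclidean in world mm; the Hausdorff
distance is the max of the two directed maxima (full HD, not a percentile,
so outliers stay visible) and ASSD the mean of all minimum distances pooled
over both directions. Sub-voxel surface models would change distances by at
most half a voxel; the voxel-centre convention was chosen because it is
exactly checkable against a brute-force all-pairs oracle. The relative volume
difference is reported as an absolute percentage by default, with the signed
value available, since sign conventions differ across reports. When ED and ES
are both evaluated, metrics are pooled (summed Dice components, max HD,
pooled ASSD distances, summed volumes for RVD) so every voxel and boundary
point contributes equally.

ED/ES are detected as the argmax/argmin of LV blood-pool volume over phases
(ties → earliest, warned). ε_LVM uses the magnitude formulation
|EDV_LVM − ESV_LVM| / mean. Its QC tolerance defaults to 10% — true systolic
myocardial volume change is debated but small, so the flag marks
non-physiological deviations rather than enforcing strict conservation. The
stroke-volume check (|LVSV − RVSV| ≤ 10 mL) is restricted to healthy
subjects because regurgitation decouples the two in patients.

Agreement statistics: Bland–Altman uses the sample (n−1) SD — cohorts here
are small — with LOA = bias ± 1.96 SD. ICC(2,1) is the two-way random-effects
absolute-agreement single-measure form computed from explicit mean squares.
SEM is reported in two conventions, pooled SD·√(1−ICC) as primary and √MS_E
alongside, since the literature uses both. Paired comparisons apply a
Shapiro–Wilk gate at α = 0.05 and fall back to Wilcoxon signed-rank (flagged)
when normality is rejected; zero-variance differences return p = 1 with a
degenerate flag rather than an error. The repeated-measures ANOVA F uses the
within-subject error term, with Tukey HSD pairwise tests on the same error
mean square via the studentized range distribution at familywise α = 0.05.

## Problem sizes in the reference experiments

The validation suite and `scripts/acceptance.py` run everything on the
default 96³ / 20-phase phantom; the end-to-end experiment trains on 12
two-phase phantoms with varied anatomy (EDV 120–170 mL, EF 35–70%, wall
8–11 mm, both contrast modes) for 40 epochs and evaluates on 4 held-out
phantoms; the statistics simulation uses 200 subjects × 2 raters × 50
replicates. These sizes make a full from-scratch reproduction run in about
ten minutes on a single CPU while exercising every pipeline stage at the
default phantom resolution.

## Known limitations

* The demons implementation prioritises determinism and the positive-Jacobian
  contract over speed; large cohorts would want a compiled registration
  backend behind the same `DeformationField` interface.
* The voxel-feature backbone has no learned spatial kernels; on real data
  with papillary muscles, trabeculation and coil shading it would need the
  CNN backend the `ModelState` seam is designed for.
* 4D propagation quality is only validated against phantom truth; on real
  data intermediate phases have no ground truth, which is precisely why the
  method exists.
* Rigid reorientation assumes axis directions are supplied (or a transform
  file); automatic long-axis detection from images is out of scope.
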