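# Methods

This note records the modelling assumptions, parameter choices and known
limitations of the package, in the order the pipeline runs.

## Phantom cohort generator

**Geometry.**  The phantom is the simplest solid that exposes every
structure label of a subject-specific L4/L5 FE model: two extruded blocks
("vertebrae", 26 mm each, cancellous core with a two-element lateral
cortical shell), a 10 mm disc (nucleus core plus exactly seven concentric
annulus layers), 1 mm cartilaginous endplates, and two posterior
facet-cartilage pad pairs separated by a 0.7 mm clearance.  The
cross-section maps a structured square grid through a square/ellipse blend
(β = 0.75) — a squircle profile chosen over a pure superellipse or pure
ellipse map because it keeps corner-cell scaled Jacobians above ≈0.4,
so mesh-quality failures downstream come from the sampled deformations,
not the template.  The grid resolution is chosen to approach the requested
surface-point count `p`; the realised count is reported.  Surface points
comprise all exterior surfaces plus the annulus–nucleus and
endplate–nucleus interfaces, mirroring how interior FE nodes carry no
anatomical information.

**Generative modes.**  Subjects are `mean + Σ_j w_ij f_j + noise`, scaled
multiplicatively about their centroid.  The named deformation fields are
(1) axial height change, (2) nucleus width (an affine radial dilation
inside the nucleus with smooth exterior decay — affine so that moderate
negative weights shrink, never invert, the core), (3) facet gap, and
(4) sagittal shear; further dimensions are lateral cosine harmonics with
even axial frequency.  All fields are orthonormalised in the
flattened-surface metric and, importantly, projected off the 7-dimensional
similarity algebra (translations, rotations, isotropic scale).  Without
that projection Procrustes alignment absorbs a large part of the height and
shear fields (observed eigenvalue losses of ~55% and ~75%), scrambling the
mode-to-eigenvalue correspondence; with it, aligned-cohort eigenvalues
equal the latent variances up to noise and the fitted modes match the
generative fields one-to-one.

**Defaults** (the emulated study conditions): `t = 152` subjects,
`p = 14015` target surface points, 4 latent modes with SDs
12 × 0.66^j mm (flattened-surface metric), iid point noise 0.05 mm,
multiplicative size spread 4%.  The noise level was set so that
correspondence jitter is visible to the model (eigenvalue floor ≈0.003
of the leading mode) without flipping thin endplate elements; the size
spread gives the Procrustes scaling step something real to remove.

**Analytic responses.**  The IDP-like and FCP-like ground-truth outcomes
are linear functions of four *linear* geometric features (segment height,
nucleus half-width as fixed-direction radial projections of the interface
ring with per-plane centroids, mean facet gap, sagittal shear).  Linearity
makes the per-mode ground-truth Jacobian exact and regression-recoverable.
Coefficients mirror the sign and dominance structure of the in-repo FE
proxy, measured once on the template: a taller, narrower segment raises
nucleus pressure; a wider nucleus lowers it; a tighter facet gap raises
facet pressure.  Harmonic modes are additionally projected off the feature
gradients, so their response coefficients are exactly zero — they exist to
test that inert shape directions are ranked last.  Intercepts (0.48 MPa
IDP, 0.80 MPa FCP) sit in the physiological range for ~400 N compression.
Coefficients are jittered ±10% per cohort seed and recorded in the ground
truth, which always stores the numerically evaluated Jacobian and the
resulting importance ranking.

## Procrustes alignment

Single-pass alignment of every subject to the first sample (left
untouched), as is common when a template subject anchors the cohort; an
iterative generalised-Procrustes mode (evolving mean) is available but off
by default.  Rotation is the Kabsch solution with the determinant forced to
+1 — anatomy must not mirror.  Scaling matches source centroid size to
target centroid size.  Collinear point sets are rejected (the rotation is
not identifiable).  The per-subject transforms are retained and re-applied
to all volumetric nodes when building the mean template, so the template
surface coincides with the shape-model mean to 1e-8 mm.

## Shape model

Eigenvalues use the `t−1` divisor (sample covariance); this choice
propagates consistently into the mean eigenvalue and hence the Kaiser
threshold.  Mode signs are fixed by making each mode's largest-magnitude
coordinate positive.  Specificity samples mode weights from
`N(0, λ_m)` truncated at ±2 SD (consistent with the cohort-generation
bounds; an unbounded option exists), 500 samples by default, seeded, and
scores each sample by its minimum RMSE to any training shape.
Generalisation is leave-one-out: the model is refit on `t−1` shapes and
the left-out shape reconstructed with the first `M` modes; the curve over
`M` is fold-averaged.  `M` may not exceed `t−2` (the leave-one-out model
has only `t−2` modes).

## Power analysis

`min_sample_size` implements the *exact random-model* test of the squared
sample multiple correlation: under multivariate-normal predictors the
non-null CDF of R² is a negative-binomial mixture of incomplete beta
functions, and the null distribution is `Beta(k/2, (n−1−k)/2)`.  For the
full design (30 predictors, ρ² = 0.15, α = 0.05, power 0.95) this gives a
minimum of 229 subjects (power 0.9501 at 229, 0.9489 at 228), which the
fixed-model noncentral-F formulation (also provided, `model="fixed"`,
noncentrality `f²·n`) does not reproduce (it gives 225).  The analytic
power function is verified against a 100k-replicate Monte-Carlo regression
oracle.  The recommended cohort size is twice the minimum, anticipating
meshing/quality attrition.

## Latin-hypercube sampling

Weights are sampled per mode from `N(0, λ_m)` *truncated* at
±`sd_range`·√λ_m and then stratified: the truncated distribution is cut
into `n` equal-probability strata and one inverse-CDF sample (uniformly
jittered within its stratum) is drawn from each.  Truncate-then-stratify
was chosen over plain normal stratification because unbounded strata would
violate the stated ±2 SD bounds.  The correlation-minimisation criterion is
an Iman–Conover rank rearrangement toward the identity correlation (van der
Waerden scores decorrelated through a Cholesky factor); it permutes within
columns only, so the marginal multisets — and the stratification invariant
— are untouched.  With `n ≤ M` columns cannot be decorrelated and the raw
stratified sample is returned unchanged.  A maximin criterion (best of ten
random shuffles) is provided for completeness.

## Template and TPS morphing

The volumetric template is the per-node arithmetic mean of all subjects'
meshes after applying the surface-derived Procrustes transforms to every
node.  Morphing fits a 3-D thin-plate spline — the true 3-D biharmonic
kernel `U(r) = r` plus an affine part, not the 2-D `r² log r` kernel — from
template surface controls to the sampled surface, then maps all nodes.
At zero regularisation (the default) the spline interpolates the controls
exactly and reproduces any affine map exactly everywhere; both properties
are asserted in tests and pin down the kernel choice.  Control points are
a single random subset (default 1000 of the surface points, uniform without
structure stratification) drawn once per pipeline run and reused for every
subject.  Morphing happens entirely in the aligned (shape-model) frame;
subjects are not back-transformed to native scales, which is immaterial for
shape-driven sensitivity and keeps the load case common to all subjects.
Each morph reports surface RMSE against the target (control-point RMSE is
~1e-9; the downsampling error is the real quantity) and the fraction of
inverted hexahedra.

## Mechanics

**Screening.**  Corner Jacobian determinants and scaled Jacobians (corner
determinant over the corner edge-norm product) are computed per element;
a mesh is rejected when any corner determinant is ≤0 or the minimum scaled
Jacobian falls below 0.05.  Rejection is a recorded outcome, not an error —
quality attrition of the sampled cohort is part of the emulated workflow
(roughly 2–20% at the CI scale depending on seed).

**Solver.**  Standard trilinear hexahedra with full 2×2×2 Gauss
integration, isotropic linear elasticity, sparse direct solve.  Reduced
integration designations (C3D8R/RH) are preserved in the INP export, but
the in-repo solver integrates fully to avoid hourglass-control machinery.
The hyperelastic structures are mapped to linear surrogates from the
Neo-Hookean ground stiffness: `μ = 2 C10`, `E = 2 μ (1+ν)`, giving the
nucleus `E ≈ 0.956 MPa` at ν = 0.49 and the annulus `E ≈ 1.97 MPa` at
ν = 0.45.  ν = 0.49 (not 0.499) is deliberate: at 0.499 fully-integrated
trilinear elements lock volumetrically and the quadrature-point pressure
field develops ~3× checkerboard spikes.  Bonded structures share nodes;
the facet pads are excluded from the stiffness system (in the full model
they interact by contact, not bonding).

**Load case.**  The upper bony endplate — exterior faces with near-axial
outward normals above the mid-plane, found topologically so deformed
subjects work — carries a uniform pressure whose consistent nodal forces
integrate exactly to the total force (400 N default, downward); the lower
endplate is fixed in all DOF.  Reactions balance the load to 1e-8 relative.

**Outcomes.**  IDP is the maximum hydrostatic pressure `−tr(σ)/3` over the
nucleus quadrature points (hydrostatic, not maximum-principal, as the
natural analogue of a fluid-core pressure; quadrature points because they
are the primary FE stress locations).  FCP is an analytic penalty
surrogate: each pad box follows its adjacent vertebra rigidly (mean
displacement of the nearest solved nodes), the post-deformation clearance
between facing pad faces is measured, and the pressure is
`1.5 MPa/mm × max(0, 1.0 mm − clearance)`.  The constants were calibrated
once on the template so the baseline FCP sits near 0.9 MPa; the surrogate
is deterministic and sensitive to facet geometry (gap, orientation) by
construction.

## Uncertainty quantification

Percentile bootstrap of the mean (1000 resamples of the original size,
default 95%), chosen over BCa for its direct correspondence to "dispersion
of outcomes around the mean".  The sample-size sweep draws a fresh
subsample *without* replacement at each size before bootstrapping (at the
full size the data are used directly, making the sweep endpoint exactly
equal to the plain bootstrap).  Kernel-density summaries of the
bootstrap-mean distribution are emitted per size for plotting.

## Sensitivity analysis

Correlations: Pearson and Spearman (average ranks, hence tie-corrected)
with two-sided p-values, flagged at α = 0.05, unadjusted for multiplicity
(a Benjamini–Hochberg adjustment can be applied downstream; none is applied
by default).  Constant columns are reported as undefined, never as zero.

Kernel SHAP runs on an ordinary-least-squares linear surrogate — justified
empirically by the near-equality of Pearson and Spearman coefficients on
this problem — with the cohort-mean weight vector as background.
Coalitions are enumerated in descending Shapley-kernel weight (extreme
cardinalities first, 1024 budget by default); a partially-filled
cardinality is sampled uniformly without replacement, seeded.  The
weighted least squares is solved with the local-accuracy constraint
eliminated exactly, so `Σ_m φ_m(x) = f(x) − f(background)` holds to
machine precision; for a linear surrogate the values equal the closed form
`β_m (x_m − b_m)` regardless of the coalition budget.  Subjects with failed
simulations are dropped listwise before any of this.  Weights enter in SD
units (w/√λ), recorded in the report metadata.

Contribution percentages are subject-averaged absolute Shapley values
normalised to 100% per outcome.  The importance cutoff sorts contributions
descending and takes the modes before the largest consecutive relative drop
within the top 8 ranks; a drop must exceed 20% (otherwise the important set
is declared empty — near-uniform contributions support no cutoff), and ties
break toward the smaller set.

## Pipeline and problem sizes

Stages communicate through a flat on-disk artifact store with per-stage
manifests (config hash, seed, version); per-stage seeds are derived from
the global seed via `SeedSequence` and kept below 2³¹.  Re-running with an
identical configuration is bitwise reproducible; deleting downstream
artifacts never changes upstream re-runs.

Two bundled configurations: `paper-scale` (152 subjects / ~14k points /
500 samples — runnable but slow) and `test-scale` (30 subjects / ~1.3k
points / 60 samples), the package's CI default.  The test scale was chosen
as the smallest phantom resolution whose seven annulus layers, nucleus core
and facet pads all remain resolvable; the complete pipeline runs in about
a minute on one CPU at that scale, and all tests and the acceptance script
use it.

## What passing tests do and do not show

The phantom validates the *machinery*: alignment, PCA recovery, sampling
bounds and stratification, TPS exactness, solver correctness against
closed forms, bootstrap calibration, SHAP exactness, and end-to-end
recovery of known dominant modes.  It does not validate anatomical
realism: the phantom's geometry is schematic, its shape modes are four
idealised fields rather than population anatomy, point noise is iid
Gaussian (real correspondence error is spatially structured), and the
linear-elastic proxy with a penalty facet surrogate is not the
hyperelastic, contact-resolving model whose parameters the INP export
carries.  Conclusions about a real cohort require real corresponded
meshes and an external solve of the exported decks.  Ligaments and
non-compressive load cases are out of scope throughout.
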