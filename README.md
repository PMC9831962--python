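# spineshape

Statistical shape modelling and mechanical shape-sensitivity analysis for
L4/L5 functional spinal units (FSUs) — two adjacent vertebrae, the
intervertebral disc and the facet joints.

The geometry of a spinal segment strongly influences its mechanical
response, but anatomical features do not vary independently: disc height,
nucleus size and facet clearance co-vary across a population.  This package
implements the workflow that respects those correlations: a PCA
point-distribution shape model trained on a corresponded mesh cohort is
sampled to generate plausible virtual subjects, each subject's volumetric
hexahedral mesh is morphed by thin-plate splines, a finite-element response
is evaluated under axial compression, and the variation in the outcomes —
intradiscal pressure (IDP) and facet contact pressure (FCP) — is attributed
back to individual shape modes by correlation and Shapley-value analysis.
The intended users are spine biomechanics and in-silico-trial researchers
who need virtual cohorts with population-realistic shape covariation.

Because subject-specific training cohorts of this kind are not public, the
package ships a fully synthetic **phantom cohort generator**: a simplified
two-vertebra + disc geometry (cortical/cancellous bone, seven concentric
annulus layers, nucleus, cartilaginous endplates, facet cartilage pads)
deformed by known latent shape modes, with analytic IDP-like and FCP-like
response functions.  Every pipeline stage is therefore testable against
exact ground truth.

## The model

Each subject is an ordered list of `p` corresponded surface points,
flattened to `s = (x_1..x_p, y_1..y_p, z_1..z_p)`.  After generalised
Procrustes alignment (rotation, translation, scaling; reflections
forbidden), PCA gives

    s = s̄ + Σ_m w_m φ_m,

with orthonormal modes `φ_m` and mode variances `λ_m` (eigenvalues of the
sample covariance, `t−1` divisor).  Modes are retained by a modified Kaiser
rule, `λ_m ≥ 0.7 λ̄`.  Model quality is reported as compactness
(cumulative explained variance), accuracy (training-shape reconstruction
RMSE), specificity (distance from sampled shapes to the nearest training
shape) and generalisation (leave-one-out RMSE).

Virtual subjects are drawn by Latin-hypercube sampling of
`w_m ~ N(0, λ_m)` truncated at ±2√λ_m, with Iman–Conover rank
rearrangement to minimise spurious inter-mode correlations; the sample size
comes from an exact power analysis of the multiple-correlation test
(random-predictor R² distribution).  Volumetric meshes follow the sampled
surfaces through a 3-D thin-plate spline (`U(r) = r`) fitted on a fixed
random subset of control points.  The in-repo solver is a small-strain
linear-elastic 8-node hexahedral FE model under a 400 N endplate pressure
(the full hyperelastic/contact material set is preserved in the Abaqus INP
export); IDP is the peak nucleus hydrostatic pressure, FCP an analytic
penalty surrogate of facet gap closure.  Outcome uncertainty is quantified
by percentile bootstrap of the mean versus sample size, and mode importance
by Pearson/Spearman correlation maps plus Kernel SHAP on a linear
surrogate, reported as normalised contribution percentages with a
drop-based importance cutoff.

## Worked example

```python
from spineshape import (PhantomSpec, generate_cohort, align_cohort,
                        fit_ssm, min_sample_size, PowerSpec)

spec = PhantomSpec(t=30, p=1300, seed=0)       # CI-sized phantom cohort
shapes, meshes, truth = generate_cohort(spec)
model = fit_ssm(align_cohort(shapes))
print(model.retained_, f"{100*model.compactness(model.retained_):.1f}%")
print(min_sample_size(PowerSpec()))            # 30 predictors, rho2=0.15
```

prints

```
4 96.2%
229
```

i.e. the Kaiser rule keeps the cohort's four generative modes (96.2% of
shape variance; leading eigenvalues 109.1, 44.6, 23.6, 7.8 mm²), and the
power analysis asks for at least 229 virtual subjects to resolve a medium
multiple-correlation effect (ρ² = 0.15) over 30 predictors at α = 0.05 and
95% power.  Solving the template mesh under 400 N axial compression gives
IDP 0.756 MPa and FCP 0.935 MPa.

The full workflow runs from the command line:

```bash
spineshape run-all --config test-scale --seed 0 --out run/
```

which writes, per stage, the cohort archive, Procrustes transforms, the
shape-model archive and performance report, the weight matrix, the warp
report, per-subject simulation results, bootstrap CI curves and the
sensitivity report (CSV/JSON plus heat-map figures).  The bundled
`paper-scale` configuration carries the full study settings (152 training
subjects, ~14k surface points, 500 synthetic subjects, 1000 TPS controls).

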