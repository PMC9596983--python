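# vesseltort

Quantitative 3D vessel-tortuosity analysis and its association with in-stent
stenosis (ISS) after flow-diverter stenting — as a tested, fully synthetic
pipeline.

Tortuous parent arteries (high curvature, strong twisting, low
straightness) are suspected to promote in-stent stenosis after
flow-diverter treatment of intracranial aneurysms. This package implements
the complete quantitative chain needed to study that question, for
researchers in vascular image analysis and clinical biostatistics:

1. **Centerline geometry.** A vessel centerline — the locus of centers of
   maximal inscribed spheres along a tubular surface — is extracted from a
   triangulated mesh, or supplied directly as discrete 3D points. A
   **free-knot regression spline** r(u) (interior knot positions optimized
   jointly with the coefficients) turns the points into an analytic curve
   with derivatives to order 3.
2. **Tortuosity metrics.** Frenet curvature and torsion,

       kappa = |r' x r''| / |r'|^3        tau = ((r' x r'') . r''') / |r' x r''|^2

   evaluated uniformly in arc length, are summarized per vessel as
   mean/max/range curvature and torsion (1/mm), together with the distance
   metric **DM = l / L** (straight-line endpoint distance over path
   length; 1 for a straight vessel).
3. **Stenosis quantification.** Percent in-stent stenosis is
   100·(1 − vessel diameter / stent diameter); narrowing strictly above
   25% is ISS, above 50% severe.
4. **Statistical association.** Univariate screening (pooled t-test,
   Pearson chi-square without continuity correction, Fisher's exact test
   for sparse tables; p < 0.1 advances), collinearity filtering
   (|r| > 0.9), multivariable binary logistic regression with Wald 95% CIs
   on the odds-ratio scale, and ROC analysis with a Youden-J cutoff.
5. **ML benchmarking.** Z-scoring, Borderline-SMOTE (variant 1)
   oversampling, recursive feature elimination, a stratified 80/20 split,
   10-fold cross-validated grid search, and per-model
   AUC/accuracy/sensitivity/specificity reports over pluggable classifier
   families (logistic regression, elastic net, SVM, random forest,
   XGBoost).

Because clinical imaging and per-patient data cannot be redistributed, the
package ships a first-class synthetic-data layer: analytic centerlines
(lines, arcs, helices — all with closed-form kappa/tau/DM), watertight tube
meshes swept around them, and patient cohorts whose feature distributions
are moment-matched to published summaries and whose ISS outcome follows a
calibrated logistic model (risk rising with maximum curvature, falling
with DM). Every pipeline stage is validated against these exact oracles.

## Worked example

From analytic helix to recovered geometry to cohort inference:

```python
import numpy as np
from vesseltort import (CurveSpec, make_curve, make_tube_mesh, extract_centerline,
                        compute_tortuosity, make_cohort, univariate_screen,
                        collinearity_filter, fit_logistic)

# helix with radius 3 mm and pitch 4 mm/rad: kappa = 3/25, tau = 4/25, DM = 0.8
curve, truth = make_curve(CurveSpec("helix", a=3.0, b=4.0, turns=1, n_points=200))
mesh = make_tube_mesh(curve, tube_radius=1.0, circumferential_resolution=24)
centerline = extract_centerline(mesh, step=0.5)
metrics, profile, spline = compute_tortuosity(centerline)
print(metrics.to_frame().round(4).to_string(index=False))
```

```
 mean_curvature  max_curvature  range_curvature  mean_torsion  max_torsion  range_torsion  DM      L       l
           0.12         0.1226           0.0037        0.1597       0.1882         0.0423 0.8 31.415 25.1327
```

The mesh-extracted, spline-fitted metrics match the analytic values
(kappa = 0.12 per mm, tau = 0.16 per mm, DM = 0.8, L = 10π ≈ 31.416 mm)
to well under a percent; the small max/range inflation comes from the
end regions of the extracted centerline.

```python
cohort = make_cohort(n=2000, iss_prevalence=0.355, seed=1)
for r in fit_logistic(cohort, ["max_curvature", "dm", "hypertension"], "iss"):
    print(f"{r.variable:15s} OR {r.odds_ratio:6.3f}  95% CI ({r.ci_low:.3f}, {r.ci_high:.3f})")
```

```
max_curvature   OR  1.089  95% CI (1.070, 1.109)
dm              OR  0.012  95% CI (0.007, 0.021)
hypertension    OR  2.411  95% CI (1.961, 2.965)
```

The fitted odds ratios recover the generating effects (1.084 per unit
maximum curvature, 0.01 per unit DM): each additional unit of maximum
curvature raises the ISS odds by ~9%, while a straighter vessel
(DM → 1) is strongly protective.

A `vesseltort` command-line tool wraps the same steps
(`synth curve|tube|cohort`, `centerline`, `metrics`, `stenosis`, `infer`,
`mlbench`); see `vesseltort --help`.

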