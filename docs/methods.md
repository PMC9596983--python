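# Methods

This note documents the models, algorithms and numerical choices behind
`vesseltort`, and what its synthetic data can and cannot say about real
vessels.

## Centerline model and extraction

The centerline of a tubular vessel is defined as the locus of centers of
maximal inscribed spheres. For an unbranched tube this is realized
cross-section by cross-section: `extract_centerline` marches planes along
the running tangent from one end ring to the other, takes each planar
section's maximal-inscribed-circle center, and then runs a second pass
re-slicing with planes normal to the smoothed tangent of the first-pass
polyline. Inscribed-circle centers of convex sections are computed exactly
as Chebyshev centers via a small linear program; nonconvex sections (rare
for sac-free tubes) fall back to the pole of inaccessibility. A full
Voronoi-based extraction would honour the same definition; the slicing
scheme was chosen because it needs no 3D medial-axis machinery and its
error is directly testable against generating curves.

Assumptions and behaviour:

- Input is a single connected, unbranched tube with **two open boundary
  rings**. Branching, closed or capped meshes raise `TopologyError`;
  bifurcation handling and aneurysm-sac removal are out of scope (inputs
  are assumed already sac-free).
- The default step of 0.5 mm is sub-voxel for rotational-angiography-scale
  vessels; spacing of the returned points is approximately the step.
- All slicing decisions are taken in a pose intrinsic to the mesh
  (principal axes signed by third moments, with boundary-ring fallbacks
  for symmetric shapes), so the extracted centerline is exactly
  independent of how the mesh is oriented in space. On synthetic tubes the
  measured invariance under random rigid motions is at the 1e-11 relative
  level, and extraction error on cylinders/torus segments stays below
  0.1% of the tube radius.
- A center that jumps by more than three steps means the slicing plane
  left the local channel (e.g. past the tube end of a coiled vessel) and
  terminates the march.

`clip_segment` cuts the sub-curve between the projections of two stent
landmarks, interpolating exact endpoint feet, and orients the result
proximal→distal (a flag disables the normalization). Landmarks farther
than one tube radius from the centerline are logged as suspicious but
still projected.

## Free-knot spline fitting

Discrete centerline points are chord-length parameterized to u ∈ [0, 1]
and fitted per coordinate with clamped B-splines sharing one knot vector.
Knot positions are free:

1. **Greedy insertion.** Starting from no interior knots, the knot
   interval carrying the most residual mass is split at the continuous
   residual-weighted median of its data parameters. The candidate is
   snapped to a fixed 1/1024 grid; this makes knot placement completely
   insensitive to rounding-level noise in the residuals (important for the
   exact-invariance guarantees below) and prevents a knot from coinciding
   with a data parameter.
2. **Model selection.** The knot count (up to `max_interior_knots`,
   default 25) is chosen by generalized cross-validation,
   GCV = (RSS/3n) / (1 − p/n)², with p basis functions per coordinate.
3. **Local optimization.** All interior knots are polished by bounded
   coordinate descent over a small stencil within each knot's neighbor
   gaps; a move is accepted only if it improves the RSS by more than 1e-10
   relatively. Coefficients are always profiled out by linear least
   squares. If the polish fails the fit falls back to uniform knots with a
   warning.
4. **Arc-length re-parameterization.** After the first fit, parameters and
   knots are mapped through the fitted arc-length function and the spline
   is refitted, making |r'| nearly constant — which conditions the Frenet
   formulas well and makes uniform-parameter sampling uniform in arc
   length.

The whole fit runs in a pose- and scale-canonical frame of the input
points and the coefficients are transformed back afterwards. Consequently
curvature/torsion profiles are invariant under rigid motions to ~1e-10
relative and exactly covariant under rescaling, as properties rather than
approximations.

**Degree and derivative accuracy.** The default degree is cubic, which
recovers curvature of a 200-point helix to better than 1e-3 absolute.
Torsion involves third derivatives, which for a cubic spline are piecewise
constant; cubic torsion on the same helix is accurate to ~3e-3. When
torsion to 1e-3 or better matters, fit with `degree=5` (errors drop to the
1e-5 level at identical cost). This guidance is encoded in the test suite.

**Degeneracy.** Where |r' × r''| ≤ 1e-8 |r'|³ (curvature below 1e-8 per
mm — far straighter than any vessel) the Frenet frame is undefined and
torsion is set to 0.

## Tortuosity summaries

Per vessel: mean/max/range of kappa and of |tau| (1/mm), path length L by
panel-wise Gauss–Legendre quadrature of |r'| between knots, straight-line
distance l between the fitted endpoints, and DM = l/L ∈ (0, 1]. Torsion is
summarized as a magnitude because tortuosity burden is chirality-free; the
signed profile is retained in `GeometryProfile.tau_signed`. Means are
arc-length weighted; since profiles are sampled uniformly in arc length
this equals the plain sample mean (the choice is stated because it would
matter under non-uniform sampling). Range summaries equal max − min over
samples; for vessels containing a straight run or an inflection the
minimum is ≈ 0 and range ≈ max, which is why the cohort generator emits
`range_curvature` as a duplicate of `max_curvature`.

## Stenosis

Percent stenosis is 100·(1 − vessel_d/stent_d). The alternative form
1 − stent_d/vessel_d that sometimes appears in figure captions yields
negative values for narrowing and is not used. Values ≤ 25 classify as
"none" (the ISS definition is *strictly* greater than 25%), 25–50 as
"ISS", above 50 as "severe"; severe counts as ISS in binary analyses.
Negative percentages (vessel wider than stent) are returned unclamped so
they can be flagged upstream.

## Synthetic data

**Curves.** Lines, arcs and helices are sampled at uniform parameter steps
with closed-form ground truth: helix r(t) = (a cos t, a sin t, b t) has
kappa = a/(a²+b²), tau = b/(a²+b²); an arc of radius a has kappa = 1/a;
DM follows from elementary arc-length geometry. The "composite" family is
a seeded low-order Fourier space curve without closed forms, for stress
testing. Measurement noise is isotropic Gaussian per coordinate — a
deliberate simplification; real centerline errors from segmentation are
spatially correlated and anisotropic.

**Tubes.** Meshes sweep a circular cross-section along the curve using
parallel-transport (rotation-minimizing) frames, which stay stable where
Frenet frames do not. The tube radius must stay below the minimum radius
of curvature (checked via discrete Menger curvature), otherwise the inner
wall would self-intersect. Ends are open by default (two boundary rings)
or capped with triangle fans into a watertight solid.

**Cohorts.** One row per patient. Continuous features are drawn from
two-parameter families moment-matched to published cohort summaries:
normal for age/BMI/parent-artery diameter, lognormal for strictly positive
right-skewed quantities (the curvature summaries have SD > mean, implying
strong skew), logit-normal for DM ∈ (0, 1) (parameters solved by
Gauss–Hermite quadrature). Height is not tabulated in the source
summaries; 161.5 ± 7 cm is used as a realistic value for a predominantly
female East-Asian cohort. Derived columns preserve internal consistency:
`range_curvature` duplicates `max_curvature`, `range_torsion` duplicates
`max_torsion`, and `straight_distance` = DM × path length. Binary features
are independent Bernoulli at their reported prevalences.

The ISS outcome follows a logistic model whose default natural-scale
coefficients encode the reported effect directions: +ln(1.084) per unit
maximum curvature, ln(0.01) per unit DM, +0.9 for hypertension. The
intercept is solved (Brent's method) on each realized sample so the mean
predicted risk equals the requested prevalence exactly — hence simulated
prevalence is calibrated by construction, verified at ±0.02 over hundreds
of replicates. CO (complete occlusion) is drawn independently at its
marginal prevalence of 0.79, since no covariate was associated with it.

What the generator does **not** emulate: correlations among features
(e.g. curvature metrics and vessel length are independent here),
measurement error in the tortuosity metrics, site effects, or any
nonlinear risk structure. Passing tests therefore demonstrate that the
*pipeline* is correct and calibrated, not that the clinical effect sizes
are reproducible from real data.

## Inference stage

- Continuous variables: two-sided pooled-variance t-test (Welch available
  by flag). Pooled variance is the default because it reproduces the
  recomputable reference p-values from printed group summaries.
- Binary variables: Pearson chi-square **without** continuity correction —
  this exactly reproduces the recomputable reference p = 0.067 for the
  hypertension 2×2 table, where the Yates-corrected value (0.118) does
  not. If any expected cell count is below 5 the test switches to
  Fisher's exact test, whose two-sided p equals exhaustive hypergeometric
  enumeration (verified for all tested tables with n ≤ 40).
- Screening threshold 0.1; no multiplicity adjustment at either stage
  (final α = 0.05), matching conventional clinical practice.
- Collinearity: of any candidate pair with |Pearson r| > 0.9 the member
  with the larger univariate p is dropped, visiting pairs in candidate
  order (deterministic; ties keep the earlier column). The source protocol
  names no specific collinearity test; this rule is declared, and chosen
  so that exactly duplicated tortuosity columns collapse to one.
- Logistic regression: maximum likelihood (statsmodels), Wald 95% CIs
  exponentiated to the OR scale; perfect separation raises an error that
  names the separating variable when a single variable accounts for it.
  Empirical CI coverage at n = 500 is ≈ 95% over 200 replicates.
- ROC: AUC via midrank Mann–Whitney (identical to the trapezoid over all
  thresholds; equal to brute-force pair counting on every tested
  instance), cutoff maximizing Youden's J — the cutoff rule is a declared
  choice, as the source reports a single operating point without naming
  its rule.

## ML benchmarking stage

- **Standardization** uses the population-SD convention and is fitted on
  one partition only; binary columns pass through. Zero-variance columns
  are dropped with a warning.
- **Borderline-SMOTE variant 1** (variant chosen as the common default): a
  minority point with m' majority neighbors among its k nearest (any
  class) is *noise* if m' = k (never seeds synthesis), *in danger* if
  k/2 ≤ m' < k. Danger points are interpolated toward their minority-class
  nearest neighbors with U(0,1) weights until the classes balance exactly.
  Parent indices are recorded so leakage can be audited.
- **SMOTE placement** defaults to `train_only`: oversampling after the
  split, from training rows only. The literal protocol being emulated
  applies SMOTE to the whole dataset *before* splitting; that places
  synthetic near-copies of minority rows in both partitions and inflates
  test metrics. Both placements are first-class
  (`smote_placement="before_split"`), so the optimistic protocol can be
  reproduced and quantified rather than silently corrected.
- **RFE** drops the least-important feature (|coefficient| for linear
  models, impurity importance otherwise) with refitting until the target
  count remains. Importance ties drop the later column, so of two
  duplicated columns the earlier survives. The six-predictor set reported
  by the emulated study (height, DM, maximum curvature, aneurysm neck,
  hypertension, dyslipidemia) ships as `ISS_PREDICTOR_PRESET` for
  synthetic experiments; the original 75-variable pool is not
  reconstructible, so configurations name their features explicitly.
- **Model comparison**: stratified 80/20 split, per-model grid search by
  stratified 10-fold cross-validation scored by AUC, with explicit small
  grids (no hidden defaults). Reported per model: mean training-fold AUC
  with a t-interval across folds (the CI construction is labelled as such,
  since the emulated protocol does not state its own), mean validation-fold
  AUC, and test AUC/accuracy/sensitivity/specificity at the 0.5 threshold.
  Training AUC exceeding validation AUC is expected optimism and is not
  treated as an error. All seeds are explicit; identical seeds give
  bitwise-identical reports. SHAP-style importance attribution is out of
  scope.

## Problem sizes

Test-suite and acceptance-script simulations use sizes chosen to make the
statistical checks decisive while keeping runs desk-scale: 200-point
curves, tubes at circumferential resolution 16–24, cohorts of 62 (the
emulated study size), 400–500 (recovery/coverage, 200 replicates) and
2000 (large-n parameter recovery), and two-model benchmark runs at n =
150–400. The full suite runs in well under a minute of compute for the
geometry and a few minutes end to end.

## Known limitations

- The centerline extractor handles single unbranched open tubes only, and
  its accuracy guarantees are established on synthetic meshes; real
  segmentations with surface noise, near-touching coils, or branch stumps
  are untested territory.
- Torsion magnitudes in published clinical tables are unit-ambiguous and
  internally inconsistent; the cohort generator matches their printed
  moments as feature distributions but no geometric meaning should be
  attached (and the spline stage reports honest 1/mm values).
- The logistic DM coefficient ln(0.01) is a point estimate with a very
  wide reported interval; synthetic cohorts treat it as exact truth.
- Free-knot optimization is local; pathological curves could in principle
  profit from a global knot search the package does not attempt.
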