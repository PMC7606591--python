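# Methods

This note documents the statistical machinery, the synthetic-data model,
the numerical choices, and the known limits of what the test suite
demonstrates.

## Vertex-wise GLM

Each measure (CT, SA, CV) is fitted independently per vertex by ordinary
least squares with design columns

`intercept, site, group, age, age², age×group, age²×group, sex, iq,
relatedness, total_sa` (plus `age³, age³×group` for the cubic model).

Coding and centering:

* Categorical factors are 0/1 indicators with documented reference levels:
  site A, control group, female sex, unrelated.  Indicators are left
  uncentered so β₂ is the case-minus-control shift at sample-average
  covariate values.
* Continuous covariates (age, IQ, total SA) are mean-centered across the
  combined sample.  Age powers are built from centered age and then
  re-centered, which limits collinearity between polynomial terms; the
  centering record is kept on the design object.
* Interactions multiply the centered age powers by the group indicator.
* The design is rank-checked at construction; rank deficiency raises an
  error naming the collinear columns.

IQ is included as a covariate by default and removable by a switch: the
source equation for this analysis family includes an IQ term even where
the accompanying prose lists the covariates inconsistently, and the
equation is the better-specified statement.  The cubic step adds both
`age³` and `age³×group`, keeping the interaction structure symmetric
across orders; a switch (`with_interactions`) exposes the
interaction-free variant.

Model selection is step-up on the combined sample: linear vs quadratic by
the nested F map `F = ((RSS_r − RSS_f)/q)/(RSS_f/(n − p_f))`, RFT
cluster-corrected at cluster p < 0.05 (one-tailed, F fields being
one-sided); only if any cluster survives is quadratic compared to cubic.
The adopted order is global — the highest order that significantly
improved fit anywhere — and the selection designs exclude age-by-group
interactions so the test isolates the age trajectory shape.

Global (whole-brain) comparisons use pooled-variance two-sample t tests
with df = n₁ + n₂ − 2 and Pearson correlations of IQ with the anatomical
globals.

## Smoothing

Per-vertex fields are smoothed by iterated graph diffusion
`x ← (I − τL)x` with `L = D − A` the combinatorial Laplacian.  The step
operator is symmetric and row-stochastic: constants are preserved exactly
and total mass is conserved (vertex areas are not weighted; on the
near-uniform meshes used here the difference is negligible).  A step with
rate τ adds per-axis positional variance `τ·Σ_e|e|²/V` on a 2-D manifold,
so the number of full steps (τ = 0.5/deg_max) plus one final partial step
is chosen to accumulate exactly the Gaussian target variance
`σ² = FWHM²/(8 ln 2)`.  FWHM 0 returns the input unchanged; negative FWHM
is an error.  The kernel is an approximation to a geodesic Gaussian,
calibrated by the variance-accumulation rule; the smoothness *estimator*
(below) measures what was actually achieved, so downstream inference does
not depend on the calibration being exact.

## Smoothness estimation and RFT cluster inference

Residuals are variance-normalized per vertex; for each mesh edge of
length d the summed squared difference of normalized residuals gives the
local correlation ρ = 1 − ssq/2, and under a Gaussian autocorrelation
model ρ(d) = exp(−2 ln2·d²/FWHM²) a per-edge FWHM.  Per-vertex
1/FWHM² values average the incident edges and are multiplied by one-ring
vertex areas to give resels per vertex.

One estimator defect matters at realistic df and is handled explicitly:
the raw per-vertex roughness is positively dependent on the statistic —
an extreme t at a vertex implies an atypically small residual norm there,
which inflates the normalized-residual differences on its edges by tens
of percent and hence inflates measured cluster extents in resels.  The
roughness (1/FWHM²) map is therefore regularized by surface-smoothing it
at twice the globally estimated FWHM before conversion to densities, the
same idea as resels-per-voxel regularization in nonstationary cluster
inference.  Without this step the empirical familywise error at nominal
0.05 was ≈0.19 on null simulations; with it, 0.05–0.07.

Cluster p-values use the expected-cluster framework for a 2-D search
region: with Euler-characteristic densities ρ₀, ρ₂ of the t (or F) field
at the forming threshold u, search resels R₂ and search-region Euler
characteristic χ,

```
E[m] = R₂·ρ₂(u) + χ·ρ₀(u)        expected cluster count
E[N] = R₂·ρ₀(u)                  expected suprathreshold resels
P(S ≥ s) = exp(−s·E[m]/E[N])     exponential extent distribution (D = 2)
p_FWE = 1 − exp(−E[m]·P(S ≥ s))
```

Defaults: cluster-forming threshold p = 0.001 per tail (configurable);
two-tailed analyses run each tail separately and double the per-tail p,
capped at 1, keeping signed clusters for downstream counting.  Zero-extent
clusters get p = 1.  Hemispheres are separate search regions whose resels
and Euler characteristics are summed for whole-brain correction; clusters
never bridge hemispheres.  Degenerate vertices (zero residual variance)
are flagged undefined and excluded from resel sums.

Validity condition: the continuum approximation requires the field's FWHM
to span roughly three or more mesh edges.  On icospheres this fixes the
radius-per-subdivision choices used throughout the tests (subdivision 3 at
radius 20 mm gives ~2.6 mm edges for 10-mm smoothing); on a coarser
lattice single-vertex excursions already exceed the theoretical mean
cluster size and the correction becomes anticonservative.

## Overlap and decomposition statistics

Masks are per-vertex {−1, 0, +1} signed indicators of cluster-corrected
significance.  Overlap classification counts each vertex of the union of
CT- and SA-significant vertices as CT-only, SA-only or both, ignoring
signs; percentages are over the union (that is what makes the published
"Total (100)" column an identity) and are rounded half-up to two decimals
with `decimal` arithmetic, not binary-float rounding.  The χ² test is a
goodness-of-fit of the three category counts against equal expectation,
df = 2.  The decomposition restricts to CV-significant vertices, splits
them by CV sign, and attributes each to CT-only / SA-only / both /
neither; percentages are per direction.

The simulation null draws, per simulation, two independent iid statistic
maps thresholded two-tailed at α.  A vertex is then significant in either
map independently with probability exactly α, so the implementation draws
the four joint significance categories directly as one multinomial per
simulation — distributionally identical to materializing random t maps,
and fast enough for 5000 simulations at 300 000 vertices.  The null maps
are deliberately unsmoothed iid fields, mirroring the stated construction
of this null; against spatially smooth observed masks this makes the null
narrow and the test anti-conservative in the direction of small p-values,
which is documented rather than "fixed".  The empirical p uses the
add-one estimator (1 + #{null ≥ observed})/(N + 1) and is never zero; its
smallest attainable value at N = 5000 is ≈0.0002.

A note on reported values in the source tables this package emulates: the
printed χ² statistics are not reproducible from the printed counts under
the described equal-distribution test, one overlap percentage (91.88 for
27 977/30 416) disagrees with its own counts by 0.1, and the simulation p
of 0.0001 is unattainable at N = 5000 under standard estimators.  The
package implements the described procedures; the count-derived arithmetic
is what the tests assert.

## Synthetic cohort generator

The generator defines the study conditions under which everything is
tested:

* Cohort: 62 cases (ages 6–31, truncated normal 16 ± 7) vs 57 controls
  (ages 6–27, 15 ± 6); IQ 82 ± 13 vs 114 ± 16; total SA 0.20 vs 0.23 m²
  with sd 0.0275 m² (the sd implied by the published group means and
  t(117) = −5.95, the printed sd being inconsistent with its own range
  and t); mean CT 2.72 ± 0.14 vs 2.73 ± 0.12 mm; total grey volume
  0.59 ± 0.23 vs 0.64 ± 0.24 L (reproducing the published non-significant
  t); sex and site approximately balanced; ~10 % relatedness flags; 9
  prodromal-psychosis cases.
* CT per subject and vertex: subject baseline + quadratic age trend
  (−0.015 mm/yr linear, +0.0006 mm/yr² by default) + planted effects +
  spatially smooth Gaussian noise (default 10-mm FWHM, sd 0.20 mm).
  Noise fields are drawn iid, surface-smoothed, and rescaled to the
  target marginal sd, so planted Cohen's-d effect sizes are in honest
  units of the realized noise sd.
* SA: template one-ring vertex areas scaled by the subject's total SA,
  modulated by a weak age trend, planted relative effects and smooth
  relative noise (sd 0.10).
* CV = CT × SA per vertex, times optional log-normal noise (sd 0.05).
  This product rule is the generative premise that makes SA-driven CV
  loss and the masking of CV differences by opposing CT/SA effects
  *emergent* outcomes of the decomposition stage.
* Planted effects are hop-balls around a seed vertex with a sign, an
  effect size, and an optional age-by-group interaction slope; ground
  truth signed masks are returned.  The overlap scenario builder places a
  CT(+) and an SA(−) ball whose Jaccard overlap matches a requested
  fraction to within about one adjacency ring, verified by brute-force
  counting.

What the generator does not emulate: scanner/site bias fields (site is a
pure mean shift), FreeSurfer reconstruction error, cortical folding
geometry (templates are spheres), spatial covariance of true anatomical
effects, or family structure beyond a binary relatedness flag.  Passing
tests therefore demonstrate the statistical machinery under its own
assumptions — Gaussian smooth noise on a homogeneous closed surface — not
robustness to real-data violations of them.

## Problem sizes and determinism

Test and acceptance problem sizes are chosen for a desk-scale suite:
642-vertex spheres (subdivision 3) for calibration and recovery, 2562
vertices (subdivision 4) for overlap-scenario geometry, n = 40 null
cohorts and 1000 simulations for familywise-error calibration, 20 seeds
for recovery rates, and 200–5000 simulations for the overlap null.  All
randomness flows from explicit seeds through `numpy.random.default_rng`;
pipelines are deterministic given the config seed, and reports embed a
config hash and per-file checksums.

## Known limitations

* Cluster inference is calibrated for the smooth-field regime; severely
  under-resolved fields (FWHM ≲ 2 edges) are outside the contract.
* The relatedness covariate is a fixed-effect indicator, not a
  mixed-effects family model.
* No peak-level (vertex-wise) RFT p-values, no TFCE, no permutation-based
  primary inference.
* CV's multiplicative construction makes its noise slightly heavy-tailed;
  group-level null calibration was verified for CV-style fields (FWE
  ≈0.04 on 300 simulations), but extreme-tail behaviour beyond that is
  unverified.
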