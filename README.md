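# surfmorph

Vertex-wise surface-based morphometry for two-group developmental cohorts:
general linear models of cortical thickness (CT, mm), surface area (SA,
mm²) and cortical volume (CV, mm³) on triangulated template surfaces,
random-field-theory (RFT) cluster correction for non-isotropic fields, a
CT/SA spatial-overlap statistic with a simulation null, and the
decomposition of CV differences into CT-driven, SA-driven, joint and
unexplained components.

The package is aimed at researchers analysing FreeSurfer-style per-vertex
measures resampled to a common template (e.g. a case/control comparison in
a genetic syndrome cohort), and at methodologists who want a desk-scale,
fully synthetic test bed for cluster-corrected surface statistics: a
built-in generator produces cohorts and per-vertex measures with known
ground truth, so every stage of the pipeline is testable without MRI data.

## The model

At each vertex *i* and subject *j*, each measure is modelled by ordinary
least squares as

```
Y_i = β0 + β1·Site + β2·Group + β3·Age + β4·Age² + β5·(Age×Group)
      + β6·(Age²×Group) + β7·Sex + β8·IQ + β9·Relatedness + β10·TotalSA + ε
```

with continuous covariates mean-centered across the combined sample.  The
age polynomial order is chosen by a step-up nested-model procedure: linear
vs quadratic by a vertex-wise F test with RFT cluster correction, then
quadratic vs cubic only if the first step is significant anywhere.

Cluster correction treats the t (or F) map as a smooth random field.  The
local FWHM of the error field is estimated from normalized-residual
differences along mesh edges, the search region is measured in resels
(area / FWHM²), and a suprathreshold cluster of extent *s* resels gets a
familywise p-value from the expected-cluster framework,
`p = 1 − exp(−E[m]·exp(−s·E[m]/E[N]))`, with per-tail p doubled for
two-tailed inference.

Cluster-corrected signed masks for CT, SA and CV then feed three bespoke
statistics:

* **overlap classification** — each significantly different vertex is
  CT-only, SA-only or both (sign ignored), with percentages over the union
  and a χ² goodness-of-fit test against equal category counts;
* **simulation null** — the overlap percentage expected from two spatially
  independent difference maps thresholded two-tailed at α (analytic mean
  `100·α²/(2α−α²)`, 2.56 % at α = 0.05), with an add-one empirical p;
* **CV decomposition** — CV-significant vertices split by direction and
  attributed to a co-occurring CT difference, SA difference, both, or
  neither ("unexplained").

## Worked example

Run the full pipeline on a synthetic cohort (62 cases vs 57 controls) with
planted, partially overlapping effects — CT increased and SA decreased in
clusters sharing 20 % of their union:

```python
from surfmorph import pipeline, overlap

cfg = pipeline.RunConfig.from_dict(dict(
    synthetic=dict(icosphere_subdivisions=3, icosphere_radius_mm=20.0,
                   overlap_fraction=0.2),
    seed=3, overlap_sims=1000))
bundle = pipeline.run_pipeline(cfg)
print(overlap.render_tables({"p<0.05": bundle.overlap_tables["p<0.05"]},
                            {"p<0.05": bundle.decomposition_tables["p<0.05"]}))
```

prints (abridged):

```
Spatial overlap of CT and SA differences [p<0.05]
measure                           left                 right              combined
ct_only                       69(37.3)              55(28.5)             124(32.8)
sa_only                       79(42.7)             90(46.63)            169(44.71)
ct_and_sa                       37(20)             48(24.87)             85(22.49)
total                         185(100)              193(100)              378(100)

CV decrease decomposition [p<0.05]
measure                           left                 right              combined
cv_total                       64(100)               79(100)              143(100)
ct_only                           0(0)                  0(0)                  0(0)
sa_only                      62(96.88)             77(97.47)             139(97.2)
ct_and_sa                      1(1.56)                  0(0)                1(0.7)
cv_explained                 63(98.44)             77(97.47)             140(97.9)
cv_unexplained                 1(1.56)               2(2.53)                3(2.1)
```

Reading the output: of the 378 vertices with any significant difference,
22.49 % differ in both CT and SA — close to the planted 20 % and far above
the 2.67 % a spatially independent null produces
(`bundle.null_overlap.p_value` ≈ 0.001 at 1000 simulations).  Because the
generator builds CV as the per-vertex product CT × SA, the 143 CV decreases
are attributed almost entirely to the planted SA reduction (97.2 %
SA-only) and the 22 CV increases to the planted CT increase — the
decomposition recovers the generative mechanism rather than restating it.

The same stages are available from the shell:

```
surfmorph run --config cfg.yaml --seed 3 --out results/
surfmorph overlap --ct ct_mask.curv --sa sa_mask.curv --alpha 0.05 --sims 5000
surfmorph decompose --cv cv.curv --ct ct.curv --sa sa.curv
surfmorph make-fixtures --out study_dir/
```

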