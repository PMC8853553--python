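# Methods

## Scope and model

`glomorph` quantifies hypertensive glomerulopathy the way clinical renal
pathology does, and validates the whole measurement chain on synthetic
cohorts with known ground truth.  The chain is:

1. **Morphometry** — per-glomerulus measurements on PAS / Masson-trichrome
   stained section profiles: tuft convex-polygon area (GLA), PAS-positive
   mesangial area (MEA), mesangial nuclei count (MEC), trichrome
   collagen/sclerosis area, and tuft counts per field of view.
2. **Stereology** — profile areas to volumes via the Weibel-type relation
   GLV = GLA^1.5·β/κ with β = 1.38 (spheres) and κ = 1.01 (near-monodisperse
   size distribution); MEV = (MEA/GLA)·GLV by the areal-fraction =
   volume-fraction identity; GCV = GLV − MEV; numerical density
   Nv = (ΣN_A/ΣA)/√(4·GLA/π) with the pooled-ratio count estimator.
3. **Lesion classification** — the human criteria: hyalinosis vs sclerosis
   by the dual-stain rule (hyaline deposits are red in *both* stains,
   sclerosis is PAS-red but trichrome blue/green); GGS when sclerosis
   occupies strictly >50% of GLA; hypertrophic / ischemic remodeling read
   off the glomerular-volume histogram as profiles above the control 95th /
   below the control 5th percentile.
4. **Cohort statistics** — normality screening (Lilliefors-corrected KS,
   D'Agostino–Pearson, Shapiro–Wilk), Welch's t with automatic Mann–Whitney
   fallback for non-Gaussian endpoints, one-way ANOVA with post hoc t-tests
   vs control, chi-square (exact fallback) for lesion frequencies,
   ROUT-style outlier removal, mean ± SEM summaries at α = 0.01.
5. **Human comparison** — twelve packaged clinical reference studies; a
   model is called "effective" at reproducing human hypertensive
   glomerulopathy only above 40% hyalinosis/FSGS and 20% GGS.

## The synthetic cohort generator

Each experimental group (chronic angiotensin-II infusion and TTRhRen
renin-transgenic mice vs FVB controls; SHR and Goldblatt 2K1C rats —
clipped and non-clipped kidneys — vs Wistar controls) is a `GroupPreset` of
effect-size multipliers relative to control (GLV, MEV, GCV, MEC, collagen,
Nv) plus size-class fractions (hypertrophic/ischemic) and stain-lesion
frequencies (hyalinosis/FSGS/GGS).  Tufts are spheres with lognormal
radius within each size class; compartments are carried as volume
fractions, nuclei as a Poisson density per mesangial volume.

Design choices worth knowing:

* **The presets target the estimator, not the raw mean.**  Published cohort
  volume changes are mean-GLA-based estimates, so class scales are solved
  on the section-area scale such that (Σ wₖaₖ)^1.5 equals the group's GLV
  ratio.  This makes the pipeline's recovered percent change an unbiased
  probe of the encoded effect even for mixture cohorts.
* **Class structure.**  The hypertrophic fold is pinned only where a value
  is reported (TTRhRen, ~3-fold); for SHR and the non-clipped kidney the
  normal class stays at control scale and the fold is solved from the
  cohort constraint (≈2.0 and ≈1.65), keeping those cohorts
  unimodal-right-shifted as their published distribution curves are.  The
  clipped kidney pins normal at control and solves the ischemic scale
  (≈0.43× volume).
* **Baselines are explicit config** because only ratios are published:
  control GLV 1.7×10⁵ μm³ (mouse) / 8×10⁵ μm³ (rat); control mesangial
  volume fraction 0.30 / 0.576 — these two values are *derived*, being the
  unique fractions for which the published GLV/MEV/GCV triplets are
  mutually consistent; MEC 18 / 30 nuclei per profile; Nv 100 / 30 mm⁻³;
  collagen fraction 0.01; counting-field area 2×10⁶ μm² (x100 field);
  section thickness 4 μm.
* **Size spread.**  Within-class log-volume SD is 0.10.  κ = 1.01 encodes a
  nearly monodisperse population; a broader spread would be inconsistent
  with using that κ.
* **Sectioning.**  `section_population` cuts every tuft with one random
  plane.  With offsets uniform over the full extent (the default) the mean
  profile area converges to (2/3)πR² — this mode, without the 5%
  grazing-section cutoff, is used to calibrate β = V/E[A]^1.5 = 1.382.
  The cohort morphometry protocol instead samples a near-equatorial window
  (offset ≤ 0.25 R), emulating the pathologist's selection of profiles
  with visible macula densa and arterioles.  Fully random offsets would
  make per-profile volumes so noisy that grazing sections of normal
  glomeruli flood the histogram's left tail and the ischemic class becomes
  undetectable; near-equatorial selection is what makes per-profile
  histograms interpretable.  One consequence, inherited from the field's
  practice, is that β = 1.38 (derived for fully random planes) then
  *overestimates absolute* volumes by a constant factor; all published and
  recovered quantities are ratios, which cancel it.
* **Field counts** are Poisson with mean Nv·D̄·A where D̄ is the same mean
  tuft diameter the density estimator divides by, making the estimator
  consistent by construction; recovery at 300 fields is a genuine
  Monte-Carlo check of the counting statistics, not an identity.

## What the synthetic data does not emulate

Real tissue brings lobulated (non-spherical, non-convex) tufts,
section-thickness overprojection, stain variability between batches,
touching glomeruli, tubulointerstitial context, and animal-level
clustering (profiles are pooled per group here, as in the source
protocol; the per-animal `kidney_id` is carried so a per-animal analysis
is possible).  Passing the recovery tests therefore demonstrates that the
estimators and classifiers are correct and well-calibrated on their own
assumptions — not that segmentation of real histology is solved.

## Numerical and procedural notes

* Stain quantification: fixed-matrix colour deconvolution (the matrix is
  shared with the tile renderer) followed by Otsu thresholding with an
  optical-density floor (0.15; 0.20 for hematoxylin) so blank tiles read
  zero.  Nucleus blobs pass a 10–80 μm² band at the default calibration of
  0.25 μm/px; touching nuclei are split by a distance-transform watershed.
* GLA is the analytic convex-hull area over pixel corners (a solid w×h
  rectangle measures exactly w·h pixels); compartment areas are pixel
  counts.  Field counts use the unbiased counting frame (include top/left
  edges, exclude bottom/right).
* The percentile size classifier carries a 5% base rate by construction:
  on the control sample itself it calls ~5% hypertrophic and ~5% ischemic,
  and on a cohort whose whole distribution is shifted it labels the bulk
  rather than a remodeled subpopulation (the angiotensin-II cohort, being
  globally diminished, is almost entirely below the control p5 without any
  ischemic remodeling).  This is a property of the histogram rule, not a
  bug; the fractions it is used for (clipped ischemic, TTRhRen/SHR
  hypertrophic) concern cohorts with a genuine separated mode.
* TTRhRen encodes a real tension in its source values: a +12% mean GLV
  with a 10% subpopulation at ~3-fold cannot both hold with the normal
  class exactly at control scale; the solver places the normal class at
  0.967× control and percentile detection lands at ~11–12%.
* ROUT is operationalised for univariate samples: robust fit = median,
  scale = MAD×1.4826, two-sided normal p-values on standardized residuals,
  Benjamini–Hochberg at Q = 1%.  Below n = 10 it is a warned no-op.
* Automatic test selection switches to Mann–Whitney when any normality
  test rejects at p < 10⁻³; the selection is recorded in the result.  No
  multiple-testing correction is applied across endpoints (each endpoint
  is reported at P < 0.01, as in the source protocol).
* Collagen percent change is reported on the volume basis (pooled areal
  fraction × GLV), consistent with MEV; the area basis would conflate the
  fraction change with the tuft-size change.
* Lesion frequencies carry a denominator floor of 2400 scanned glomeruli;
  below it the estimate is computed but flagged and the adequacy verdict
  is withheld.  Human chi-square contrasts assume a nominal denominator of
  1000 where a study published only percentages (flagged approximate).
* Determinism: every stochastic step takes an explicit seed; a fixed
  (preset, n, seed) reproduces measurement tables byte for byte.

## Problem sizes

The standard protocol is 600 profiles and 300 counting fields per group,
with 3000 scanned glomeruli for rare-lesion frequencies and 10⁵ sphere
sections for the β calibration; these match the source protocol's scales
and keep every analysis script and the full test suite fast on one CPU.

## Known limitations

Solidified glomeruli are representable in truth labels but have no
automatic classifier (distinguishing them from ischemic GGS requires
Bowman-capsule context the tile model does not include); none are
generated by the packaged presets, which mirrors the source finding.
Absolute nephron number per kidney is out of scope (no cortical volume is
modeled); Nv ratios carry the nephron-number conclusions.  The Columbia
FSGS subtypes, crescents, adhesions and arteriolar lesions are not
scored.
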