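# glomorph

Quantitative assessment of hypertensive glomerulopathy in animal models,
using the criteria of human renal pathology.

Most experimental-hypertension studies grade kidney damage with ad-hoc
"glomerular lesion scores" that cannot be compared between studies or
with patients.  This package implements the alternative: measure each
glomerulus, classify each lesion with the definitions used in clinical
pathology, and put the animal numbers on the human scale.  It is aimed at
renal pathology and hypertension researchers who have (or simulate)
per-glomerulus measurements from PAS- and Masson-trichrome-stained
sections.

## What it computes

**Stereology.**  From the convex-polygon tuft area GLA of sectioned
glomeruli:

    GLV = GLA^1.5 · β/κ          (β = 1.38 for spheres, κ = 1.01)
    MEV = (MEA/GLA) · GLV        (areal fraction = volume fraction)
    GCV = GLV − MEV
    Nv  = (ΣN_A / ΣA) / √(4·GLA/π)

giving glomerular, mesangial and capillary volumes and the numerical
density of glomeruli (nephron-number proxy), plus mesangial cellularity
(MEC, nuclei within MEA).

**Lesion classification.**  Hyalinosis vs sclerosis by the dual-stain
rule (hyaline deposits are red in both PAS and trichrome; sclerosis is
PAS-red but trichrome blue/green); global glomerulosclerosis when the
sclerotic area exceeds 50% of GLA; hypertrophic and ischemic glomeruli
from the volume histogram (beyond the control 5th/95th percentiles).

**Cohort statistics.**  Normality screening, Welch's t with automatic
Mann–Whitney fallback, ANOVA + post hoc tests, chi-square lesion-frequency
tests, ROUT-style outlier removal, mean ± SEM, α = 0.01.

**Synthetic cohorts.**  A first-class generator produces virtual 3-D
glomerulus populations, random plane sections, measurement tables and
optional rasterized PAS/trichrome tiles with ground-truth masks, under
presets encoding four hypertensive models (angiotensin-II infusion,
TTRhRen renin-transgenic mice, SHR, Goldblatt 2K1C rats) — the pipeline's
end-to-end validation harness.  See `docs/methods.md` for the model and
its assumptions.

## Worked example

```python
import glomorph as g

control = g.simulate_cohort(g.get_preset("control_mouse"), 600, seed=1)
angii   = g.simulate_cohort(g.get_preset("angii"), 600, seed=1)

vc, va = g.cohort_volumes(control), g.cohort_volumes(angii)
print(f"GLV {100 * (va.glv_um3 / vc.glv_um3 - 1):+.1f}%  "
      f"GCV {100 * (va.gcv_um3 / vc.gcv_um3 - 1):+.1f}%  "
      f"MEV {100 * (va.mev_um3 / vc.mev_um3 - 1):+.1f}%  "
      f"MEC {g.percent_change(angii['mec_count'], control['mec_count']):+.1f}%")
```

prints

```
GLV -39.0%  GCV -68.2%  MEV +28.9%  MEC +92.9%
```

— the angiotensin-II kidney loses ~39% of glomerular volume through a
collapsed capillary compartment while the mesangium expands and nearly
doubles its cell count: mesangioproliferative injury, not hypertensive
glomerulosclerosis.  The same cohorts feed the lesion classifiers and the
human comparison (`g.run_pipeline(...)`), which verdicts every packaged
model "not effective" at reproducing human-scale hypertensive
glomerulopathy (>40% hyalinosis/FSGS, >20% GGS).

The numbered drivers under `analysis/` run the full study — cohort
simulation, volume changes, lesion frequencies, nephron density,
statistics, human comparison — writing tables to `results/`.  A CLI is
included: `glom simulate --preset angii --n 600 --seed 1 --out dir/`,
plus `glom measure` (tiles → measurement table), `glom analyze` and
`glom report`.

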