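# sonoderm

Quantitative analysis of high-frequency B-mode ultrasound (HFUS, 20 MHz
class) images of skin, built for longitudinal treatment monitoring of
actinic keratosis and similar conditions. Given expert-contoured layer
boundaries — entry echo, subepidermal low-echogenic band (SLEB), dermis —
the package extracts a battery of per-layer morphological, echogenicity
and texture features, and runs the nonparametric statistical design used
in post-therapy follow-up studies: a paired Wilcoxon battery of every
follow-up visit against baseline, a Mann–Whitney contrast against healthy
control skin, Kruskal–Wallis/Dunn contrasts across severity stages, and a
paired test of the AKASI clinical severity score.

Because clinical HFUS datasets are rarely shareable, the package also
ships a first-class phantom generator: three-layer speckle phantoms with
known ground-truth contours and controllable longitudinal effects, so the
whole pipeline is testable and demonstrable without any patient data.

## Features extracted per layer

With a region mask R (|R| pixels, intensities I ∈ [0, 255]) and boundary
polylines u(c), l(c) over columns c:

* **Thickness** — mean over columns of (l(c) − u(c)) · Δz (mm), and
  **TVI** (thickness variation index), the sample SD of the same profile.
* **SR** — surface roughness: sample SD of the rasterized upper-edge rows
  (px). **PAR** — perimeter-to-area ratio of the pixel-square union.
  **ACR** — area over convex-hull area, ≤ 1, with 1 for a convex band.
* **LEP / MEP / HEP** — fraction of pixels with I < 30, 50 ≤ I ≤ 150 and
  I > 200 respectively (the bands 30–49 and 151–200 are deliberately
  unclassified, so the three ratios need not sum to 1).
* **MPI, PIV, EPI** — mean intensity, sample SD of intensity, and Shannon
  entropy of the 256-bin histogram normalized by 8 bits (EPI ∈ [0, 1]).
* **GLCM contrast / correlation / energy / homogeneity** — from masked,
  symmetric gray-level co-occurrence matrices at distance 1 in four
  directions (0°, 45°, 90°, 135°), counting only pixel pairs that lie
  entirely inside the layer; reported per direction plus the mean.

Statistical battery: two-sided Wilcoxon signed-rank (exact for n ≤ 25
without ties), one-sided follow-up only after two-sided rejection, effect
size r = |z|/√n graded small/moderate/large at 0.3/0.5, and sample-size
estimation via the noncentral-t paired design inflated by the Wilcoxon
minimum asymptotic relative efficiency 0.864.

## Worked example

Simulate the default 56-marker cohort (visits at weeks 0/4/8/12 plus a
35-image control arm) with one injected treatment effect — SLEB thinning
to 0.575× baseline at week 12 — then run every analysis stage:

```python
from sonoderm import CohortSpec, run_all
from sonoderm.phantom import BASELINE_SPREADS

effect = (0.2325 - 0.4039) / BASELINE_SPREADS[("thickness", "sleb")]
cspec = CohortSpec(per_feature_effect={("thickness", "sleb", 12): effect}, seed=1)
report, summary = run_all(cspec)
print(summary)
```

prints

```
sonoderm run report (seed=1)
  extraction: ok
  longitudinal: ok
    18/276 cells significant
  control: ok
  stage_wise: ok
  akasi: ok
    median 4.58 -> 0.08, r=0.869 (large), clearance 48%
```

The longitudinal battery tests 276 (feature × layer × week-pair) cells;
with a single injected effect, significant cells are that effect plus
features mechanically coupled to SLEB thickness and a false-positive
fringe near the 5% level. The injected cell itself comes out decisively:

```python
[r for r in report["stages"]["longitudinal"]["output"]["results"]
 if (r["feature"], r["layer"], r["week_pair"]) == ("thickness_mm", "sleb", "0-12")]
# [{'n': 56, 'p_two_sided': 1e-10, 'effect_r': 0.869, 'effect_grade': 'large',
#   'direction': 'decrease', 'significant': True, ...}]
```

The AKASI line shows the paired severity-score test on the generated
clinical scores: median 4.58 before vs 0.08 after, a large rank effect
(r = 0.869), with 48% of patients reaching complete clearance.

The same run is available from the shell:

```
sonoderm all --seed 1 --out report.json
sonoderm simulate --seed 1 --out fixture/   # PNG frames + contour CSVs + manifest
sonoderm extract fixture/manifest.json --out features.csv
sonoderm analyze features.csv --out-dir results/
```

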