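# isletex

Quantitative analysis of insulin-granule exocytosis in pancreatic islets
across the stages of type 2 diabetes progression.

In two-photon recordings of islets bathed in the membrane-impermeant dye
sulforhodamine B (SRB), every granule that fuses with the plasma membrane
fills with dye and appears as an abrupt, persistent punctate brightening.
In prediabetic (stage 1) db/db islets these fusion events become spatially
clustered: granules fuse sequentially onto an existing fusion site
(*compound exocytosis*), instead of each fusing independently through its
own pore (*primary exocytosis*). `isletex` implements the full quantitative
workflow around that observation, for imaging labs and modellers who want a
tested, seedable reference implementation:

- **synthetic scenes** (`isletex.synthetic`) — seeded SRB movies with ground
  truth: primary events as a homogeneous spatial Poisson process, compound
  sites as a Neyman–Scott cluster process (Poisson parents, jittered
  offspring, sequential fusion times with exponential gaps), rendered as
  additive Gaussian spots that persist after fusion; plus synthetic GTT
  curves and Fura-2 calcium traces.
- **event detection** (`isletex.detect`) — fusion events as local maxima of
  the smoothed frame-to-frame difference with a robust per-pixel noise model
  (temporal MAD), prominence filtering, sub-pixel centroids, repeated-fusion
  site grouping, spot FWHM measurement and per-cell assignment.
- **neighborhood statistics** (`isletex.spatial`) — for each event, the
  number of events inside a 4 μm² window centred on it; an event with ≥ 7
  granules in its window is classified as compound exocytosis, < 7 as
  primary; the tail frequency P(count ≥ k) summarises the clustering.
- **disease staging** (`isletex.staging`) — trapezoidal AUC of the glucose
  tolerance test and the four-stage severity classification
  (< 1,600 / 1,600–2,200 / 2,200–2,800 / > 2,800 mmol/l × min).
- **calcium** (`isletex.calcium`) — ratiometric (Grynkiewicz) conversion
  [Ca²⁺] = K_d · β · (R − R_min)/(R_max − R) and baseline/peak summaries.
- **group statistics** (`isletex.report`) — secretion as % of insulin
  content, pooled two-tailed unpaired t tests, and spider-plot
  normalisation across stages.

## Worked example

```python
import numpy as np
from isletex import (SceneParams, generate_scene, detect_events,
                     neighborhood_counts, classify_exocytosis, tail_frequency,
                     GTTCurve, stage_curve)

# a 50x50 um, 20-min recording with both primary and compound events
scene, truth = generate_scene(SceneParams(cluster_rate=0.002, seed=42))
events = detect_events(scene)
print(f"true events: {len(truth.events)}  detected: {len(events)}")

profile = neighborhood_counts(events)
cls = classify_exocytosis(events)
print(f"compound events: {cls.n_compound}/{cls.n_compound + cls.n_primary} "
      f"({100 * cls.fraction_compound:.1f}%)")
print(f"tail frequency at 7: {100 * tail_frequency(profile, 7):.2f}%")

result = stage_curve(GTTCurve([0, 15, 30, 60, 90, 120],
                              [6.1, 14.8, 17.2, 12.0, 9.4, 7.6]))
print(f"GTT AUC: {result.auc_mmol_l_min:.0f} mmol/l x min -> stage {result.stage}")
```

prints

```
true events: 89  detected: 80
compound events: 14/80 (17.5%)
tail frequency at 7: 17.50%
GTT AUC: 1411 mmol/l x min -> stage 1
```

89 granule fusions were simulated; 80 are detected (sequential fusions at
one compound site that land in the same frame closer than the merge radius
are reported as one step, so the detected count sits slightly below truth on
clustered scenes). 17.5% of the detected events have seven or more events
within their 4 μm² window and are therefore classified as compound
exocytosis — the clustered regime; an unclustered (Poisson) scene of the
same density gives a tail frequency near zero. The GTT with fasting glucose
6.1 mmol/l integrates to 1,411 mmol/l × min, below the 1,600 boundary, so
the animal is stage 1 (compensated, prediabetic).

The same pipeline is available from a shell:

```bash
isletex simulate --config scene.yaml --out sim/
isletex detect --movie sim/movie.tif --out events.csv
isletex classify --events events.csv --window-area 4 --threshold 7
isletex stage --gtt curves.csv
```

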