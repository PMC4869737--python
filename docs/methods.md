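# Methods

## Scope and model

`isletex` analyses granule-fusion activity in beta cells imaged with the
SRB dye-entry assay, and the surrounding physiology used to stage disease in
the db/db mouse model: glucose-tolerance-test (GTT) AUC, Fura-2 calcium, and
insulin secretion normalised to content. The package is organised in the
order the analysis runs: synthetic data generation → event detection →
spatial classification → staging / calcium / group statistics.

## Synthetic scene generator

The generator produces movies with the statistical structure the analysis
assumes, so every stage can be validated against known ground truth.

**Point processes.** Primary fusion events form a homogeneous spatial
Poisson process with intensity `primary_rate` (events/μm² per recording) and
uniform event times. Compound sites form a Neyman–Scott cluster process:
parent sites are Poisson with intensity `cluster_rate`; each parent spawns
`cluster_size_dist` granules (default: fixed 8, on the scale of the
multi-granule footprints seen in clustered islet recordings; any
distribution with support ≥ 2 can be supplied), jittered isotropically with
SD `cluster_sd_um` (default 0.2 μm, well inside the 2 μm window side so a
cluster stays co-windowed). Granules at one site fuse sequentially with
exponential inter-fusion gaps (mean `inter_fusion_interval_s`, default
10 s); times that would overrun the recording are clamped to its end so
every generated event is observable.

**Rendering.** Each event adds a 2-D Gaussian spot (σ = `event_radius_um`,
default 0.5 μm; peak `event_amplitude`, default 20 a.u.) from its first
frame onward — a fused granule stays dye-filled, so there is no decay by
default (an optional single-exponential decay is available). Overlapping
spots add, which reproduces the fluorescence staircase of sequential
compound fusion. Spots are truncated at the field edge without wrap-around.
Additive Gaussian noise (default SD 2 a.u., i.e. SNR 10) is applied last and
frames are clipped at zero.

**Geometry and defaults.** All generator geometry is in μm; pixels appear
only at render time (pixel i sits at i × `pixel_size_um`). The default
recording is a 50×50 μm field at 0.25 μm/pixel, 240 frames at 5 s — a
20-minute stimulation, the standard glucose-challenge protocol. Cell
interiors are dark (20 a.u.) against the bright SRB bath (100 a.u.).

**Cell masks.** When requested, cells are a Voronoi partition of uniformly
seeded centres (one per ~`cell_diameter_um`² = 100 μm²), with a 0.5 μm
extracellular boundary band (label 0) between cells where the bath dye sits;
events are then placed only on cell footprints by rejection sampling.

**Randomness.** One root seed is split (`numpy.random.SeedSequence.spawn`)
into independent sub-streams for cell geometry, event positions, event times
and pixel noise, so changing the noise level cannot move the events.
Identical parameters give bit-identical output.

**GTT and calcium forward models.** Synthetic GTT curves rise linearly from
fasting to a peak (default at 30 min) and relax exponentially back toward
fasting; the default sampling schedule is 0/15/30/45/60/90/120 min.
Synthetic calcium traces hold a baseline, relax exponentially toward a peak
after the stimulus, and are converted to Fura-2 ratio units through the
exact inverse of the Grynkiewicz calibration, with optional Gaussian noise
added in ratio units (where photon noise lives), so the analysis-side
conversion round-trips exactly at zero noise.

## Event detection

Dye entry is an abrupt persistent step, so the detector works on the
frame-to-frame difference of spatially smoothed frames (Gaussian,
`smoothing_um` = 0.3 μm).

- **Noise model.** The noise SD of the difference stack is estimated per
  pixel as the temporal median absolute deviation (× 1.4826), which is
  robust to the sparse event steps and captures the elevated variance of
  border pixels under reflective smoothing. Because the temporal MAD of a
  short recording is itself noisy while the true noise field varies slowly,
  the SD map is spatially smoothed (Gaussian, 3 px).
- **Threshold.** A pixel is a candidate when its difference exceeds
  `diff_threshold_sd` × its local SD. The default of 6 is chosen so the
  family-wise false-alarm expectation over an entire ~10⁷-sample difference
  stack is well below one event per recording. A small positive floor
  (10⁻⁶ of the dynamic range) keeps the threshold meaningful on noise-free
  movies, where the MAD vanishes.
- **Peaks.** Candidates are reduced to regional maxima with prominence of at
  least 6 global SDs (grey-scale h-maxima), which rejects noise bumps riding
  the suprathreshold shoulder of a bright spot; simultaneous peaks closer
  than `min_separation_um` (default 1 μm) are merged, keeping the brighter
  (exact ties: the earlier row-major maximum).
- **Localisation.** Positions are refined to the intensity-weighted centroid
  of the positive difference in a window of ± 2 × `smoothing_um`; the event
  time is frame_index × frame interval, with the step assigned to the later
  frame of the differenced pair. The reported amplitude is the raw 3×3-mean
  intensity step at the peak.
- **Sites.** Events are grouped into fusion sites greedily in time order: an
  event joins the nearest existing site within `site_radius_um` (default
  1 μm) — repeated fusion at that site — or founds a new one.
- **Size.** Event size is the FWHM of the radially averaged post-minus-pre
  intensity increase (3 frames each side), with the apex read from the
  centre pixel and the half-maximum crossing interpolated between 1-pixel
  radial bins. Events too close to the field edge for a full profile, or
  whose increase does not clear 3 noise SDs, are flagged (size `None`).

Two fusions at one site that land in the same frame interval closer than
`min_separation_um` are physically one step in the difference image and are
reported as one event; detector validation therefore quotes recall and
precision on unclustered scenes (where coincidences are negligible) and
treats clustered scenes with the spatial statistics below.

## Neighborhood statistic and compound classification

For each event the window count is the number of events — the focal event
included — inside an axis-aligned square of area `window_area_um2` (default
4 μm², side 2 μm) centred on it, pooled over the whole recording, with
boundary-inclusive membership (|Δx| ≤ side/2 and |Δy| ≤ side/2). The area
statement does not fix a shape; a disc of equal area is available
(`window_shape="disc"`) for sensitivity analysis, and an exclusive-focal
convention (`include_focal=False`) is likewise exposed because published
tail percentages do not state which convention was used. An event is
classified compound when its count is at least `compound_threshold`
(default 7), else primary. `tail_frequency(profile, k)` is the fraction of
events with count ≥ k; at k = threshold it equals the compound fraction by
definition. Counts are computed with a k-d tree under the Chebyshev metric
(square window) and agree exactly with the brute-force all-pairs rule; no
edge correction is applied — events near the field border simply have
truncated windows.

**Known bias of the windowed rule.** On mixtures of primary events and
clusters, the estimated compound fraction is very slightly above the
generative compound fraction (≈ +0.002 absolute at the default validation
mixture): a primary event that happens to fall inside a cluster's window
genuinely has ≥ 7 co-windowed granules and is labelled compound. This is a
property of the classification rule, not an estimator defect; recovery is
exact on pure-cluster scenes.

## Staging

GTT AUC is the total trapezoidal area (baseline included) of glucose vs
time in mmol/l × min — exact for piecewise-linear curves and additive over
splits. Stages: AUC < 1,600 → 1; [1,600, 2,200) → 2; [2,200, 2,800) → 3;
≥ 2,800 → 4. The printed boundaries overlap at the endpoints, so each
boundary is assigned to the higher-numbered stage (half-open intervals,
lower bound inclusive upward). Fasting blood glucose is the time-0 sample.

## Calcium

Concentration = K_d · β · (R − R_min)/(R_max − R), strictly increasing on
[R_min, R_max) with a pole at R_max; ratios outside the range raise rather
than extrapolate. K_d defaults to 224 nmol/l (Fura-2 at physiological
temperature); R_min, R_max and β are instrument-specific and must be
supplied. The response summary takes the baseline as the mean converted
concentration over a caller-chosen window before the stimulus and the peak
as the single maximum sample after it (no smoothing by default; an optional
centred moving average is available). At a ratio-noise SD of 0.01 the
baseline estimator's bias is far below 1 nmol/l because the calibration is
locally nearly linear at resting calcium.

## Group statistics

Secretion is normalised as 100 × secreted/content (%), scale-invariant by
construction. Two-group comparisons use the classical pooled-variance
two-tailed unpaired t test (df = n_a + n_b − 2) with significance at
p < 0.05; Welch's unequal-variance form is behind a flag, and no
multiple-testing correction is applied. Two constant equal samples return
t = 0, p = 1; constant samples with unequal means raise (no sampling
variability to test against). The spider summary rescales each variable's
group mean and SEM by a stated per-variable reference maximum; the AUC is
inverted (1 − AUC/5,000 mmol/l × min) so that a healthier, lower AUC plots
larger, and the ribbon half-width SEM/reference is unaffected by the flip.

## Validation sizes

The test suite and the acceptance script size their simulations to run on a
single CPU in minutes: detector performance uses 20 seeded 50×50 μm,
240-frame movies at SNR 10 (≈ 1,000 events total); point-process and
recovery properties use 100–200 seeds of event lists without rendering;
oracle agreement uses 100 random patterns of up to 500 events.

## What the synthetic data does and does not show

The generator reproduces the features the analysis relies on — abrupt
persistent punctate steps, additive staircases at compound sites, Poisson
vs clustered spatial structure, dark cells on a bright bath — but not
optical blur beyond a Gaussian spot, photobleaching, focus drift, cell
movement, the z-extent of a two-photon volume, or autofluorescence
structure. Passing tests therefore demonstrate the correctness of the
algorithms under the stated model, not detector performance on real islet
recordings; thresholds (`diff_threshold_sd`, `min_separation_um`,
`site_radius_um`) should be re-examined on real data where the noise is not
white and spots are not Gaussian.

## Limitations

- Detection is 2-D and frame-differencing based: events dimmer than the
  prominence requirement, or pairs fusing simultaneously within the merge
  radius, are not resolved.
- Event amplitudes in the generator are constant; real granule fusion shows
  an amplitude/size distribution that is only summarised here by the FWHM
  measurement.
- The neighborhood statistic pools all events of a recording; no temporal
  windowing of "co-occurrence" is attempted.
- Stage classification applies fixed AUC boundaries; it does not model
  glucose kinetics or insulin sensitivity.
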