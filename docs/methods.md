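# Methods

This note records the models, estimators, numeric choices and limitations
behind `centrotrack`, in the order the pipeline runs.

## Conventions and calibration

Images are `(frame, row, col)` arrays of arbitrary nonnegative intensity
units; the loader never rescales them. Positions are `(x, y)` with
`x = col * pixel_size`, `y = row * pixel_size`; all distances are reported
in micrometers and all rates in µm/min (velocimetry) or µm/s (comets).
The default pixel size is 0.1426 µm — the confocal calibration the
analyses were designed around — and the chemokine-source direction is an
explicit movie attribute (`+y` by default) rather than an assumption about
image orientation. Channel roles (`centriole`, `polarity`, `reference`,
`cells`, …) are explicit labels, never inferred from page order, because
real acquisitions mix marker combinations.

## Synthetic movies

Each generator is a pure function of its parameters and one seed, and
returns ground truth sufficient to score the downstream stage without
touching pixels.

- **Centriole pairs.** Two Gaussian puncta (isotropic PSF, σ = 0.2 µm by
  default, matching the diffraction scale at the default pixel size; the
  acquisitions themselves do not constrain it). Inter-centriole distance is
  0.8 µm by default — within the 0.5–1 µm cohesion range observed in
  persistently migrating cells — held constant until a scripted fracture
  onset, then piecewise-linear: growing at the scripted rate (µm/min,
  matching the reported micrometers-per-minute scale of separation
  velocities) and shrinking at the same rate after an optional repair
  frame. Piecewise-linear kinetics are the simplest model consistent with
  reporting a single separation-velocity scalar.
- **Noise.** Poisson shot noise on signal + background plus additive
  Gaussian read noise; SNR is defined as peak signal amplitude over
  read-noise σ. The puncta SNR of real acquisitions is not known; SNR 5–10
  is used as a conservative test range.
- **Polarity cells.** A rectangular cell translating along +y with a linear
  reporter ramp achieving the requested front/back ratio and a uniform
  reference channel. A rectangle makes the projection density along the
  migration axis uniform, so the binned ratios have an exact closed form:
  with front/back ratio r, bin k of n has normalized ratio
  `(1 + (r−1)(2k+1)/(2n)) · 2/(1+r)`.
- **FRAP.** Five 1-s pre-bleach frames by default; post-bleach ROI mean
  follows `f0 + m(1−f0)(1 − 2^(−t/t½))` on a background pedestal with a
  constant reference ROI.
- **Drift.** Frames are windows into one large static texture sampled at a
  moving origin, so integer shifts are exact crops and sub-pixel shifts are
  bilinear samples recorded exactly.
- **Vessels.** Rasterized line segments; ground-truth cell distances are
  exhaustive nearest-vessel-pixel searches — deliberately a different
  algorithm from the distance transform they validate.

What the generators do **not** emulate: cell-shape realism, acquisition
photobleaching (outside FRAP), sub-cellular background structure, 3D
effects, or detector artifacts. Passing the synthetic validation therefore
demonstrates correctness of the estimators under the stated noise model,
not robustness to every property of real movies.

## Spot detection and pair linking

Detection filters each frame with a scale-normalized Laplacian of Gaussian
tuned to the expected punctum diameter (0.65 µm default, the comet-detector
setting reused for centrioles) and keeps local maxima above a quality
threshold. The per-movie automatic threshold is 8 robust σ (MAD) of the
first frame's LoG response — a stand-in for an interactively adjusted
threshold. Sub-pixel refinement is an intensity-weighted centroid in a
recentered window of half-width ≈ diameter/2 (3 iterations, window minimum
subtracted); the tight window keeps the partner centriole of a cohesive
pair out of the weights. Measured accuracy: ≈ 0.09 px RMS noiseless,
≈ 0.2 px at SNR 10. Diameters under 2 px are rejected as under-resolved.

Linking maintains two identities A/B. Per frame, the assignment of (up to
four) candidate spots minimizing summed displacement wins; exact ties are
broken by spot quality rank. A missing identity carries its last position
as memory for up to `gap_size` frames (3 by default, the published linker
setting, with 25 µm maximum distance); longer gaps terminate the track at
the last observation. Missing frames are omitted from the distance series,
never interpolated. More than four persistent candidates raise an
ambiguous-cell error rather than guessing.

## Fracture metrics

The 1.5-µm threshold is applied inclusively (d ≥ 1.5 µm is fractured):
the published wording mixes "above 1.5 µm" and "1.5 µm apart", and the
category scheme places 1.5 µm in "near", which the inclusive rule matches.
Category boundaries printed as 1.49/2.99/4.99 are treated as display
rounding of half-open intervals with inclusive lower edges. The cell-level
call requires ≥ 2 fractured time points, counted anywhere in the series
(the criterion says "time points", not consecutive frames).

Separation velocity is the maximum over 3-sample sliding windows of
Δd/Δt after onset (starting one sample before the threshold crossing so
the rise is covered). The series is first smoothed with a centered 3-point
moving average: a window maximum is an extreme-value statistic, and
unsmoothed localization noise would bias it upward by several tenths of a
µm/min at SNR 5; the smoothing leaves a monotone linear rise unchanged
away from its endpoints. The published velocity has no defined estimator;
this one recovers scripted 2 µm/min rates within ±0.1 µm/min at SNR 5.

Repair requires the distance to fall back below threshold and stay there
for ≥ 3 frames (sustained re-cohesion, guarding against localization
flicker); a series ending during an unconfirmed re-cohesion run is
censored; an isolated dip followed by re-separation counts as
non-repaired. Junction decision time runs from first entry of the cell
reference point into the junction polygon to the first frame after its
final exit (re-entrant excursions extend the "during" phase); a track
ending inside the junction yields a lower bound. Whether the biological
clock should instead start at the first protrusion split is unknowable
from the data model here; entry-based timing is the declared definition.

## Intensity measurements

Line profiles sample bilinearly at a uniform step (0.1 µm default) along a
5-µm segment. Normalization divides by the single pooled mean of the first
and last four samples; the published "first and last four … respectively"
is ambiguous between pooled and per-end normalization, so per-end is
available behind `pooled=False`. The two-ROI intactness ratio uses
pixel-center membership in 0.35-µm disks and always divides by the larger
mean, so it lies in (0, 1]; overlapping ROIs warn rather than fail, and a
nonpositive ROI mean is an error. FRAP curves are background-subtracted,
divided by the in-cell reference, and rescaled to unit pre-bleach mean
(single-reference normalization, no whole-cell double normalization). The
recovery fit `plateau − (plateau − f0)·e^(−kt)` is an explicit extension —
recovery was published as curves, not statistics — and reports
t½ = ln 2 / k and mobile fraction (plateau − f0)/(1 − f0); flat curves
return mobile fraction 0, non-recovering fits raise.

## Polarity profiling

Pixels within 1.5 µm of any centriole ("1.5-µm area" read as a disk of
radius 1.5 µm) are excluded for the entire analysis, including the
normalization mean, which is computed per cell per channel over all time
points of the included pixels only. Projections onto the per-frame
migration direction are rescaled to [0, 1] by the full-mask extent along
the axis (the cell length), binned into 50 or 2 equal segments, and the
per-bin mean-reporter / mean-reference ratio is averaged first within and
then across time points. Empty bins stay missing and are never imputed.
The migration direction is the cell-centroid displacement smoothed over 3
frames — the published procedure relied on sustained chemotactic movement
without defining an axis estimator. Cells observed in fewer than 6 frames
are rejected by default (matching ≥ 30 min at 5-min intervals).
Segmentation is upstream: masks are inputs; an Otsu helper exists for
convenience but is not part of the contract.

## Velocimetry

Background correction subtracts the pixelwise temporal mean and clips
negatives (correlation on signed residuals is unstable for sparse scenes).
Size filtering removes 8-connected components outside the inclusive
cell-size band. "Optimal overlap" between consecutive frames is
operationalized as maximal Pearson correlation of the overlapping region
over integer shifts within a 25-px search radius, ties broken toward the
smaller shift to avoid drift inflation on featureless frames; optional
parabolic interpolation of the correlation surface refines to sub-pixel
(≤ 0.02 px error on scripted 0.5-px shifts). Phase correlation is
available as an alternative registration path. Chemotactic velocity is the
y-displacement toward the declared source × pixel size / frame interval.
Particle filtering is applied after background correction; the original
tool's ordering is unstated.

## Vessel proximity

The distance map is the exact Euclidean distance transform of the
non-vessel region, scaled to µm; it matches brute-force nearest-pixel
search exactly. Cells are reduced to centroids with nearest-pixel lookup
by default; a per-pixel mode reports the distance distribution over all
supra-threshold cell pixels instead. Binarization thresholds are inputs —
the original analysis set them manually.

## Determinism and problem sizes

Every stage is deterministic given (inputs, config, seed); the run log
contains config, seed and version only, so identical runs are
byte-identical. The validation cohort uses 100 cells (50 scripted
fractures) of 40 frames at 96×96 px and SNR 5 — large enough for stable
sensitivity/specificity estimates while keeping the whole validation suite
under a minute on one CPU.

## Known limitations

- The tracker assumes one cell with ≤ 4 candidate spots per frame; crowded
  fields need upstream cell cropping.
- The linker is greedy frame-to-frame; it does not revise past
  assignments, so prolonged crossings of two centrioles can swap
  identities (the distance series is unaffected by relabeling).
- Velocimetry measures bulk population drift, not per-cell tracks.
- The published population figures cannot be reproduced here: the raw
  movies are unavailable, so validation is against synthetic ground truth
  and the printed numeric rules.
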