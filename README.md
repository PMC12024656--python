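# centrotrack

Quantification of **centrosome fracturing** and related phenotypes in
time-lapse movies of migrating cells.

The centrosome — a pair of centrioles embedded in pericentriolar material —
is the main microtubule-organizing center of motile immune cells. When a
cell navigates complex environments (path junctions, dense collagen,
obstacle fields), mechanical forces can stretch the centriole pair and, if
cohesion fails, fracture it into two independently moving centrioles.
`centrotrack` implements the image-quantification pipeline for this
phenotype and its companion measurements, end to end, validated against
synthetic movies with known ground truth:

- **Centriole-pair tracking** — LoG spot detection with sub-pixel centroid
  refinement, two-identity nearest-neighbour linking with gap closing, and
  inter-centriole distance series *d(t)* in micrometers.
- **Fracture metrics** — per-frame categories (dendritic-cell scheme:
  close [0, 1.5), near [1.5, 3.5), short-distance separated [3.5, 5),
  long-distance separated [5, ∞) µm; fibroblast scheme: close / near /
  far with bounds 1.5 and 3 µm); a cell is *fractured* when d ≥ 1.5 µm at
  ≥ 2 time points; breakage frequency, fracture onset, peak separation
  velocity (µm/min), maximal separation, repair outcome
  (repaired / non-repaired / censored), and junction decision time.
- **Intensity quantification** — 5-µm line profiles along the centriolar
  axis normalized to the mean of the first and last four samples; the
  intact-centrosome ratio of two 0.35-µm circular ROIs (higher value as
  divisor); FRAP background subtraction, reference normalization and
  single-exponential recovery fits (half-time, mobile fraction).
- **Polarity profiling** — back-to-front reporter/reference ratio
  (e.g. PH-Akt over CETN2) in 50 or 2 length-normalized segments along the
  migration axis, excluding a 1.5-µm disk around each centriole, normalized
  per cell over all time points, with fractured/intact stratification.
- **Bulk velocimetry** — temporal-mean background correction, cell-size
  particle filtering, overlap-optimizing displacement between consecutive
  frames (normalized cross-correlation, optional sub-pixel refinement), and
  chemotactic velocity from the y-displacement toward the chemokine source.
- **Vessel proximity** — Euclidean distance transform of a lymphatic-vessel
  mask, per-cell nearest-vessel distances and inside/outside counts.
- **Synthetic data** — deterministic generators for every input: puncta
  pairs with scripted fracture kinetics, polarity-gradient cells, FRAP
  series, drifting textures and vessel scenes, each with exact ground truth.

## Worked example

Track a synthetic dendritic cell whose centriole pair fractures at frame 10
(2 µm/min separation) and re-coheses after frame 20, imaged at SNR 8 with
a 15-s frame interval:

```python
import centrotrack as ct

movie, truth = ct.make_centriole_movie(
    n_frames=40, frame_interval=15.0, fracture=(10, 2.0, 20),
    snr=8, seed=42, shape=(96, 96),
)
track = ct.track_centriole_pair(movie)
series = ct.distance_series(track)            # (time s, distance um)
report = ct.analyze_series(series[:, 0], series[:, 1])
print(f"fractured:           {report.fractured}")
print(f"onset frame:         {report.onset_frame}")
print(f"separation velocity: {report.separation_velocity:.2f} um/min")
print(f"maximal separation:  {report.max_separation:.2f} um")
print(f"repair outcome:      {report.repair}")
```

prints

```
fractured:           True
onset frame:         12
separation velocity: 2.09 um/min
maximal separation:  5.76 um
repair outcome:      repaired
```

The cell is called fractured at frame 12 — the first frame the measured
distance reaches the 1.5-µm threshold, two frames after the scripted onset
because the pair starts at 0.8 µm and needs 0.7 µm of separation to cross
it. The recovered peak velocity (2.09 µm/min) matches the scripted
2 µm/min, the maximal separation agrees with the scripted peak (5.80 µm)
within the localization error, and the sustained return below 1.5 µm is
classified as a repair.

The same analyses are available from the shell:

```sh
centrotrack synth --kind centriole --fracture "10,2.0,20" --seed 42 --out data/
centrotrack fracture --movie data/movie.tif --out results/
```

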