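# Methods

`tipkit` quantifies polarized tip growth of root hairs from time-lapse
microscopy: tip position and growth kinetics, bleach-corrected tip-signal
variability, a tiled image-cross-correlation statistic for cytoskeleton
dynamics, a linear-feature detector for actin filaments, membrane/cytosol
recruitment ratios, and axial intensity distributions relative to the
apex.  Because live-cell recordings cannot be regenerated, every stage is
validated by parameter recovery on synthetic movies whose generative
parameters are known exactly.

## The synthetic movie generator

The generator renders a root hair as a straight tube (stadium shape: a
rectangle capped by a hemisphere of the tube radius) whose tip advances
along a configurable axis at

    v(t) = v0 * (1 + a * sin(2*pi*t / tau))        [µm/min]

with closed-form cumulative displacement, so the per-frame true tip
position is known analytically.  Rasterization places pixel centers at
`(i+0.5) * pixel_size` and anti-aliases by 2×2 supersampling; geometric
ground truth is therefore sub-pixel exact.  Default calibration is
0.2 µm/pixel (a 63× objective with 2× binning).

Rendering modes:

* **DIC-like** — signed edge relief: the directional derivative of the
  smoothed cell coverage along a 45°-offset shear direction, scaled to a
  configurable amplitude on a mid-gray background.  Like real DIC, the
  outline loses contrast where the edge runs parallel to the shear
  direction; the tracker must cope with that gap.
* **fluorescence** — the cell interior carries a sum of Gaussian axial
  components anchored at the *moving* apex (`(distance, amplitude,
  sigma)` triplets) on a uniform in-cell baseline (default 20% of the
  component amplitude), multiplied by first-order photobleaching
  `exp(-k_bleach * t)` and an optional sinusoidal amplitude modulation
  `1 + m*sin(2*pi*t/T)` of the tip signal.
* **membrane ring** — the outermost 0.4 µm of the cell carries
  `pm_cs_ratio` times the interior intensity; the apex advances as in the
  growth modes.
* **AR(1) texture** — per pixel `X_t = sqrt(lam)*S + sqrt(1-lam)*Z_t`
  with `S` a fixed standard-normal field and `Z` an AR(1) chain of
  coefficient `rho` with unit marginal variance.  The expected Pearson
  correlation between frames `Delta` apart is exactly
  `lam + (1-lam)*rho**Delta`: a single-exponential decay with
  `y0 = 1`, plateau `lam`, and decay constant `K = -ln(rho)` per frame.
  This is the analytic oracle for the dynamics statistic.
* **filament stills** — anti-aliased bright line segments with flat
  (butt) end caps, so the rendered extent equals the recorded
  ground-truth length.

Camera noise is additive Gaussian with a floor at zero (Poisson
optionally on top).  Noise levels quoted as SNR mean (signal amplitude) /
(noise SD): the DIC edge amplitude for DIC movies, the brightest axial
component for fluorescence, the cytosol level for membrane-ring movies.
Identical seed and parameters give bit-identical movies.

What the generator does *not* emulate: optical PSF and depth sectioning,
curved or branching hair morphologies, spatially varying background,
stage drift, and intensity textures inside the cell other than the axial
profile.  Passing recovery tests therefore demonstrates correctness of
the estimators' geometry and numerics under idealized image formation,
not robustness to every artifact of real microscopy.

## Tip tracking

Per frame:

1. **Segmentation by relative contrast.** The frame is smoothed
   (Gaussian, sigma 1 px) and a local standard-deviation filter (radius
   3 px) is divided by the local mean plus a floor (15% of the 99th
   intensity percentile).  Dividing by the local mean makes one Otsu
   threshold work on both DIC relief and fluorescence movies with strong
   axial brightness gradients.  The thresholded outline is closed
   morphologically (radius 10 px, enough to bridge the DIC shear-gap),
   the entry border is closed, holes are filled, and the filled region is
   eroded by the std-filter radius to undo the outward spread of the
   contrast response.  The largest component touching the entry border is
   the cell.  If fewer than 90% of frames segment this way, segmentation
   is retried on a centered 3-frame rolling mean (the apex moves well
   under a pixel per frame in low-SNR fluorescence protocols); the
   variant with more valid frames wins.  Frames that still fail are
   flagged invalid, never interpolated.
2. **Axis.** Principal component of the foreground pixels, re-fit on the
   shank only (pixels more than 1.2 widths behind the apex, when that
   slab is itself elongated), oriented tip→base.  The apex's transverse
   position is taken on the centerline; its axial position is the
   extremal foreground projection.
3. **Sub-pixel refinement.** The intensity profile along the tip ray is
   either a step (fluorescence: interior level → background) or a
   symmetric bump (DIC relief): the boundary is the outermost half-level
   crossing, or the parabolic peak, respectively.  The step/bump decision
   is made once per movie by majority vote across frames — a single
   tilted ray crossing an interior structure must not flip the model.

Positions are median-filtered over 3 frames before rate computation (raw
positions retained); the first and last positions stay raw because a
truncated median window pulls them inward and shortens the total
displacement by about one frame's growth.  Two quality controls flag
frames invalid rather than repairing them: a configurable jump limit
(2 µm per frame interval), and a trajectory-consistency check that
rejects up to three positions lying more than 0.35 µm from the linear
interpolation of their valid neighbours — a monotone mid-size
segmentation error passes both the jump limit and the running median,
and a single such frame can inflate the maximum-rate statistic by tens
of percent through the interval difference.

Growth series: cumulative apex displacement projected on the mean axis,
differenced at the requested interval (µm/min).  Growth cessation is the
first time after which the rate stays below 0.1 µm/min for at least
10 min.  Both all-interval and growing-only mean rates are reported.

Measured accuracy on synthetic movies: apex error ≤ 0.75 px
(fluorescence, noise-free), ~1 px (DIC; the residual is transverse and
traces to the shear gap); mean-rate recovery within 2% for rates
0.5–2 µm/min at SNR ≥ 10; oscillatory peak-rate recovery within 5%
(finite 30-s interval averaging attenuates the true peak by ~1.6%).

## Tip fluorescence

* **Dark-frame subtraction** clamps at zero.
* **Bleach correction** fits `ln(raw) = ln A - k t` by ordinary least
  squares over all frames (no robust trimming) and divides the fitted
  decay out; the corrected series is dimensionless with mean ≈ 1.
* **Coefficient of variation** uses the sample (n−1) standard deviation
  over the mean.  CV is scale-invariant and, after bleach correction,
  invariant to any imposed global exponential decay (checked to 1e-6).
* **Tip CV** averages intensity in a circular ROI of radius 2 µm
  (configurable; the radius is recorded in output metadata) centered on
  the axis one radius behind the apex, clipped to the segmented cell.

### PM/CS recruitment ratio

The apical membrane is modelled as the circular cap of radius w/2
centered on the axis half a width behind the apex (w = hair width,
estimated from the transverse extent of the segmented shank).  The PM
sampling arc is restricted to the central half of the hair width
(|transverse offset| ≤ w/4, i.e. polar angle within ±30° of the apex).

Radial intensity profiles across the membrane are averaged over the arc
and over all frames, and fit with a four-parameter edge model: cytosol
plateau, a membrane band of assumed width 0.4 µm ending at the cell
boundary, background zero, all blurred by a Gaussian of fitted width
(the effective PSF plus pixel kernel).  This calibrates the boundary
position and blur once per cell.  Each frame's membrane intensity then
comes from a two-parameter *linear* fit of that frame's radial profile
to the frozen model — which recovers the band's true level rather than a
point sample attenuated by partial volume, and is unbiased for dim
membranes (ratio < 1), where peak-picking would lock onto the cytosol.
The cytosol intensity is the mean bilinear sample 0.5 µm behind the
membrane line (the reported protocols vary between 0.4 and 0.5 µm; the
offset is a parameter).  The per-cell ratio is the mean of per-frame
PM/CS ratios.  Noise-free recovery error is ≤ 0.5% across ratios
0.8–2.0; cohorts at ratios 1.01 vs 0.93 (n = 33 vs 27, SNR 10) are
recovered within 0.01 and separate at p < 1e-4.

## Actin dynamics (cross-correlation decay)

The movie is tiled into 6×6 µm² squares on two interleaved grids
displaced by 3 µm (partial border tiles discarded, duplicates removed).
For each tile the zero-lag spatial Pearson correlation is computed
between **all** frame pairs — implemented via the Gram matrix of the
per-frame standardized pixel vectors, so all T(T−1)/2 pairs cost one
matrix product — and averaged per interval length up to Δmax = T/2
(configurable; this keeps at least T/2 pairs per interval).  The decay
curve is fit by bounded nonlinear least squares with

    y = (y0 - p) * exp(-K x) + p,   K >= 0,  y0, p in [-1, 1]

initialized from the first point, the last-quartile mean, and the 1/e
crossing.  Non-converging tiles are flagged and excluded.  The 10 tiles
with the largest span (y0 − p) represent the cell (ties broken by tile
origin, row then column); the per-cell statistic is their mean K, and
genotypes are compared with a two-sided Mann-Whitney test (exact for
small tie-free samples).  Activity maps render hue ∝ K and brightness ∝
span over each tile's central region, with selected tiles outlined.

Pearson correlation is affine-invariant per frame pair, so no bleach
correction is applied before tiling.  On AR(1) textures the fitted K
matches −ln(rho) and the plateau matches lambda within 3 Monte-Carlo
standard errors over 20 seeds for rho ∈ {0.8, 0.9, 0.95}, lambda ∈
{0, 0.3, 0.6} at 120 frames / 1 s intervals; the validation uses
96×96 px regions because the nonlinear fit acquires a small downward K
bias (∼0.8% at rho = 0.8) when correlation-estimate noise grows at
smaller region sizes — at 6×6 µm (30 px) tiles on real protocols this
bias is dwarfed by biological variation between tiles.

## Actin organization (filament detection)

The image is smoothed (Gaussian, sigma 1.5 px) and probed at each pixel
with four anti-aliased centered line kernels (0°, 45°, 90°, 135°; length
7 px); the response is the best orientation's mean minus the mean of the
other three, clipped at zero, followed by non-maximum suppression across
the winning orientation's normal at 1 and 2 px (the 2-px test removes
the parallel side-lobe responses thick filaments produce).  The response
is binarized with the iterative intermeans (isodata) threshold computed
over its positive support, thinned to a 1-px skeleton, spur-pruned
(≤4 px side branches), split at branch points, and collinear pieces
across ≤3 px gaps are stitched (the winning orientation alternates along
lines oblique to all probes).  Path length sums 1-px orthogonal and
√2-px diagonal steps; segments shorter than 1 µm are discarded (gated on
the raw skeleton length).  For straight paths (RMS transverse residual
≤ 1 px) the reported length is refined to the distance between half-max
crossings of the intensity profile along the fitted line, which undoes
both the probe's end smear and skeleton grid quantization.

Known limitation: a four-orientation probe bank has an angular
selectivity dip midway between probe orientations; with the default
smoothing the detector is validated for filaments within ±8° of the
probe angles (single-filament recovery: exact count and length within
2 px over 40 random seeds, noise-free and at SNR 20).  Thin filaments
20° off every probe can fragment.  Crossing filaments are split at the
junction, as the skeleton-based protocol dictates.

The front-most-filament distance is the per-frame minimum Euclidean
distance from any segment pixel to the tracked apex (NaN when no
filament is present).

## Axial profiles, kymographs, tip windows

Per frame the hair is resampled on a grid aligned with that frame's axis
(bilinear interpolation): axial bins of one pixel from the apex toward
the base, transverse samples across 80% of the hair width, averaged over
samples falling inside the (1-px-eroded) segmented cell.  Each frame's
profile is normalized to max = 100% and profiles are averaged over
frames (average-then-normalize is available behind a flag).  The peak
distance is the bin of the global maximum; plateau ties resolve to the
tied-bin centroid with a flag.  Near the apex (within half a width) the
profile is geometrically depressed — transverse averaging over the dome
mixes a shrinking cell cross-section with boundary blur; peak estimates
for markers ≥ 1 µm behind the apex are unaffected (recovery within
0.3 µm at SNR 5 with 60-frame averages, for peaks at 2–7 µm).

Two-channel landmark analysis interpolates the first crossing of two
normalized profiles linearly between bins, and locates the extremum of
the B/A ratio over bins where A exceeds a 5% floor.

Kymographs sample along a lab-frame-fixed line (the axis of the last
valid frame), one row per frame, so a growing tip traces a curve; the
per-frame tip projection onto the line is returned for overlay and slope
checks (slope matches the growth-series mean rate within 2%).  The
tip-window trace averages the cell region within a fixed axial depth
(default 2 µm) of the moving apex.

## Statistics

Group comparisons are two-sided: classic pooled-variance t-test (Welch
optional, off by default to match the era's conventions), one-way ANOVA
with Tukey HSD for all pairs, and the Mann-Whitney rank-sum test (exact
enumeration when both groups have ≤ 8 tie-free values, normal
approximation with tie correction otherwise).  Degenerate comparisons
(identical constant groups) report p = 1 with a flag.  The exact
rank-sum path is cross-checked in the tests against brute-force
enumeration of all label assignments, the t statistic against the
textbook formula, and the ANOVA's type-I error against a null
simulation (rejection rate ≈ 5% at alpha = 0.05).

## Numerical and validation choices

* Coordinates are (row, col) pixel indices; physical positions are
  `(index + 0.5) * pixel_size`, distances in µm, rates in µm/min,
  bleach and decay rates in 1/s.
* Sub-pixel sampling is bilinear everywhere (never pixel rounding).
* Problem sizes in the validation suite: growth movies of 30–60 frames
  at 30 s, fluorescence protocols of 36–60 frames at 5 s, AR(1) oracles
  of 120 frames at 1 s, 20-seed Monte-Carlo sweeps.  These match the
  acquisition protocols the measurements were designed for.
* Determinism: all synthetic data flows through `numpy.random
  .default_rng(seed)`; identical configuration gives byte-identical
  CSV outputs.
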