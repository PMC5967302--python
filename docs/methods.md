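# Methods

This note documents the models behind each analysis, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical choices that affect results.

## Syncytium morphometry

A microscopic field is a labelled segmentation mask (one integer per
MyHC-stained object), a table of nuclei centroids, and optionally the MyHC
channel itself. Per object we measure the pixel-count area (converted to
μm² via `pixel_size²`), the centroid, and the aspect ratio of the
moment-matched ellipse: the ellipse whose second central moments equal
those of the filled region, with axis lengths `4·√λ` for the eigenvalues λ
of the normalized covariance (the standard image-moments convention, as
implemented by `skimage.measure.regionprops`). Nuclei are assigned to
objects by nearest-pixel containment of their centroid — deterministic and
exact for point centroids; centroids on background count toward the field
total but no object.

Three field-level percentages follow by direct counting:

* **fusion index** = 100 × (nuclei in MyHC⁺ objects with ≥ *N* nuclei) /
  (nuclei in all MyHC⁺ objects), with *N* a dataset-dependent threshold
  (16 by default; 26 and 50 are used for per-syncytium variants);
* **elongation index** = 100 × (area of MyHC⁺ objects with aspect ratio
  ≥ 3) / (total MyHC⁺ area);
* **differentiation index** = 100 × (nuclei in MyHC⁺ objects) / (all
  nuclei in the field).

A zero denominator is an error, not a zero — an index over no MyHC⁺
nuclei is undefined. Whether the elongation index should include
mononucleated MyHC⁺ objects is ambiguous; the default includes every
MyHC⁺ object, with `elongation_multinucleate_only` as the switch.
Indices are reported per field; `aggregate_fields` offers opt-in
unweighted averaging.

**Known limitation.** Aspect ratios of rasterized thin ellipses carry a
quantization bias that is largest (~2% at a 10-pixel minor semi-axis)
when the ellipse is exactly axis-aligned, because row-width rounding
errors then correlate along entire rows. At generic orientations and
minor semi-axes ≥ 12 px the error stays below ~2%, which is the tolerance
used throughout.

## Cortical enrichment score

The cell boundary is the sub-pixel 0.5-level contour of the hole-filled
mask. Anchors are spaced every `rectangle_spacing` (default 2 μm) along
the contour arclength; the inward normal at each anchor is the gradient of
the Euclidean distance transform, smoothed with a 1.5-px Gaussian to
remove grid quantization in the direction estimate, normalized, and
orientation-checked by probing the mask one pixel inward. From each anchor
an intensity profile runs inward to `profile_depth` (12 μm) in
`profile_step` (0.2 μm) increments, each sample being the mean of bilinear
reads across the rectangle width (1 μm); reads outside the mask are
excluded rather than zero-filled so thin regions are not diluted.

Per rectangle: peak = maximum profile sample within 0–5 μm of the edge
(no sub-pixel peak interpolation — the simplest reproducible reading);
mean = mean profile value within 2–7 μm inward *of the peak position*.
The cortex/cytoplasm ratio is the average of peak/mean over all valid
rectangles; rectangles whose bands fall outside the mask, or whose
mean-band value is non-positive, are excluded and counted.

The rectangle width, spacing, and profile geometry are not dictated by the
measurement's definition; the defaults were fixed once so that the 0–5 μm
and 2–7 μm bands fit inside the profile with margin, and all are
config-overridable. The score is invariant to multiplicative intensity
scaling but **not** to additive offsets: background must be subtracted
upstream if present.

## Optical-trap mechanics

A trapped bead sits in a harmonic potential `V(x) = k x²/2`. Equipartition
assigns `k_B T/2` per degree of freedom, so `k = k_B T / ⟨x²⟩` with
`⟨x²⟩` the position variance about the mean. The default variance
estimator is a Gaussian fit to the position histogram (Freedman–Diaconis
bins, nonlinear least squares on bin centres), matching the experimental
procedure; `direct_variance` (unbiased sample variance) is the
cross-check, and the Gaussian fit falls back to it with a warning on
non-convergence. Units: pN, μm, s, K; `k_B = 1.380649×10⁻⁵ pN·μm/K`.
Room temperature defaults to 296.15 K (23 °C) and is overridable.

Tether force-extension curves combine a bead track and a stage track:
stage positions are interpolated onto bead timestamps, the pull onset is
the last still sample before stage motion, bead deviation is zeroed
against its mean over the 0.5 s before onset (when a ramp starts
immediately there is no pre-pull data and the track is trusted as
deviation from the trap centre), force is `F = k·Δx`, and the extension
axis is stage displacement from onset (the controlled quantity; tether
extension `stage − Δx` is available via a flag).

**First-linear-region fit.** The fit window grows from the pull onset one
sample at a time and stops at the first structural break — a sample whose
deviation from the running prefix fit exceeds `n_sigma` (default 5) times
the prefix RMS residual, with a tiny absolute floor so that noiseless data
stop exactly at a kink. Among scanned prefixes, the longest with
`R² ≥ r2_min` (default 0.98) and at least `min_points` (default 10)
samples is fitted by ordinary least squares. The residual-break criterion
exists because R² alone cannot localize the end of the linear part: adding
one off-trend point after n collinear points changes R² by only O(1/n³),
so any pure-R² window rule overshoots a changepoint by many samples.
Conversely, a low R² on a short noisy prefix does not abort the scan,
since R² of a genuinely linear noisy curve only rises as the window grows.

Conversion of tether force to membrane tension requires a bending-modulus
model that is deliberately out of scope; the analysis stops at tether
force and force-extension slope.

## Trace statistics

* **Δratio** — trace maximum minus the value at the reference time
  (default 60 s, resolved to the nearest sample; with the 10-s sampling
  of the imaging protocol this is on-grid). Non-negative by construction.
* **Basal level** — mean over a pre-stimulus window, default the first
  60 s (the protocol perfuses buffer for 2 min before agonist, so any
  window inside that is baseline; the exact window is not dictated and is
  config).
* **Relative peak current** — |peak(treated)|/|peak(control)| with the
  peak taken in the stated direction (inward = most negative sample).
* **Median time course** — per-timepoint median with the lower-median
  convention for even n (integer-stable on integer intensity data).
* **Positive fraction** — percentage strictly above a gate; the default
  gate is the 99th percentile of a negative-control population, the
  standard single-colour choice when no explicit gate is stated.
* **2^−ΔΔCt** — relative expression fold change; exactly halves per added
  sample-target cycle.

## Synthetic data

Generators emit the same primitives the analyses consume, plus ground
truth computed by direct counting from the generating parameters (never
from the emitted raster/track). All randomness flows from one integer
seed per spec; every generator is deterministic given (spec, seed).

* **Trapped bead** — exact Ornstein–Uhlenbeck discretization
  `x[n+1] = x[n]·e^(−dt/τ) + N(0, σ²(1−e^(−2dt/τ)))` with `τ = γ/k`,
  `σ² = k_B T/k`; exact at any step size, unlike an Euler update.
  Defaults are the recording conditions: k = 7.29 pN/μm, 1000 frames/s
  for 10 s, drag from Stokes' law (`γ = 6πηr`) for a 1.76-μm bead in
  water at 23 °C (η = 0.933 mPa·s), giving τ ≈ 2.1 ms. Camera motion
  blur from the 1-ms exposure is *not* modeled; at τ ≈ 2 ms it would
  bias a real calibration high by a few percent, so the simulated tracks
  are an idealization in this respect.
* **Tether pull** — stage ramp at 1 μm/s sampled every 10 ms against a
  series spring: `Δx = k_t/(k+k_t)·stage`, optional Gaussian position
  noise. The series-spring form is a stand-in (only the existence of a
  first linear part is asserted experimentally); its virtue is exact
  known slopes: force-vs-stage = `k·k_t/(k+k_t)`, force-vs-tether
  extension = `k_t`. Default k_t = 20 pN/μm, a plausible tether scale.
* **Syncytium fields** — filled rotated ellipses rasterized by
  pixel-centre test, one label each, pairwise non-overlapping (checked
  after rasterization); nuclei rejection-sampled inside a one-pixel-eroded
  mask with ±0.3 px jitter so containment is unambiguous; the MyHC channel
  puts `cell_level` on differentiated cells and background elsewhere,
  plus Gaussian noise. `sample_field_spec` draws random layouts with
  aspect ratios kept away from the threshold 3 ([1.2, 2.5] ∪ [3.5, 4.5])
  and minor semi-axes of 12–24 px so shape classification is well-posed.
* **Cortical images** — a bright band of `cortex_level` within
  `cortex_depth` (default 1.5 μm) of the mask edge by distance transform,
  `interior_level` inside, zero outside.
* **Fura2 traces** — baseline, then a saturating-exponential rise
  (optionally decaying) from the onset; samples every 10 s over 600 s
  with a 120-s baseline by default, mirroring the perfusion protocol.
* **Intensity populations** — two log-normal components about a decade
  apart, 20% positive by default.

What passing tests on these fixtures show — and what they do not: they
verify the *quantification* (counting, moments, band statistics,
calibration algebra, fit logic) exactly or to stated tolerance, but the
fixtures have no microscope PSF, no segmentation errors, no camera blur,
no cytometer spillover, and perfectly elliptical cells, so they say
nothing about upstream segmentation or instrument artefacts in real data.

## Pipeline

Tasks are described by a YAML config (`task`, `inputs`, `params`,
`seed`); validation fills documented defaults and rejects unknown keys
with their path before any computation. Outputs are CSV/JSON (images as
TIFF), plus a `manifest.json` with parameters, seed, package version and
SHA-256 checksums of every output; nothing time-dependent is written, so
identical (config, seed) reproduce byte-identical outputs. Logging goes
to stderr and `run.log` in the output directory.

## Problem sizes used in tests

The suite simulates 10⁴-frame calibration tracks (50 seeds), 100 random
five-cell fields of 320×320 px at 0.5 μm/px, 160×160-px cortical images,
and 500-sample tether ramps — sizes chosen so each fixture's Monte-Carlo
or rasterization error is comfortably below the assertion tolerance it
feeds.
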