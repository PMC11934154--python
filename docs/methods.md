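# Methods

## Signal model and processing chain

A dynamic-OCT acquisition holds one B-scan cross-section fixed and
re-images it N times at frame rate f_s (defaults: N = 512, f_s = 56 Hz,
2.53 µm isotropic pixels). Sub-resolution motion of scatterers inside a
pixel modulates its speckle intensity; the fluctuation spectrum of that
modulation is the contrast. Because cellular motion of interest lies
below 20 Hz, any frame rate above the Shannon bound of 40 Hz suffices;
at 56 Hz the measurable band is 0–28 Hz.

Processing per cross-section:

1. **Frame normalisation.** Each frame is divided by its own spatial
   mean. This removes frame-to-frame source/gain instability and bulk
   intensity drift but no spatial registration is attempted.
2. **DC removal.** Each pixel's temporal mean is subtracted before
   spectral estimation. Without this the zero-frequency term dominates
   every spectrum and all centroids collapse toward 0 Hz; removing the
   whole-series mean once (rather than per Welch segment) keeps the
   estimator a plain windowed periodogram average of the fluctuation
   component.
3. **Welch PSD per pixel** (`scipy.signal.welch`): Hann window,
   segment length 256, 50 % overlap, one-sided density scaling. With
   512 frames this averages 3 segments and gives a 0.22 Hz grid over
   0–28 Hz. All parameters are exposed (`WelchParams`); segment length
   must not exceed the series length. For short test series the
   defaults clip to the series length.
4. **Moment maps.** fmean is the PSD-weighted centroid, fstd the
   PSD-weighted standard deviation, STD the per-pixel temporal standard
   deviation with 1/N (population) normalisation. A pixel with zero
   total fluctuation power gets fmean = fstd = 0 by convention; such
   pixels fall outside any intensity mask in practice. Negative
   spectral variance from floating cancellation is clamped at −1e−9
   relative; anything larger raises.
5. **Smoothing.** The fmean raster only is Gaussian-filtered with
   σ = 3 truncated to a 3×3 kernel — deliberately the literal filter
   (a heavily truncated, near-uniform 3×3 average) rather than a
   "corrected" wider kernel — with replicate border padding. fstd and
   STD stay raw.
6. **Tiling.** `compute_dynamics_maps(n_chunks=1|4|9)` processes the
   image in spatial tiles (the memory/parallelism layout for large
   volumes). Pixels are spectrally independent and the FFT backend is
   deterministic per 1-D transform, so any tiling returns bitwise
   identical maps; this is asserted in tests.

## Segmentation

- **Spheroid mask**: Otsu (default) or an absolute threshold on the
  temporal-mean intensity raster; largest 8-connected component, holes
  filled, small components discarded. Otsu always finds *some* split,
  so a contrast guard (foreground mean ≥ 1.5× background mean) rejects
  cross-sections that contain no spheroid at all instead of
  hallucinating a mask from a uniform noise plane.
- **Viability split**: viable = fmean < threshold, necrotic = fmean ≥
  threshold inside the spheroid. The default threshold, 10.5 Hz, is
  the midpoint between the viable band's upper limit (9.5 Hz) and the
  necrotic band's lower limit (11.5 Hz). Ties go to necrotic; the
  threshold lies strictly between the observed bands so the choice is
  immaterial on realistic data.
- **Edge-artifact rim rule**: the refractive-index step at the
  spheroid/medium interface produces a broadband specular ring that
  the split mislabels necrotic. Any necrotic 8-connected component
  that touches the spheroid boundary and lies entirely within
  rim_width (default 5) pixels of it (Euclidean distance transform) is
  reclassified as edge artifact. Reclassified pixels rejoin the viable
  mask by default (`reassign="viable"`, since the interface cells are
  in fact highly viable) or can be excluded from both classes
  (`reassign="exclude"`, which lowers the reported viability). The
  rule is idempotent, and deep necrotic lobes that merely reach the
  boundary are untouched because they extend beyond the rim.
- **Viability** = viable pixels / spheroid pixels, computed after the
  rim correction by default.

## Quantification

Per-mask average fmean is the plain arithmetic mean over mask pixels.
Depth profiles report class-wise averages per y plane, with depth 0 at
the first plane whose spheroid mask is non-empty and rows emitted only
for non-empty classes. Longitudinal tables are tidy per-(sample, day)
records; duplicates are an error. Confidence bands across replicate
phantoms are mean ± 1.96·SE matched on (depth, class). Output CSVs are
deliberately ANOVA-ready, but no between-method statistics are
computed here (there is no reference modality in a synthetic setting).

## Pseudo-color rendering

Hue = fmean clamped to [8, 13] Hz and scaled linearly to [0, 0.66]
(red → blue); saturation = 1/fstd; value = STD. The source material for
this mapping does not define how 1/fstd and STD reach the [0, 1] HSV
ranges, so both are normalised by a robust percentile (default 99th,
configurable) and clipped — resistant to hot pixels, and no fixed
scale is any less arbitrary. fstd = 0 maps to saturation 0 (gray)
rather than infinity. Channels are monotone in their inputs and the
RGB output is clamped to [0, 1] for any input.

## Phantom generator

The generator emulates the *statistical* contrast the pipeline
measures, not OCT physics: no coherent speckle formation, attenuation,
refraction or decorrelation dynamics. A pixel in layer L is

    I(t) = R_L · s · (1 + x_L(t)),

with R_L the layer reflectivity (viable 1.0, necrotic 0.8), s a static
per-pixel gamma-distributed speckle texture (mean 1, sd 0.3), and
x_L(t) a zero-mean fluctuation. Background pixels carry a rectified
Gaussian noise floor (sd 0.03) — backscatter intensity is nonnegative.
Two fluctuation processes:

- `band_tones`: equal-amplitude random-phase cosines on the
  full-series DFT grid inside a band, total RMS =
  `fluctuation_amplitude`, plus an optional flat white floor. Its PSD
  is a row of equal spikes, so the expected centroid is essentially the
  band midpoint — crisp for recovery tests.
- `ar1_plus_white`: an AR(1) (Lorentzian spectrum, low-frequency
  weighted, coefficient 0.8 by default) plus white floor — closer to
  real speckle dynamics.

Defaults place the viable shell at band 8–9.5 Hz with amplitude 0.3
and the necrotic core at 11.5–13 Hz with amplitude 0.1 (strong/slow vs
weak/fast, the observed contrast), each with a 0.02 white floor. The
optional edge ring is a 3-pixel boundary shell of elevated
reflectivity (1.5×) carrying pure broadband fluctuation (RMS 0.25),
which lands near the 14 Hz flat-spectrum centroid and therefore gets
mislabelled necrotic — exactly the failure mode the rim rule corrects.

`expected_fmean` evaluates the closed-form process PSD on a stated
frequency grid and takes the centroid; it is the analytic oracle the
recovery tests compare against. Geometry is an axis-aligned ellipsoid
(outer and core radii in µm); the ground-truth label raster (0
background, 1 viable, 2 necrotic, 3 ring) ships with every phantom.
(spec, seed) fully determines the output bitwise; volume and
growth-series generation derive per-plane / per-day child seeds from
a `SeedSequence` so runs are reproducible and below 2³¹.

## Problem sizes

The full-scale configuration (660×660 pixels, 512 frames) processes in
seconds-to-minutes per cross-section. The test and reproduction
scripts use reduced phantoms — 128×128 pixels with 256 frames
(Welch segment 128) for recovery and edge-correction checks, 96×96
with 128 frames for growth series — chosen because the per-layer pixel
counts (thousands) already average the centroid estimate well below
the 0.3 Hz recovery tolerance, so larger rasters only add runtime, not
information.

## Known limitations

- The phantom's spectra are stipulated, not biophysical: passing
  recovery tests shows the estimator and segmentation logic are
  correct, not that real necrotic tissue sits at 11.5–13 Hz.
- No bulk-motion registration; only per-frame mean normalisation.
  Real data with sample drift would decorrelate spectra.
- The rim rule assumes the interface artifact is a thin
  boundary-confined component; a necrotic region genuinely touching
  the surface and confined to the rim would be misassigned.
- Welch parameters are package defaults, not measured properties of
  any instrument; changing segment length shifts the frequency grid
  and slightly moves band-edge centroids.
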