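# doct — dynamic-OCT viability mapping for 3D cell spheroids

`doct` quantifies site-dependent cell viability inside three-dimensional
cell spheroids (e.g. hepatocyte spheroids) from **dynamic optical
coherence tomography**: a time series of OCT B-scans of one cross-section,
acquired fast enough that sub-resolution cellular motion modulates each
pixel's speckle intensity. Viable cells fluctuate strongly at low
frequency; necrotic cells and background noise fluctuate weakly and
broadband. Mapping each pixel's fluctuation spectrum therefore separates
the viable outer shell from the necrotic core without stains or
sectioning — which matters to anyone using spheroids for drug toxicity
screening, where an undetected necrotic core distorts the readout.

It is intended for OCT / biophotonics researchers and tissue-engineering
labs who have (or want to prototype against) repeated-B-scan intensity
stacks. Since no public datasets of this kind exist, the package includes
a synthetic phantom generator with analytic spectral oracles, so the whole
pipeline is testable end to end.

## Method

For each pixel's intensity time series *I*(t) (frames normalised by their
spatial mean, per-pixel temporal mean removed), the one-sided Welch power
spectral density *P*(f) is estimated, and reduced to three co-registered
maps:

- mean frequency (spectral centroid):
  f<sub>mean</sub> = Σᵢ (Pᵢ / Σⱼ Pⱼ) · fᵢ
- frequency standard deviation (bandwidth):
  f<sub>std</sub> = sqrt( Σᵢ wᵢ fᵢ² − (Σᵢ wᵢ fᵢ)² ),  wᵢ = Pᵢ / Σⱼ Pⱼ
- temporal amplitude: STD = sqrt( (1/N) Σᵢ (I(tᵢ) − Ī)² )

A light Gaussian filter (σ = 3 on a 3×3 support) removes aberrant pixels
from the f<sub>mean</sub> map. Segmentation thresholds f<sub>mean</sub> at
10.5 Hz — the midpoint between the observed viable band (8–9.5 Hz) and
necrotic band (11.5–13 Hz) — inside an intensity-based spheroid mask, and a
5-pixel rim rule reclassifies the spurious high-frequency ring caused by the
refractive-index step at the spheroid/medium interface. **Viability** is the
viable-pixel fraction of the spheroid cross-section. For display, the three
maps go to HSV (hue = f<sub>mean</sub>, 8→13 Hz mapped to 0→0.66; saturation
= 1/f<sub>std</sub>; value = STD), so viable tissue renders red-yellow and
necrotic tissue blue-green.

## Worked example

```python
from doct import (PhantomSpec, WelchParams, compute_dynamics_maps,
                  generate_phantom, segment_cross_section)

spec = PhantomSpec(shape=(128, 128), outer_radii=(140.0, 140.0),
                   core_radii=(70.0, 70.0), n_frames=256, seed=1)
stack, labels, expected = generate_phantom(spec)
maps = compute_dynamics_maps(stack, WelchParams(segment_length=128))
for label, name in ((1, "viable"), (2, "necrotic")):
    print(name, round(maps.fmean[labels == label].mean(), 2),
          "Hz (analytic", round(expected[name], 2), "Hz)")
seg = segment_cross_section(maps.fmean, stack.values.mean(axis=0))
print("viability", round(seg.viability, 3))
```

prints

```
viable 8.89 Hz (analytic 8.77 Hz)
necrotic 12.24 Hz (analytic 12.32 Hz)
viability 0.748
```

The measured layer centroids land inside their generating bands
(8–9.5 Hz and 11.5–13 Hz), and the viability matches the geometric area
ratio 1 − (r<sub>core</sub>/R)² = 0.75 of the phantom to sub-percent
accuracy. The scripts in `examples/` walk through each capability
(mapping, segmentation with edge correction, pseudo-color rendering,
3D depth profiles, longitudinal monitoring).

## Command line

```bash
doct simulate --config phantom.yaml --out phantom_dir     # synthetic stack + ground truth
doct process phantom_dir/stack.tif --config cfg.yaml --out maps
doct segment maps --threshold 10.5 --rim 5 --out seg
doct render maps --mask seg/mask_spheroid.tif --out color.tif
doct quantify maps seg --out quant.csv
doct profile volume_dir --out profile.csv
```

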