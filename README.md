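# hsdepth

Depth reconstruction of absorbing inclusions in turbid media from a
**single hyperspectral image**.

## The problem

Optical tomography of turbid media (tissue, tissue phantoms) normally
needs interferometry (OCT) or ultrasound detection (photoacoustics).
Yet a plain hyperspectral reflectance cube already encodes depth: an
absorbing inclusion (an ink-filled channel, a blood vessel) darkens the
surface reflectance more the closer it lies to the surface, while its
extra scattering brightens it.  In the spectral range where the
inclusion's absorber is strong (blue/green for a red-transparent ink)
absorption wins; where it is transparent (red) scattering wins.  In
between there can be a wavelength where the two effects cancel — the
**iso-point** λ_iso — at which the surface reflectance is independent
of the inclusion's cover depth.

Referencing an absorption-band intensity to the iso-point band gives a
per-pixel depth statistic

```
d_i = 1 − I(λ_abs) / I(λ_iso)
```

(λ_abs ≈ λ_iso − 25 nm by default, mirroring the classic 550/575 nm
pair) which is zero over inclusion-free substrate and varies
monotonically with cover depth: linearly for shallow inclusions, then
decaying exponentially once the iso-point degrades at depth.

`hsdepth` implements the complete analysis — white-reference
normalization, iso-point detection by per-band regression of
reflectance on depth, whole-image d_i mapping, and piecewise
linear/exponential calibration with depth inversion — together with a
synthetic phantom generator that reproduces the cancellation mechanism
with exact ground truth, so every stage is verifiable without measured
phantom data.

It is aimed at researchers in biomedical optics and spectral imaging
who want to prototype or validate depth-resolved band-ratio analyses.

## Worked example

```python
import hsdepth as h
from hsdepth.preprocess import median_filter, normalize, band_average

# a 10%-ink analogue scene: 2 mm channel, cover depth ramping 0→10 mm
substrate, inclusion, acq = h.canonical_scene("absorbing", seed=1)
raw, reference, truth = h.simulate_cube(substrate, inclusion, acq)

cube, band_mask = normalize(median_filter(raw), median_filter(reference))
cube = band_average(cube, 20)            # ≈6 nm window, < 10 nm resolution

result = h.IsoPointModel.from_cube(cube, truth).fit()
print(result.summary())
```

prints (95×500×950 cube, 1 % noise):

```
Iso-point detection
----------------------------------------
status            : found
iso wavelength    : 574.82 nm
crossing band idx : 605
bands             : 950
slope range       : [-1.318e-03, 1.079e-03] /mm
```

The detected iso-point sits 0.33 nm from the generator's analytic
crossover at 575.15 nm.  Continuing to the depth map and calibration:

```python
dmap = h.depth_parameter_map(cube, result.iso_wavelength - 25,
                             result.iso_wavelength)
profile = h.extract_profile(dmap, truth, axis="along").labelled()
fit = h.DepthCalibration(profile).fit(inner=0.6)   # central 60 %
print(fit.summary())
```

reports the regime breakpoint, the linear slope and the exponential
decay rate with their explained variances; `fit.predict_depth(d_i)`
inverts the calibration (round-trip RMSE ≈ 0.007 mm in the linear
regime on noise-free scenes).

The same pipeline runs from the shell:

```sh
hsdepth run --scene absorbing --seed 1 --out out/
hsdepth simulate --scene clear --out water/   # no absorber → no iso-point
```

A water-filled channel (`clear`) yields status `absent` and the
pipeline skips depth mapping with an explanatory message; the
boundary-concentration scene, where the spectra just touch, yields
`boundary`.

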