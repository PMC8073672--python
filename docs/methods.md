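# Methods

## The measurement model

A pushbroom hyperspectral camera images a turbid slab containing a
single cylindrical inclusion (diameter 2 mm) whose cover depth *d*
ramps affinely along the scan axis.  The analysis rests on two opposing
depth effects on the surface diffuse reflectance: in the spectral range
where the inclusion's absorber is strong, the inclusion darkens the
surface more the shallower it lies; in the absorber-transparent range
its extra scattering (and boundary reflection) brightens the surface
more the shallower it lies.  Where the two effects balance — the
iso-point wavelength λ_iso — reflectance is depth-invariant, and the
band ratio

d_i = 1 − I(λ_abs) / I(λ_iso)

is a depth statistic: zero over inclusion-free substrate (after
baseline handling), monotone in cover depth over the inclusion.

## Synthetic phantom forward model

No closed forward model accompanies the measurement idea, so the
generator adopts the simplest perturbation model that realises the
mechanism with an analytic iso-point:

R(λ, d) = R0(λ) · [ 1 + C(λ) · W(λ, d) · p(r, d) ]

* **Background** R0(λ): diffusion-approximation total reflectance of a
  semi-infinite medium, R0 = a′ / (1 + 2k(1−a′) + (1 + 2k/3)√(3(1−a′)))
  with transport albedo a′ = µs′/(µs′+µa) and internal-reflection
  parameter k = (1+r_d)/(1−r_d), r_d = −1.44 n⁻² + 0.710 n⁻¹ + 0.668 +
  0.0636 n.  The closed form has testable limits (R0→1 as µa→0, R0→0 as
  µs′→0) and is monotone in a′.
* **Contrast** C(λ) = c_s − c_a·ε(λ): a wavelength-flat scattering
  brightening c_s opposed by the absorber-band darkening.  The
  extinction ε(λ) is flat at its peak value for λ ≤ peak (a red
  -transparent ink absorbs strongly throughout the blue and green) and
  falls as a Gaussian on the red flank (half the peak at peak+FWHM/2).
  The one-sided drop gives C exactly one zero crossing inside the
  camera's range; a symmetric band would cross twice, which contradicts
  the physics being emulated.  The analytic iso-point recorded in the
  ground truth is the root of C, found by bisection; it exists iff C
  changes sign, so the water scene (concentration 0, C > 0 everywhere)
  has none and the boundary-concentration scene (min C = 0, no sign
  change) has none either.
* **Depth kernel** W(λ, d) = exp(−2 µ_eff d), µ_eff = √(3µa(µa+µs′)) of
  the substrate: the perturbation is attenuated on the way in and out.
* **Lateral footprint** p(r, d): the 2 mm box profile convolved with a
  Gaussian of σ(d) = σ0 + σ1·d (closed form via erf), so deep
  inclusions appear wider and dimmer than their physical size — the
  blur that makes the inclusion "look larger than it is".

Raw frames are illumination × reflectance, convolved along wavelength
with a Gaussian spectral PSF, with multiplicative Gaussian noise; the
white-standard reference frame uses the same model at reflectance 0.99.

### Defaults (the simulated study conditions)

| parameter | default | rationale |
|---|---|---|
| cube size | 95 × 500 × 950 | native acquisition geometry |
| pixel pitch | 260 µm (x) × 43 µm (y) | native optics |
| spectral range / sampling | 407–670 nm, ≈0.277 nm/band | 950 bands; prints as 0.3 nm |
| spectral PSF FWHM | 10 nm | effective resolution of the instrument |
| substrate µa / µs′ | 0.02 mm⁻¹ / 1.2·(λ/500 nm)^−1.2 mm⁻¹ | deliberately below tissue so depth effects span ~1 cm |
| refractive index | 1.5 | polyurethane-like |
| absorber | peak 530 nm, FWHM 100 nm, 0.88 mm⁻¹ per unit conc. | ~100 nm-wide red-transparent band |
| contrasts c_s, c_a | 0.05, 1.0 mm | place the 10 %-conc. iso-point at 575.15 nm |
| scene concentrations | 0 (clear), 0.0568 (boundary), 0.10 (absorbing) | no / touching / genuine crossing |
| depth ramp | 0 → 10 mm along the 21.5 mm scan extent | covers both regimes |
| blur σ0, σ1 | 0.3 mm, 0.5 per mm depth | grows with depth; exact law is a free choice |
| noise | 1 % relative, multiplicative | strong-source regime; shot noise omitted |

The substrate absorption is spectrally flat: it keeps the water scene's
depth-sensitivity spectrum bounded away from zero at every band, which
makes the absent/boundary classification well-posed.

## Pipeline estimators

**Preprocessing** is fixed as 5×5 spatial median (both cube and
reference, reflect borders) → division by the reference spectrum
(bands where the reference falls below 10⁻⁶ of its own maximum are
masked) → 20-band running mean (≈6 nm at the native sampling, below
the 10 nm resolution, so no spectral information is lost).  Even
windows use the symmetric length-21 kernel with half-weight endpoints
so a linear spectrum is reproduced exactly at interior bands.

**Iso-point detection** regresses each band's reflectance on inclusion
depth (ordinary least squares over centre-line samples) and classifies
the slope spectrum.  A band is significantly depth-sensitive when its
slope exceeds both 2 standard errors and 10 % of the spectrum's peak
slope magnitude; the second, relative criterion suppresses spurious
sign flips of near-zero slopes under noise, and both are invariant to
global rescaling of the spectra.  Exactly one sign change among the
significant bands ⇒ `found`, with λ_iso interpolated linearly between
the bracketing bands; a dip inside the tolerance band without a sign
change ⇒ `boundary`; otherwise `absent`.  Several well-separated sign
changes raise an ambiguity error carrying all candidates.

**Depth map**: per-pixel d_i at the bands nearest λ_abs (default
λ_iso − 25 nm) and λ_iso (nearest-band ties go to the longer
wavelength), minus the median d_i over the background region (pixels
more than three inclusion diameters from the mask), so inclusion-free
substrate sits at zero by construction.

**Profile extraction** averages d_i over the full mask width per scan
line (cover depth is constant across the width, so this uses the
feature's whole support to suppress noise) and bins consecutive lines
so the along-axis spacing matches the 260 µm across-axis pitch — the
43 µm line pitch oversamples the millimetre-scale ramp more than
twentyfold, so binning is depth-faithful.

**Calibration** grid-searches the regime breakpoint over the sample
depths: OLS linear fit at or below each candidate, three-parameter
exponential A·exp(−rate·d)+c above it (deterministic initialisation:
offset from the decay-end value, amplitude/rate from a log-linear
regression; no random restarts), minimum total SSE wins, ties to the
smaller breakpoint.  The degenerate all-linear and all-exponential
candidates compete on the same footing, so the piecewise SSE never
exceeds either single-model fit.  On ideal noise-free profiles the
single exponential often wins outright — the generator's decay is
globally near-exponential and only approximately linear near the
surface; the two-regime structure emerges on noisy data, where the
deep, signal-starved tail is better served by its own branch.  When no
linear branch is identified, the "linear regime" used for round-trip
evaluation is the shallowest third of the calibrated range.

**Inversion** solves the linear branch in closed form and the
exponential branch by logarithm, preferring the linear branch where
both apply.  The mapping is surjective (akin to y = x²): beyond the
breakpoint a parameter value may be reachable from both branches, and
values unreachable by either are signalled (scalar: exception; array:
masked), never silently dropped.

## Numerical choices and degenerate inputs

* Reference-masked or nonpositive iso-band pixels are flagged invalid
  in the map, not dropped.
* r² is defined as 1 − SSE/SST, with r² ≡ 0 for zero-variance data
  (slope-0 fit on constant data); it can be negative for
  worse-than-mean fits.
* A fitted exponential with rate < 10⁻⁸ is reported degenerate
  (amplitude and offset only jointly identified).
* Breakpoint SSE ties are resolved at 10⁻⁹ relative tolerance toward
  the smaller breakpoint.
* Depth-map sentinel: −1 outside the inclusion; the boolean mask is
  authoritative (depth 0 is meaningful — a surface-touching inclusion).
* All randomness flows from a single integer seed per scene.

## What the synthetic scenes do and do not show

The generator reproduces the *mechanism* — opposing absorption and
scattering contrasts whose influence decays exponentially with depth,
an analytic iso-point, depth-growing lateral blur, multiplicative
noise — with exact ground truth, so tests verify the estimators
end-to-end.  It does not model photon-transport corrections beyond the
diffusion approximation, shot noise, keystone/smile distortion, rough
or curved surfaces, multiple inclusions, or chromophores with
structured spectra (e.g. haemoglobin's double peak).  Passing tests
therefore demonstrate correctness of the analysis given the stated
physics, not performance on measured phantom or in-vivo data; measured
explained-variance figures on physical phantoms (≈85 % full profile,
>95 % inner 60 %) are qualitative context the synthetic conditions
echo (≈94 % inner-60 % at 1 % noise) but do not reproduce.

## Problem sizes used in tests

Unit and property tests run on reduced scenes (31×160 pixels, 1 nm
band sampling) whose physics is identical; the end-to-end test and the
reproduction script run the native 95×500×950 geometry.  Oracle
equivalence is checked against naive per-pixel loop implementations on
100 random instances per operation.

## Known limitations

* The method needs ground-truth depth labels (or a user-supplied
  λ_iso) to detect the iso-point — on real data a calibration target
  or a priori wavelength is required.
* Single straight inclusion assumed by the profile extractor; dense or
  crossing inclusions would need unmixing, which is out of scope.
* The exponential regime's parameters are poorly conditioned at low
  SNR (the deep tail carries little signal); its per-branch r² is then
  small even when the piecewise fit as a whole explains most variance.
* Depth prediction beyond the breakpoint is branch-ambiguous by the
  surjectivity of the mapping.
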