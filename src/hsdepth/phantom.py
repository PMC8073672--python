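"""Synthetic turbid-phantom scene generator.

Emulates a pushbroom hyperspectral acquisition of a polyurethane-like
turbid slab containing a single cylindrical inclusion (2 mm diameter)
drilled diagonally, so that its cover depth ramps linearly along the
scan axis.  The inclusion carries a red-transparent Gaussian-band
absorber at configurable concentration plus a depth-independent
scattering brightening, which together produce the central phenomenon
the analysis pipeline detects: a crossover wavelength (*iso-point*)
where absorption-driven darkening and scattering-driven brightening of
the surface reflectance cancel, making that band insensitive to
inclusion depth.

Forward model (perturbation form)
---------------------------------
For a pixel whose inclusion cover depth is ``d`` the reflectance is ::

    R(λ) = R0(λ) * (1 + C(λ) * W(λ, d) * p(r, d))

with

* ``R0`` the diffusion-approximation background reflectance of the
  substrate (:func:`hsdepth.optics.background_reflectance`),
* ``C(λ) = c_s - c_a * ε(λ)`` the inclusion contrast: a flat scattering
  brightening ``c_s`` opposed by an absorber-band darkening,
* ``W(λ, d) = exp(-2 μ_eff(λ) d)`` the depth sensitivity kernel,
* ``p(r, d)`` the lateral footprint: the inclusion's 2 mm box profile
  convolved with a Gaussian whose width grows with depth, so deep
  inclusions appear wider and dimmer than their physical size.

The analytic iso-point is the root of ``C(λ)``; the generator records
it in the ground truth so detection can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq
from scipy.special import erf

from .cube import SpectralCube
from .errors import InvalidGeometryError
from .optics import (
    AbsorberSpec,
    MediumOptics,
    background_reflectance,
    effective_attenuation,
    extinction,
)

__all__ = [
    "InclusionGeometry",
    "AcquisitionSpec",
    "GroundTruth",
    "contrast",
    "analytic_iso_wavelength",
    "simulate_cube",
    "canonical_scene",
    "make_fixture_suite",
    "DEPTH_SENTINEL",
    "BOUNDARY_CONCENTRATION",
]

#: Depth-map value marking pixels with no inclusion underneath.  The
#: boolean mask is authoritative; the sentinel is negative because a
#: depth of exactly 0 (surface-touching inclusion) is meaningful.
DEPTH_SENTINEL = -1.0

#: Reflectance of the white standard used for the reference frame.
_R_STANDARD = 0.99

#: Ink concentration at which the contrast curve touches zero without
#: crossing (peak absorption darkening exactly balances the scattering
#: brightening): c_s / (c_a * peak_extinction) for the default specs.
BOUNDARY_CONCENTRATION = 0.05 / (1.0 * 0.88)


@dataclass(frozen=True)
class InclusionGeometry:
    """Cylindrical inclusion drilled through the slab.

    ``entry_point`` and ``exit_point`` are ``(x_mm, y_mm, depth_mm)``
    scene coordinates of the inclusion axis at its two ends; cover depth
    varies affinely between them along the in-plane axis.

    ``scatter_contrast`` (c_s) is the relative reflectance brightening
    from the inclusion's extra scattering / boundary reflection;
    ``absorption_contrast_gain`` (c_a, mm) converts the absorber's
    extinction (mm⁻¹) into a relative darkening.
    """

    diameter: float = 2.0
    entry_point: tuple[float, float, float] = (12.35, 0.0, 0.0)
    exit_point: tuple[float, float, float] = (12.35, 21.5, 10.0)
    absorber: AbsorberSpec = field(default_factory=AbsorberSpec)
    scatter_contrast: float = 0.05
    absorption_contrast_gain: float = 1.0
    blur_sigma0_mm: float = 0.3
    blur_sigma_per_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.scatter_contrast < 0 or self.absorption_contrast_gain < 0:
            raise ValueError("contrast amplitudes must be nonnegative")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Camera and sampling model of the pushbroom acquisition.

    Defaults reproduce the emulated instrument: 95×500 spatial pixels at
    260 µm × 43 µm pitch, 950 bands spanning 407–670 nm (≈0.3 nm per
    band) with an effective spectral resolution of about 10 nm, a flat
    illumination spectrum and 1 % relative multiplicative noise.
    """

    n_x: int = 95
    n_y: int = 500
    pixel_pitch_x_um: float = 260.0
    pixel_pitch_y_um: float = 43.0
    band_range_nm: tuple[float, float] = (407.0, 670.0)
    band_sampling_nm: float = (670.0 - 407.0) / 949.0
    spectral_psf_fwhm_nm: float = 10.0
    illumination_spectrum: Optional[np.ndarray] = None
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.band_range_nm
        if not lo < hi:
            raise ValueError("band_range_nm must satisfy low < high")
        if self.band_sampling_nm <= 0:
            raise ValueError("band_sampling_nm must be positive")
        if self.spectral_psf_fwhm_nm < self.band_sampling_nm:
            raise ValueError("spectral_psf_fwhm_nm must be >= band_sampling_nm")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")

    @property
    def wavelengths(self) -> np.ndarray:
        lo, hi = self.band_range_nm
        n_bands = int(round((hi - lo) / self.band_sampling_nm)) + 1
        return np.linspace(lo, hi, n_bands)

    @property
    def extent_mm(self) -> tuple[float, float]:
        return (
            self.n_x * self.pixel_pitch_x_um / 1000.0,
            self.n_y * self.pixel_pitch_y_um / 1000.0,
        )

    def pixel_positions_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinate vectors (x_mm, y_mm)."""
        px = self.pixel_pitch_x_um / 1000.0
        py = self.pixel_pitch_y_um / 1000.0
        return (np.arange(self.n_x) + 0.5) * px, (np.arange(self.n_y) + 0.5) * py


@dataclass
class GroundTruth:
    """Per-pixel truth recorded by the generator.

    ``depth_map`` holds the inclusion cover depth in mm, with
    :data:`DEPTH_SENTINEL` outside the inclusion; ``inclusion_mask`` is
    the authoritative indicator.  ``iso_wavelength_analytic`` is the
    root of the contrast curve ``C(λ)`` on the simulated band range, or
    ``None`` when ``C`` does not change sign.
    """

    depth_map: np.ndarray
    inclusion_mask: np.ndarray
    iso_wavelength_analytic: Optional[float]
    background_spectrum: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        nx, ny = self.depth_map.shape
        xi, yi = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        return pd.DataFrame(
            {
                "x": xi.ravel(),
                "y": yi.ravel(),
                "depth_mm": self.depth_map.ravel(),
                "in_inclusion": self.inclusion_mask.ravel().astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path, background_spectrum=None, iso_wavelength=None) -> "GroundTruth":
        df = pd.read_csv(path)
        nx = int(df["x"].max()) + 1
        ny = int(df["y"].max()) + 1
        depth = np.full((nx, ny), DEPTH_SENTINEL)
        mask = np.zeros((nx, ny), dtype=bool)
        depth[df["x"], df["y"]] = df["depth_mm"]
        mask[df["x"], df["y"]] = df["in_inclusion"].astype(bool)
        return GroundTruth(
            depth_map=depth,
            inclusion_mask=mask,
            iso_wavelength_analytic=iso_wavelength,
            background_spectrum=background_spectrum,
        )


def contrast(inclusion: InclusionGeometry, wavelength_nm) -> np.ndarray:
    """Inclusion contrast ``C(λ) = c_s - c_a ε(λ)`` (dimensionless).

    Positive where scattering brightening dominates (the inclusion
    appears brighter when closer to the surface), negative where
    absorber darkening dominates.
    """
    return inclusion.scatter_contrast - inclusion.absorption_contrast_gain * extinction(
        inclusion.absorber, wavelength_nm
    )


def analytic_iso_wavelength(
    inclusion: InclusionGeometry, band_range_nm: tuple[float, float]
) -> Optional[float]:
    """Root of the contrast curve on ``band_range_nm``, or None.

    ``None`` exactly when ``C(λ)`` has no sign change on the range —
    either the absorber is too weak (contrast positive everywhere,
    water-filled inclusion) or, at the boundary concentration, the
    curve touches zero without crossing.
    """
    lam = np.linspace(band_range_nm[0], band_range_nm[1], 2048)
    c = contrast(inclusion, lam)
    # a strict sign change is required: a curve that merely touches zero
    # (boundary concentration) has no iso-point
    sign_change = np.nonzero(c[:-1] * c[1:] < 0)[0]
    if len(sign_change) == 0:
        return None
    i = sign_change[0]
    return float(brentq(lambda w: float(contrast(inclusion, w)), lam[i], lam[i + 1]))


def _geometry_fields(
    inclusion: InclusionGeometry, acq: AcquisitionSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel (depth, perpendicular distance, inclusion mask)."""
    x0, y0, d0 = inclusion.entry_point
    x1, y1, d1 = inclusion.exit_point
    ex, ey = acq.extent_mm
    for px, py in ((x0, y0), (x1, y1)):
        if not (0.0 <= px <= ex and 0.0 <= py <= ey):
            raise InvalidGeometryError(
                f"inclusion axis point ({px}, {py}) mm outside scene {ex:.2f}×{ey:.2f} mm"
            )
    xs, ys = acq.pixel_positions_mm()
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    ax, ay = x1 - x0, y1 - y0
    length = np.hypot(ax, ay)
    if length == 0:
        raise InvalidGeometryError("inclusion entry and exit coincide in-plane")
    ux, uy = ax / length, ay / length
    s = ((X - x0) * ux + (Y - y0) * uy) / length
    r = -(X - x0) * uy + (Y - y0) * ux
    s = np.clip(s, 0.0, 1.0)
    depth = d0 + (d1 - d0) * s
    depth = np.maximum(depth, 0.0)
    mask = np.abs(r) <= inclusion.diameter / 2.0
    return depth, r, mask


def _lateral_profile(inclusion: InclusionGeometry, r: np.ndarray, depth: np.ndarray) -> np.ndarray:
    """Box profile of half-width a blurred with a depth-growing Gaussian.

    Closed form of boxcar ⊗ Gaussian:
    ``p(r) = ½ [erf((r+a)/(√2 σ)) − erf((r−a)/(√2 σ))]`` with
    ``σ(d) = σ0 + σ1 d``.  p ∈ [0, 1]; as σ → 0 it approaches the sharp
    2 mm footprint.
    """
    a = inclusion.diameter / 2.0
    sigma = inclusion.blur_sigma0_mm + inclusion.blur_sigma_per_mm * depth
    q = np.sqrt(2.0) * sigma
    return 0.5 * (erf((r + a) / q) - erf((r - a) / q))


def simulate_cube(
    substrate: MediumOptics,
    inclusion: Optional[InclusionGeometry],
    acq: AcquisitionSpec,
) -> tuple[SpectralCube, SpectralCube, GroundTruth]:
    """Render one synthetic acquisition.

    Returns ``(raw, reference_frame, truth)``: the raw intensity cube
    (illumination × reflectance, spectrally blurred, noisy), a white
    standard frame acquired under the same model, and the generator's
    ground truth.  Pass ``inclusion=None`` for an inclusion-free slab.
    All randomness derives from ``acq.seed``; ``acq.noise_sigma = 0``
    gives the deterministic noise-free cube.
    """
    lam = acq.wavelengths
    n_bands = len(lam)
    r0 = background_reflectance(substrate, lam).astype(np.float32)

    if inclusion is not None:
        depth, r_perp, mask = _geometry_fields(inclusion, acq)
        c_lam = contrast(inclusion, lam).astype(np.float32)
        mu_eff = effective_attenuation(substrate, lam)
        # W(λ, d): (n_x, n_y, n_bands), float32 to bound memory at full size
        w = np.exp(
            (-2.0 * depth[:, :, None] * mu_eff[None, None, :]).astype(np.float32)
        )
        p_lat = _lateral_profile(inclusion, r_perp, depth).astype(np.float32)
        reflectance = r0 * (1.0 + c_lam * w * p_lat[:, :, None])
        depth_map = np.where(mask, depth, DEPTH_SENTINEL)
        iso = analytic_iso_wavelength(inclusion, acq.band_range_nm)
    else:
        reflectance = np.broadcast_to(r0, (acq.n_x, acq.n_y, n_bands)).copy()
        depth_map = np.full((acq.n_x, acq.n_y), DEPTH_SENTINEL)
        mask = np.zeros((acq.n_x, acq.n_y), dtype=bool)
        iso = None

    illum = (
        np.ones(n_bands, dtype=np.float32)
        if acq.illumination_spectrum is None
        else np.asarray(acq.illumination_spectrum, dtype=np.float32)
    )
    if illum.shape != (n_bands,):
        raise ValueError("illumination_spectrum length must match the band count")

    sigma_bands = acq.spectral_psf_fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / acq.band_sampling_nm
    raw = illum * reflectance
    raw = gaussian_filter1d(raw, sigma_bands, axis=2, mode="nearest")
    ref = np.broadcast_to(illum * np.float32(_R_STANDARD), raw.shape).copy()

    rng = np.random.default_rng(acq.seed)
    if acq.noise_sigma > 0:
        raw = raw * (1.0 + acq.noise_sigma * rng.standard_normal(raw.shape, dtype=np.float32))
        ref = ref * (1.0 + acq.noise_sigma * rng.standard_normal(ref.shape, dtype=np.float32))

    meta = dict(pitch_x_um=acq.pixel_pitch_x_um, pitch_y_um=acq.pixel_pitch_y_um)
    truth = GroundTruth(
        depth_map=depth_map,
        inclusion_mask=mask,
        iso_wavelength_analytic=iso,
        background_spectrum=np.asarray(r0, dtype=float),
    )
    return (
        SpectralCube(raw, lam, **meta),
        SpectralCube(ref, lam, **meta),
        truth,
    )


_SCENES = {"clear": 0.0, "boundary": BOUNDARY_CONCENTRATION, "absorbing": 0.10}


def canonical_scene(
    kind: str = "absorbing",
    *,
    n_x: int = 95,
    n_y: int = 500,
    noise_sigma: float = 0.01,
    seed: int = 0,
    band_sampling_nm: Optional[float] = None,
) -> tuple[MediumOptics, Optional[InclusionGeometry], AcquisitionSpec]:
    """Component specs for one of the three canonical phantom scenes.

    ``kind`` selects the inclusion filling: ``"clear"`` (water, no
    absorber — no iso-point), ``"boundary"`` (absorption exactly
    balancing scattering at the band peak — spectra touch in one
    point), ``"absorbing"`` (strong ink — a genuine iso-point near
    575 nm), or ``"none"`` for an inclusion-free slab.
    """
    substrate = MediumOptics.power_law()
    acq_kwargs = dict(n_x=n_x, n_y=n_y, noise_sigma=noise_sigma, seed=seed)
    if band_sampling_nm is not None:
        acq_kwargs["band_sampling_nm"] = band_sampling_nm
    acq = AcquisitionSpec(**acq_kwargs)
    if kind == "none":
        return substrate, None, acq
    if kind not in _SCENES:
        raise ValueError(f"unknown scene kind {kind!r}; expected one of {sorted(_SCENES)} or 'none'")
    ex, ey = acq.extent_mm
    inclusion = InclusionGeometry(
        entry_point=(ex / 2.0, 0.0, 0.0),
        exit_point=(ex / 2.0, ey, 10.0),
        absorber=AbsorberSpec(concentration=_SCENES[kind]),
    )
    return substrate, inclusion, acq


def make_fixture_suite(seed: int, dest, **scene_kwargs) -> dict[str, dict[str, Path]]:
    """Write the three canonical scenes (ENVI cubes + truth CSV) to ``dest``.

    Deterministic given ``seed``: each scene uses a seed derived from it.
    Extra keyword arguments (e.g. ``n_x``, ``n_y``, ``noise_sigma``) are
    forwarded to :func:`canonical_scene`, allowing reduced-size suites.
    Returns a mapping scene name → written file paths.
    """
    from .envi import write_envi

    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    written: dict[str, dict[str, Path]] = {}
    for offset, kind in enumerate(("clear", "boundary", "absorbing")):
        substrate, inclusion, acq = canonical_scene(kind, seed=seed + offset, **scene_kwargs)
        raw, ref, truth = simulate_cube(substrate, inclusion, acq)
        base = dest / kind
        paths = {
            "cube": base.with_suffix(".raw"),
            "cube_header": base.with_suffix(".hdr"),
            "reference": Path(str(base) + "_reference.raw"),
            "truth": Path(str(base) + "_truth.csv"),
            "config": Path(str(base) + "_scene.cfg"),
        }
        write_envi(raw, paths["cube"])
        write_envi(ref, paths["reference"])
        truth.to_csv(paths["truth"])
        iso = truth.iso_wavelength_analytic
        conc = 0.0 if inclusion is None else inclusion.absorber.concentration
        paths["config"].write_text(
            f"scene = {kind}\n"
            f"seed = {acq.seed}\n"
            f"noise_sigma = {acq.noise_sigma}\n"
            f"concentration = {conc!r}\n"
            f"iso_wavelength_analytic = {'none' if iso is None else round(iso, 4)}\n"
        )
        written[kind] = paths
    return written
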