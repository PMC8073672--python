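"""Optical property models for the turbid phantom.

The phantom substrate and its inclusion are characterised by
wavelength-resolved absorption ``mu_a(λ)`` and reduced scattering
``mu_s'(λ)`` coefficients (mm⁻¹) plus a refractive index.  Two closed
forms derived from the diffusion approximation provide the forward
physics used by the simulator:

* :func:`background_reflectance` — total diffuse reflectance of a
  semi-infinite homogeneous medium under the diffusion approximation
  with an internal-reflection boundary parameter,
* :func:`sensitivity_kernel` — the exponential decay
  ``exp(-2 mu_eff d)`` of a deep perturbation's influence on surface
  reflectance, with ``mu_eff = sqrt(3 mu_a (mu_a + mu_s'))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "AbsorberSpec",
    "MediumOptics",
    "extinction",
    "background_reflectance",
    "effective_attenuation",
    "sensitivity_kernel",
    "internal_reflection_parameter",
]

_4LN2 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class AbsorberSpec:
    """Gaussian-band absorber (red-transparent ink analogue).

    The extinction curve is a single Gaussian in wavelength:
    ``eps(λ) = peak_extinction * concentration * exp(-4 ln2 (λ-peak)²/fwhm²)``.

    Parameters
    ----------
    peak_wavelength
        Band centre in nm.
    fwhm
        Full width at half maximum of the band, nm (> 0).
    peak_extinction
        Extinction at the band centre per unit concentration, mm⁻¹.
    concentration
        Dimensionless concentration fraction in [0, 1].
    """

    peak_wavelength: float = 530.0
    fwhm: float = 100.0
    peak_extinction: float = 0.88
    concentration: float = 0.10

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be nonnegative")
        if self.peak_extinction < 0:
            raise ValueError("peak_extinction must be nonnegative")


def extinction(absorber: AbsorberSpec, wavelength_nm) -> np.ndarray:
    """Extinction coefficient of ``absorber`` at ``wavelength_nm`` (mm⁻¹).

    The curve is flat at its peak value for wavelengths at or below the
    band centre (red ink absorbs strongly throughout the blue and
    green) and falls off as a Gaussian on the red flank, reaching half
    the peak at ``peak + fwhm/2`` and under 0.2 % of the peak beyond
    ``peak + 1.5 fwhm``.  This one-sided drop is what creates exactly
    one absorption-to-scattering crossover within the camera's range.
    """
    lam = np.asarray(wavelength_nm, dtype=float)
    x = np.maximum(lam - absorber.peak_wavelength, 0.0) / absorber.fwhm
    return absorber.peak_extinction * absorber.concentration * np.exp(-_4LN2 * x * x)


@dataclass(frozen=True)
class MediumOptics:
    """Wavelength-resolved optical properties of a turbid medium.

    ``mu_a`` and ``mu_s_reduced`` are callables mapping wavelength (nm,
    scalar or array) to coefficients in mm⁻¹.  Use
    :meth:`MediumOptics.power_law` for the common Mie-like
    ``a (λ/λ0)^(-b)`` scattering with constant absorption.
    """

    mu_a: Callable[[np.ndarray], np.ndarray]
    mu_s_reduced: Callable[[np.ndarray], np.ndarray]
    refractive_index: float = 1.5

    def __post_init__(self) -> None:
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")

    @staticmethod
    def power_law(
        mu_a: float = 0.02,
        scatter_amplitude: float = 1.2,
        scatter_exponent: float = 1.2,
        reference_wavelength: float = 500.0,
        refractive_index: float = 1.5,
    ) -> "MediumOptics":
        """Constant absorption + power-law reduced scattering.

        Defaults give coefficients deliberately below soft-tissue values
        (µa = 0.02 mm⁻¹, µs' ≈ 1.2 mm⁻¹ at 500 nm), so depth-dependent
        effects play out over a centimetre scale.
        """
        if mu_a < 0 or scatter_amplitude <= 0:
            raise ValueError("require mu_a >= 0 and scatter_amplitude > 0")
        return MediumOptics(
            mu_a=lambda lam, c=mu_a: np.full_like(np.asarray(lam, dtype=float), c),
            mu_s_reduced=lambda lam, a=scatter_amplitude, b=scatter_exponent, l0=reference_wavelength: a
            * (np.asarray(lam, dtype=float) / l0) ** (-b),
            refractive_index=refractive_index,
        )


def internal_reflection_parameter(refractive_index: float) -> float:
    """Boundary parameter ``k = (1+r_d)/(1-r_d)`` for a refractive mismatch.

    ``r_d`` is the standard empirical polynomial in the relative index
    ``n``: ``r_d = -1.44 n⁻² + 0.710 n⁻¹ + 0.668 + 0.0636 n``.
    For matched boundaries (n = 1) r_d ≈ 0 and k ≈ 1.
    """
    n = float(refractive_index)
    r_d = -1.44 * n**-2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_d) / (1.0 - r_d)


def background_reflectance(optics: MediumOptics, wavelength_nm) -> np.ndarray:
    """Diffuse reflectance R0(λ) of the semi-infinite substrate.

    Diffusion-approximation closed form in the transport albedo
    ``a' = mu_s'/(mu_s' + mu_a)``::

        R0 = a' / (1 + 2k(1-a') + (1 + 2k/3) sqrt(3(1-a')))

    with ``k`` from :func:`internal_reflection_parameter`.  Monotone
    increasing in ``a'``; R0 → 1 as absorption vanishes and R0 → 0 as
    scattering vanishes.
    """
    lam = np.asarray(wavelength_nm, dtype=float)
    mu_a = np.asarray(optics.mu_a(lam), dtype=float)
    mu_s = np.asarray(optics.mu_s_reduced(lam), dtype=float)
    total = mu_a + mu_s
    if np.any(total <= 0):
        raise ValueError("mu_a + mu_s_reduced must be positive at every wavelength")
    albedo = mu_s / total
    k = internal_reflection_parameter(optics.refractive_index)
    denom = 1.0 + 2.0 * k * (1.0 - albedo) + (1.0 + 2.0 * k / 3.0) * np.sqrt(3.0 * (1.0 - albedo))
    return albedo / denom


def effective_attenuation(optics: MediumOptics, wavelength_nm) -> np.ndarray:
    """``mu_eff(λ) = sqrt(3 mu_a (mu_a + mu_s'))`` in mm⁻¹."""
    lam = np.asarray(wavelength_nm, dtype=float)
    mu_a = np.asarray(optics.mu_a(lam), dtype=float)
    mu_s = np.asarray(optics.mu_s_reduced(lam), dtype=float)
    return np.sqrt(3.0 * mu_a * (mu_a + mu_s))


def sensitivity_kernel(optics: MediumOptics, wavelength_nm, depth_mm) -> np.ndarray:
    """Depth weight ``W(λ, d) = exp(-2 mu_eff(λ) d)`` in (0, 1].

    The factor 2 reflects the return trip: light must reach the buried
    inclusion and come back to the surface, each leg attenuated at the
    effective attenuation rate.  ``W(λ, 0) = 1`` (surface-touching
    inclusion) and W decreases strictly with depth.
    """
    depth = np.asarray(depth_mm, dtype=float)
    if np.any(depth < 0):
        raise ValueError("depth must be nonnegative")
    return np.exp(-2.0 * effective_attenuation(optics, wavelength_nm) * depth)
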