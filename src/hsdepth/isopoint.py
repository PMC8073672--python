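"""Iso-point detection and the band-ratio depth parameter.

The central observation: an absorbing inclusion darkens the surface
reflectance more the closer it sits to the surface, while a scattering
inclusion brightens it — so between the absorption-dominated and the
scattering-dominated spectral ranges there can be a wavelength (the
*iso-point*) where the two effects cancel and the reflectance is
independent of inclusion depth.  Referencing an absorption-band
intensity to the iso-point band gives a per-pixel depth statistic ::

    d_i = 1 - I(λ_abs) / I(λ_iso)

which is zero over inclusion-free substrate (after baseline handling)
and varies monotonically with the inclusion's cover depth while the
iso-point holds.

:class:`IsoPointModel` follows the model/results idiom: it is built
from depth-labelled spectra, and :meth:`IsoPointModel.fit` regresses
every band's reflectance on depth, then classifies the slope spectrum
as ``found`` / ``boundary`` / ``absent`` and interpolates the
zero-crossing wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cube import SpectralCube
from .errors import AmbiguousIsoPointError
from .phantom import DEPTH_SENTINEL, GroundTruth

__all__ = [
    "SensitivitySpectrum",
    "IsoPointModel",
    "IsoPointResults",
    "DepthParameterMap",
    "depth_sensitivity",
    "detect_isopoint",
    "depth_parameter",
    "depth_parameter_map",
]


@dataclass
class SensitivitySpectrum:
    """Per-band OLS slope of reflectance versus inclusion depth.

    ``slope`` is in reflectance units per mm, ``stderr`` its ordinary
    least-squares standard error (which absorbs both noise and
    lack-of-fit of the linear depth model).
    """

    wavelengths: np.ndarray
    slope: np.ndarray
    stderr: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.wavelengths)
        if self.slope.shape != (n,) or self.stderr.shape != (n,):
            raise ValueError("slope/stderr must match the wavelength axis length")
        if not (np.all(np.isfinite(self.slope)) and np.all(np.isfinite(self.stderr))):
            raise ValueError("sensitivity spectrum must be finite")


def depth_sensitivity(spectra: np.ndarray, depths: np.ndarray, wavelengths: np.ndarray) -> SensitivitySpectrum:
    """Regress reflectance on depth, band by band.

    Parameters
    ----------
    spectra
        Array ``(n_samples, n_bands)`` of reflectance spectra.
    depths
        Inclusion cover depth (mm) for each sample; at least three
        distinct values are required.
    """
    spectra = np.asarray(spectra, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if spectra.ndim != 2 or depths.shape != (spectra.shape[0],):
        raise ValueError("need spectra (n_samples, n_bands) and matching depths")
    n = len(depths)
    if len(np.unique(depths)) < 3:
        raise ValueError("need at least 3 distinct depths for a sensitivity regression")
    d = depths - depths.mean()
    sxx = float(d @ d)
    slope = (d @ (spectra - spectra.mean(axis=0))) / sxx
    resid = spectra - spectra.mean(axis=0) - np.outer(d, slope)
    sse = np.einsum("ij,ij->j", resid, resid)
    stderr = np.sqrt(np.maximum(sse, 0.0) / (n - 2) / sxx)
    return SensitivitySpectrum(np.asarray(wavelengths, dtype=float), slope, stderr)


def detect_isopoint(
    sens: SensitivitySpectrum,
    tolerance: float = 2.0,
    smooth_window: int = 1,
    relative_floor: float = 0.1,
) -> "IsoPointResults":
    """Classify the sensitivity spectrum and locate the iso-point.

    A band is *significantly* depth-sensitive when its slope exceeds
    both ``tolerance`` standard errors and ``relative_floor`` times the
    spectrum's peak slope magnitude (the latter suppresses spurious
    sign flips of near-zero slopes under noise; both criteria are
    invariant to a global rescaling of the spectra).  The spectrum is
    ``found`` when the significant bands change sign exactly once along
    wavelength (the crossing wavelength is interpolated linearly
    between the bracketing bands), ``boundary`` when the slope dips
    inside the tolerance band without a significant sign change, and
    ``absent`` otherwise.  Several well-separated significant sign
    changes raise :class:`~hsdepth.errors.AmbiguousIsoPointError`
    carrying all candidate wavelengths.
    """
    slope = sens.slope
    if smooth_window > 1:
        kernel = np.full(smooth_window, 1.0 / smooth_window)
        slope = np.convolve(np.pad(slope, smooth_window // 2, mode="reflect"), kernel, mode="same")[
            smooth_window // 2 : smooth_window // 2 + len(sens.slope)
        ]
    tol = np.maximum(tolerance * sens.stderr, relative_floor * np.max(np.abs(slope)))
    sig = np.where(slope > tol, 1, np.where(slope < -tol, -1, 0))

    # transitions between runs of significant bands of opposite sign
    sig_idx = np.nonzero(sig != 0)[0]
    candidates: list[tuple[int, float]] = []
    for a, b in zip(sig_idx[:-1], sig_idx[1:]):
        if sig[a] != sig[b]:
            # locate the sign change of the (smoothed) slope inside (a, b]
            seg = slope[a : b + 1]
            change = np.nonzero(np.sign(seg[:-1]) != np.sign(seg[1:]))[0]
            i = a + (change[0] if len(change) else 0)
            s0, s1 = slope[i], slope[i + 1]
            w0, w1 = sens.wavelengths[i], sens.wavelengths[i + 1]
            frac = 0.5 if s1 == s0 else s0 / (s0 - s1)
            candidates.append((i, float(w0 + frac * (w1 - w0))))
    if len(candidates) > 1:
        raise AmbiguousIsoPointError([w for _, w in candidates])
    if len(candidates) == 1:
        idx, wavelength = candidates[0]
        return IsoPointResults("found", wavelength, idx, sens)
    if np.any(np.abs(slope) <= tol):
        return IsoPointResults("boundary", None, None, sens)
    return IsoPointResults("absent", None, None, sens)


@dataclass
class IsoPointResults:
    """Outcome of iso-point detection.

    ``status`` is ``"found"`` (iso_wavelength set), ``"boundary"``
    (depth sensitivity touches zero without changing sign) or
    ``"absent"`` (no depth-insensitive wavelength).
    """

    status: str
    iso_wavelength: Optional[float]
    crossing_index: Optional[int]
    sensitivity: SensitivitySpectrum

    def summary(self) -> str:
        lines = [
            "Iso-point detection",
            "-" * 40,
            f"status            : {self.status}",
        ]
        if self.iso_wavelength is not None:
            lines.append(f"iso wavelength    : {self.iso_wavelength:.2f} nm")
            lines.append(f"crossing band idx : {self.crossing_index}")
        s = self.sensitivity
        lines.append(f"bands             : {len(s.wavelengths)}")
        lines.append(
            f"slope range       : [{s.slope.min():.3e}, {s.slope.max():.3e}] /mm"
        )
        return "\n".join(lines)

    def to_keyvalue(self) -> dict:
        return {
            "status": self.status,
            "iso_wavelength_nm": "" if self.iso_wavelength is None else f"{self.iso_wavelength:.4f}",
            "crossing_index": "" if self.crossing_index is None else str(self.crossing_index),
        }

    def plot(self, ax=None):
        """Slope spectrum with its ±2 SE band and the detected crossing."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.sensitivity
        ax.axhline(0.0, color="0.6", lw=0.8)
        ax.fill_between(
            s.wavelengths, -2 * s.stderr, 2 * s.stderr, color="0.85", label="±2 SE"
        )
        ax.plot(s.wavelengths, s.slope, lw=1.2, label="dR/dd")
        if self.iso_wavelength is not None:
            ax.axvline(self.iso_wavelength, color="r", ls="--", label=f"iso {self.iso_wavelength:.1f} nm")
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("reflectance slope vs depth (1/mm)")
        ax.legend(frameon=False)
        return ax


class IsoPointModel:
    """Depth-sensitivity model over a set of depth-labelled spectra.

    Parameters
    ----------
    spectra
        ``(n_samples, n_bands)`` reflectance spectra (normalized,
        band-averaged).
    depths
        Inclusion cover depth (mm) per sample.
    wavelengths
        Band centres, nm.
    """

    def __init__(self, spectra: np.ndarray, depths: np.ndarray, wavelengths: np.ndarray):
        self.spectra = np.asarray(spectra, dtype=float)
        self.depths = np.asarray(depths, dtype=float)
        self.wavelengths = np.asarray(wavelengths, dtype=float)

    @classmethod
    def from_cube(
        cls,
        cube: SpectralCube,
        truth: GroundTruth,
        max_depth: Optional[float] = None,
    ) -> "IsoPointModel":
        """Sample the inclusion centre line of a labelled cube.

        For every scan line intersecting the inclusion mask, the pixel
        at the centre of the mask run is taken (the least
        blur-attenuated sample) together with its true cover depth.
        Assumes the inclusion axis runs predominantly along the y
        (line) direction, as in the canonical scenes.
        """
        spectra, depths = [], []
        for y in range(cube.n_y):
            xs = np.nonzero(truth.inclusion_mask[:, y])[0]
            if len(xs) == 0:
                continue
            xc = xs[len(xs) // 2]
            d = truth.depth_map[xc, y]
            if d == DEPTH_SENTINEL or (max_depth is not None and d > max_depth):
                continue
            spectra.append(cube.values[xc, y, :])
            depths.append(d)
        if not spectra:
            raise ValueError("inclusion mask is empty; no depth-labelled spectra to sample")
        return cls(np.array(spectra), np.array(depths), cube.wavelengths)

    def fit(self, tolerance: float = 2.0, smooth_window: int = 1) -> IsoPointResults:
        sens = depth_sensitivity(self.spectra, self.depths, self.wavelengths)
        return detect_isopoint(sens, tolerance=tolerance, smooth_window=smooth_window)


def depth_parameter(i_abs, i_iso):
    """Band-ratio depth statistic ``d_i = 1 − I_abs / I_iso``.

    Scalar inputs with ``I_iso <= 0`` raise; array inputs return a
    masked array with the offending elements masked (invalid values are
    signalled, never silently dropped).
    """
    if np.isscalar(i_abs) and np.isscalar(i_iso):
        if i_iso <= 0:
            raise ValueError(f"I_iso must be positive, got {i_iso}")
        return 1.0 - i_abs / i_iso
    i_abs = np.asarray(i_abs, dtype=float)
    i_iso = np.asarray(i_iso, dtype=float)
    invalid = i_iso <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        values = 1.0 - i_abs / np.where(invalid, 1.0, i_iso)
    return np.ma.masked_array(values, mask=np.broadcast_to(invalid, values.shape))


@dataclass
class DepthParameterMap:
    """Whole-image depth parameter with baseline handling.

    ``values`` holds the baseline-subtracted ``d_i`` per pixel;
    ``valid`` marks pixels where both bands were usable.  ``baseline``
    is the median raw ``d_i`` over the background region that was
    subtracted so inclusion-free substrate sits at zero.
    """

    values: np.ndarray
    valid: np.ndarray
    lambda_abs_nm: float
    lambda_iso_nm: float
    baseline: float
    pitch_x_um: float = 260.0
    pitch_y_um: float = 43.0

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.values.astype(np.float32))

    def to_frame(self) -> pd.DataFrame:
        nx, ny = self.values.shape
        xi, yi = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        return pd.DataFrame(
            {
                "x": xi.ravel(),
                "y": yi.ravel(),
                "depth_param": self.values.ravel(),
                "valid": self.valid.ravel().astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(
            np.where(self.valid, self.values, np.nan).T,
            origin="lower",
            aspect="auto",
            cmap="viridis",
        )
        ax.figure.colorbar(im, ax=ax, label="depth parameter $d_i$")
        ax.set_xlabel("x (pixels)")
        ax.set_ylabel("y (pixels)")
        return ax


def depth_parameter_map(
    cube: SpectralCube,
    lambda_abs: float,
    lambda_iso: float,
    background_region: Optional[np.ndarray] = None,
    band_mask: Optional[np.ndarray] = None,
) -> DepthParameterMap:
    """Whole-image Eq.-1 map at the nearest bands to the two wavelengths.

    ``background_region`` is a boolean pixel mask of inclusion-free
    substrate; the median raw ``d_i`` over it is subtracted so that
    background pixels sit at zero.  With no region given, the whole
    image is used (appropriate for inclusion-free frames).  Pixels with
    nonpositive iso-band intensity, or either band outside the
    reference-validity mask, are flagged invalid.
    """
    ia = cube.band_index(lambda_abs)
    ii = cube.band_index(lambda_iso)
    if band_mask is not None and not (band_mask[ia] and band_mask[ii]):
        raise ValueError("requested band lies outside the reference-validity mask")
    i_abs = cube.values[:, :, ia].astype(float)
    i_iso = cube.values[:, :, ii].astype(float)
    raw = depth_parameter(i_abs, i_iso)
    valid = ~np.ma.getmaskarray(raw)
    raw = np.ma.filled(raw, 0.0)
    region = valid if background_region is None else (background_region & valid)
    baseline = float(np.median(raw[region])) if np.any(region) else 0.0
    values = np.where(valid, raw - baseline, 0.0)
    return DepthParameterMap(
        values=values,
        valid=valid,
        lambda_abs_nm=float(cube.wavelengths[ia]),
        lambda_iso_nm=float(cube.wavelengths[ii]),
        baseline=baseline,
        pitch_x_um=cube.pitch_x_um,
        pitch_y_um=cube.pitch_y_um,
    )
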