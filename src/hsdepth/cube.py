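"""Spectral cube container.

A :class:`SpectralCube` is the in-memory representation of one pushbroom
hyperspectral acquisition: a 3-D intensity (or, after normalization,
reflectance) array with axes ``(x, y, band)`` plus a strictly increasing
wavelength axis in nanometres and the physical pixel pitch of the two
spatial axes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class SpectralCube:
    """Hyperspectral data cube with wavelength and pixel-pitch metadata.

    Parameters
    ----------
    values
        Array of shape ``(n_x, n_y, n_bands)``.  Dimensionless intensity
        (raw frames) or reflectance in ``[0, inf)`` (normalized frames).
    wavelengths
        Band centres in nm, strictly increasing, length ``n_bands``.
    pitch_x_um, pitch_y_um
        Physical size of one pixel along the two spatial axes, in µm.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    pitch_x_um: float = 260.0
    pitch_y_um: float = 43.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"cube values must be 3-D (x, y, band), got shape {self.values.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[2]:
            raise ValueError(
                "wavelength axis length "
                f"{len(self.wavelengths)} does not match band dimension {self.values.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube values must be finite")

    @property
    def n_x(self) -> int:
        return self.values.shape[0]

    @property
    def n_y(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band centre nearest to ``wavelength_nm``.

        Ties between two equally near band centres are broken toward the
        longer wavelength.
        """
        w = self.wavelengths
        if wavelength_nm < w[0] or wavelength_nm > w[-1]:
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside cube range [{w[0]}, {w[-1]}] nm"
            )
        dist = np.abs(w - wavelength_nm)
        # argmin returns the first minimum = shorter wavelength; check the
        # next band for an exact tie and prefer it.
        i = int(np.argmin(dist))
        if i + 1 < len(w) and dist[i + 1] == dist[i]:
            i += 1
        return i

    def with_values(self, values: np.ndarray) -> "SpectralCube":
        """Copy of this cube carrying new values, metadata preserved."""
        return replace(self, values=values)
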