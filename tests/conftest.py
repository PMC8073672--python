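"""Shared fixtures: small rendered phantom scenes and their preprocessed cubes.

All scenes are generated at test time (reduced spatial size and 1 nm
band sampling so the suite stays fast); the full-size geometry is
exercised only by the end-to-end acceptance test.
"""

from __future__ import annotations

import numpy as np
import pytest

from hsdepth import canonical_scene, simulate_cube
from hsdepth.preprocess import band_average, median_filter, normalize

SMALL = dict(n_x=31, n_y=160, band_sampling_nm=1.0)


def render(kind: str, noise: float = 0.0, seed: int = 0, **overrides):
    """Render a reduced-size canonical scene."""
    params = {**SMALL, **overrides}
    substrate, inclusion, acq = canonical_scene(
        kind, noise_sigma=noise, seed=seed, **params
    )
    return simulate_cube(substrate, inclusion, acq)


def preprocess(raw, ref, window: int = 20):
    """Standard chain: median filter both, normalize, band-average."""
    normalized, band_mask = normalize(median_filter(raw), median_filter(ref))
    return band_average(normalized, window), band_mask


@pytest.fixture(scope="session")
def absorbing_nf():
    """Noise-free strong-ink scene (has an iso-point near 575 nm)."""
    return render("absorbing", noise=0.0, seed=1)


@pytest.fixture(scope="session")
def absorbing_nf_smoothed(absorbing_nf):
    raw, ref, truth = absorbing_nf
    smoothed, band_mask = preprocess(raw, ref)
    return smoothed, band_mask, truth


@pytest.fixture(scope="session")
def clear_nf():
    """Noise-free water-filled scene (no iso-point)."""
    return render("clear", noise=0.0, seed=1)


@pytest.fixture(scope="session")
def boundary_nf():
    """Noise-free boundary-concentration scene (spectra touch)."""
    return render("boundary", noise=0.0, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
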