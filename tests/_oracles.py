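"""Naive brute-force reference implementations used as independent oracles.

These deliberately use explicit Python loops and direct formula
evaluation so they share no code path with the package.
"""

from __future__ import annotations

import numpy as np


def naive_median_2d(frame: np.ndarray, size: int = 5) -> np.ndarray:
    """Sliding-window median with reflected (edge-repeating) borders."""
    half = size // 2
    padded = np.pad(frame, half, mode="symmetric")
    out = np.empty_like(frame)
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            out[i, j] = np.median(padded[i : i + size, j : j + size])
    return out


def naive_band_mean(spectrum: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean, reflect-padded; even windows use the
    symmetric half-endpoint kernel of length window+1."""
    if window % 2 == 1:
        weights = np.full(window, 1.0 / window)
    else:
        weights = np.full(window + 1, 1.0 / window)
        weights[0] = weights[-1] = 0.5 / window
    half = len(weights) // 2
    padded = np.pad(spectrum.astype(float), half, mode="symmetric")
    out = np.empty(len(spectrum))
    for i in range(len(spectrum)):
        acc = 0.0
        for k, w in enumerate(weights):
            acc += w * padded[i + k]
        out[i] = acc
    return out


def naive_depth_parameter_map(
    values: np.ndarray, i_abs: int, i_iso: int, background: np.ndarray
) -> np.ndarray:
    """Per-pixel Eq.-1 loop with background-median baseline removal."""
    nx, ny = values.shape[:2]
    raw = np.empty((nx, ny))
    for x in range(nx):
        for y in range(ny):
            raw[x, y] = 1.0 - values[x, y, i_abs] / values[x, y, i_iso]
    baseline = np.median([raw[x, y] for x in range(nx) for y in range(ny) if background[x, y]])
    return raw - baseline
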