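"""Empirical wavelet transform: adaptive Fourier-band filter bank.

Band edges are placed at the midpoints between adjacent local maxima of the
magnitude spectrum; each band is extracted by a Meyer-type filter whose
transition uses the classical Meyer auxiliary polynomial. Adjacent filter
transitions are amplitude-complementary, so the bank is a partition of unity
over the spectrum and the extracted modes sum back to the input signal.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)


def _meyer_beta(x: np.ndarray) -> np.ndarray:
    """Meyer auxiliary polynomial: 0 at 0, 1 at 1, smooth in between."""
    x = np.clip(x, 0.0, 1.0)
    return x**4 * (35 - 84 * x + 70 * x**2 - 20 * x**3)


def spectrum_boundaries(x: np.ndarray, fs: float, n_modes: int) -> np.ndarray:
    """Band boundaries (Hz) as midpoints of adjacent retained spectral maxima.

    The ``n_modes`` largest local maxima of the magnitude spectrum are
    retained (DC excluded); midpoints between frequency-adjacent pairs give
    ``n_modes - 1`` boundaries. If fewer maxima exist, the bank falls back to
    as many modes as found (logged).
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    n = len(x)
    mag = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    peaks, _ = find_peaks(mag)
    if len(peaks) < n_modes:
        logger.info(
            "spectrum_boundaries: found %d spectral maxima, requested %d modes; "
            "falling back to %d mode(s)", len(peaks), n_modes, max(1, len(peaks)),
        )
        n_modes = max(1, len(peaks))
    if n_modes == 1:
        return np.empty(0)
    top = peaks[np.argsort(mag[peaks])[-n_modes:]]
    top = np.sort(top)
    return (freqs[top[:-1]] + freqs[top[1:]]) / 2.0


def filter_bank(boundaries: np.ndarray, n: int, fs: float) -> np.ndarray:
    """Meyer-type filters on the rfft grid, one row per band.

    Transitions at each boundary have half-width ``gamma * b`` with the usual
    tightest-gap ratio rule; lower/upper filters crossfade with the Meyer
    polynomial and sum to 1 at every frequency.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    boundaries = np.sort(np.asarray(boundaries, dtype=float))
    n_bands = len(boundaries) + 1
    if n_bands == 1:
        return np.ones((1, len(freqs)))

    # tightest-gap ratio keeps adjacent transitions disjoint
    gamma = 0.45
    if len(boundaries) > 1:
        gaps = (boundaries[1:] - boundaries[:-1]) / (boundaries[1:] + boundaries[:-1])
        gamma = min(gamma, float(np.min(gaps)))
    gamma = max(min(gamma, 0.9), 1e-6)

    # d_k: smooth 0 -> 1 step across boundary k; bands = telescoping differences
    steps = np.empty((len(boundaries), len(freqs)))
    for k, b in enumerate(boundaries):
        tau = gamma * b
        steps[k] = _meyer_beta((freqs - (b - tau)) / (2.0 * tau))
    bank = np.empty((n_bands, len(freqs)))
    bank[0] = 1.0 - steps[0]
    for k in range(1, n_bands - 1):
        bank[k] = steps[k - 1] - steps[k]
    bank[-1] = steps[-1]
    return bank


def ewt_decompose(x: np.ndarray, fs: float, n_modes: int) -> tuple[np.ndarray, np.ndarray]:
    """Split ``x`` into empirical modes; returns ``(modes, boundaries_hz)``.

    ``modes`` has one row per band (possibly fewer than ``n_modes`` when the
    spectrum has too few maxima); rows sum to the original signal.
    """
    x = np.asarray(x, dtype=float)
    bounds = spectrum_boundaries(x, fs, n_modes)
    bank = filter_bank(bounds, len(x), fs)
    X = np.fft.rfft(x)
    modes = np.vstack([np.fft.irfft(X * h, n=len(x)) for h in bank])
    return modes, bounds
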