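"""Independent brute-force oracles for the spectral and bispectral features.

Everything here evaluates definitions directly — explicit DFT summation,
explicit loops over frequency pairs — sharing no code path with
``cpreeg.features``.
"""

from __future__ import annotations

import numpy as np


def naive_dft(y: np.ndarray) -> np.ndarray:
    """One-sided DFT by explicit summation (no FFT)."""
    n = y.size
    k = np.arange(n // 2 + 1)
    t = np.arange(n)
    basis = np.exp(-2j * np.pi * np.outer(k, t) / n)
    return basis @ y


def naive_spectrum(x: np.ndarray, fs: float, window: np.ndarray):
    """Periodogram with Parseval normalization, via the naive DFT."""
    n = x.size
    X = naive_dft(x * window)
    p = np.abs(X) ** 2 / n**2
    p[1 : (n + 1) // 2] *= 2.0
    f = np.arange(n // 2 + 1) * fs / n
    return f, p


def naive_band_power(f: np.ndarray, p: np.ndarray, low: float, high: float,
                     include_low: bool = False) -> float:
    total = 0.0
    for fi, pi in zip(f, p):
        if (fi > low + 1e-9 or (include_low and abs(fi - low) <= 1e-9)) and fi <= high + 1e-9:
            total += pi
    return total


def naive_bispectrum_band(
    windows: list[np.ndarray], fs: float, window_fn: np.ndarray,
    low: float, high: float,
) -> float:
    """Sum of averaged bispectral magnitudes with low <= f1 + f2 <= high.

    Triple products are accumulated pair by pair with explicit loops over the
    principal domain (0 < f1 <= f2, f1 + f2 <= Nyquist).
    """
    n = windows[0].size
    specs = [naive_dft(w * window_fn) / n for w in windows]
    # need bins up to Nyquist for the conjugate term
    full = [np.fft.fft(w * window_fn) / n for w in windows]  # only for length check
    del full
    m = n // 2 + 1
    df = fs / n
    total = 0.0
    for i1 in range(1, m):
        for i2 in range(i1, m):
            if i1 + i2 > m - 1:
                break
            fsum = (i1 + i2) * df
            if low - 1e-9 <= fsum <= high + 1e-9:
                acc = 0.0 + 0.0j
                for X in specs:
                    acc += X[i1] * X[i2] * np.conj(X[i1 + i2])
                total += abs(acc / len(specs))
    return total
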