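"""The eleven per-epoch EEG parameters.

Each pre-shock epoch is summarized by: the peak absolute amplitude
(magnitude), the bispectral SynchFastSlow log-ratio, two band log-ratios
(BetaR, DeltaR), five band-power fractions (AlphaPR, BetaPR, DeltaPR,
ThetaPR, BG_Alpha+), and two entropies of a probability model of the signal
(log energy entropy and Renyi entropy with alpha = 0.5).  Scalar parameters
are computed per 2-s sub-epoch and arithmetically averaged over the three
sub-epochs; the bispectrum is estimated once per epoch with the three
sub-epochs as its averaging ensemble.

Band sums use 0.5 Hz bins from the 2-s windows.  A bin on a shared band
edge belongs to the lower band, so the delta/theta/high fractions of total
power partition exactly: DeltaPR + ThetaPR + BG_Alpha+ = 1.

Zero-denominator ratios and entropies of empty support yield NaN (logged)
rather than raising; downstream statistics drop them pairwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.signal import get_window

from .config import ANALYSIS_BAND, FeatureConfig
from .preprocess import SubEpoch, make_subepochs

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "SpectralEstimate",
    "BispectrumEstimate",
    "compute_magnitude",
    "compute_spectrum",
    "compute_power_ratios",
    "compute_bispectrum",
    "compute_synch_fast_slow",
    "probability_model",
    "compute_log_energy_entropy",
    "compute_renyi_entropy",
    "compute_feature_vector",
]

FEATURE_NAMES = (
    "magnitude",
    "synch_fast_slow",
    "beta_r",
    "delta_r",
    "alpha_pr",
    "beta_pr",
    "delta_pr",
    "theta_pr",
    "bg_alpha_plus",
    "log_energy_entropy",
    "renyi_entropy",
)

_EDGE_TOL = 1e-9


@dataclass
class SpectralEstimate:
    """One-sided periodogram with Parseval normalization.

    ``power.sum()`` equals the mean square of the windowed signal; the grid
    step is 0.5 Hz for the 2-s sub-epochs.
    """

    frequencies: np.ndarray
    power: np.ndarray

    def band_power(self, low: float, high: float, include_low: bool = False) -> float:
        """Sum of power over bins in (low, high]; ``include_low`` closes the
        lower edge (used for the band at the analysis floor)."""
        f = self.frequencies
        sel = (f > low + _EDGE_TOL) & (f <= high + _EDGE_TOL)
        if include_low:
            sel |= np.abs(f - low) <= _EDGE_TOL
        return float(self.power[sel].sum())


@dataclass
class BispectrumEstimate:
    """Direct (FFT-based) bispectrum magnitudes on the principal domain.

    ``magnitude[i, j]`` holds |mean over windows of X(f1) X(f2) X*(f1+f2)|
    for f1 = frequencies[i] <= f2 = frequencies[j], f1 + f2 <= Nyquist, and
    zero elsewhere (DC row excluded).
    """

    frequencies: np.ndarray
    magnitude: np.ndarray

    def band_bispectrum(self, low: float, high: float) -> float:
        """Sum of magnitudes over pairs with low <= f1 + f2 <= high."""
        f = self.frequencies
        fsum = f[:, None] + f[None, :]
        sel = (fsum >= low - _EDGE_TOL) & (fsum <= high + _EDGE_TOL)
        return float(self.magnitude[sel].sum())


def _as_array(sub) -> np.ndarray:
    return np.asarray(sub.eeg if isinstance(sub, SubEpoch) else sub, dtype=float)


def compute_magnitude(sub) -> float:
    """Peak absolute amplitude (uV) of the sub-epoch."""
    x = _as_array(sub)
    return float(np.max(np.abs(x))) if x.size else 0.0


def compute_spectrum(sub, fs: float = 250.0, window: str = "hann") -> SpectralEstimate:
    """Single-window periodogram of a 2-s sub-epoch.

    One-sided, normalized so that the power bins sum to the mean square of
    the windowed signal (interior bins carry twice the rFFT power).
    """
    x = _as_array(sub)
    n = x.size
    w = get_window(window, n) if window else np.ones(n)
    y = x * w
    X = np.fft.rfft(y)
    p = np.abs(X) ** 2 / n**2
    p[1 : (n + 1) // 2] *= 2.0       # fold negative frequencies; DC/Nyquist once
    return SpectralEstimate(np.fft.rfftfreq(n, 1.0 / fs), p)


def compute_power_ratios(spec: SpectralEstimate) -> Dict[str, float]:
    """The seven band-ratio parameters from one spectral estimate.

    Fractions are over total band power P[0.5, 47]; BetaR and DeltaR are
    natural-log ratios of disjoint bands.  Zero denominators yield NaN.
    """
    lo, hi = ANALYSIS_BAND
    total = spec.band_power(lo, hi, include_low=True)

    def frac(num: float) -> float:
        if total <= 0:
            logger.warning("zero total band power; fraction undefined")
            return float("nan")
        return num / total

    def log_ratio(num: float, den: float, name: str) -> float:
        if den <= 0 or num <= 0:
            logger.warning("zero band power in %s; feature undefined", name)
            return float("nan")
        return float(np.log(num / den))

    return {
        "alpha_pr": frac(spec.band_power(8.0, 13.0)),
        "beta_pr": frac(spec.band_power(13.0, 30.0)),
        "delta_pr": frac(spec.band_power(lo, 4.0, include_low=True)),
        "theta_pr": frac(spec.band_power(4.0, 8.0)),
        "bg_alpha_plus": frac(spec.band_power(8.0, hi)),
        "beta_r": log_ratio(spec.band_power(30.0, hi), spec.band_power(11.0, 20.0), "beta_r"),
        "delta_r": log_ratio(spec.band_power(8.0, 20.0), spec.band_power(1.0, 4.0), "delta_r"),
    }


def compute_bispectrum(
    subs: Sequence, fs: float = 250.0, window: str = "hann"
) -> BispectrumEstimate:
    """Direct bispectrum averaged over the sub-epoch ensemble.

    Per window, B(f1, f2) = X(f1) X(f2) X*(f1 + f2); the complex mean over
    windows is taken before the magnitude, so phase-random content cancels
    while quadratically phase-coupled triples survive.  Only the principal
    domain 0 < f1 <= f2, f1 + f2 <= Nyquist is populated.
    """
    arrays = [_as_array(s) for s in subs]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("all windows must share one length")
    w = get_window(window, n) if window else np.ones(n)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    m = freqs.size
    acc = np.zeros((m, m), dtype=complex)
    i = np.arange(m)
    i1g, i2g = np.meshgrid(i, i, indexing="ij")
    valid = (i1g >= 1) & (i2g >= i1g) & (i1g + i2g <= m - 1)
    isum = np.where(valid, i1g + i2g, 0)
    for a in arrays:
        X = np.fft.rfft(a * w) / n
        acc += np.where(valid, X[i1g] * X[i2g] * np.conj(X[isum]), 0.0)
    return BispectrumEstimate(freqs, np.abs(acc / len(arrays)))


def compute_synch_fast_slow(bis: BispectrumEstimate) -> float:
    """ln of total-band to high-band bispectral activity.

    Bands are on the bifrequency sum: numerator f1 + f2 in [0.5, 47],
    denominator f1 + f2 in [40, 47].  Zero denominator yields NaN.
    """
    lo, hi = ANALYSIS_BAND
    num = bis.band_bispectrum(lo, hi)
    den = bis.band_bispectrum(40.0, hi)
    if den <= 0 or num <= 0:
        logger.warning("zero bispectral band activity; SynchFastSlow undefined")
        return float("nan")
    return float(np.log(num / den))


def probability_model(
    sub,
    source: str = "amplitude_histogram",
    spec: Optional[SpectralEstimate] = None,
    bin_width: float = 0.5,
    value_range: float = 40.0,
) -> np.ndarray:
    """Probability vector p(x_i) for the entropy parameters.

    ``amplitude_histogram`` (default): normalized counts of a fixed-width
    amplitude histogram (``bin_width`` uV bins spanning +-``value_range``,
    values clipped into range).  With fixed bins, a larger and more
    irregular signal occupies more bins, so both entropies grow with
    background activity — matching the observed joint rise of magnitude and
    the entropy indices with perfusion.  ``spectral_bins``: the one-sided
    power spectrum over the 0.5-47 Hz bins, normalized to 1 — entropies
    then measure spectral shape only and are invariant to amplitude
    scaling, as is ``sample_energy`` (per-sample energy x_i^2 / sum x^2).
    """
    if source == "spectral_bins":
        spec = spec if spec is not None else compute_spectrum(sub)
        lo, hi = ANALYSIS_BAND
        f = spec.frequencies
        sel = ((f > lo + _EDGE_TOL) | (np.abs(f - lo) <= _EDGE_TOL)) & (f <= hi + _EDGE_TOL)
        p = spec.power[sel]
    elif source == "sample_energy":
        x = _as_array(sub)
        p = x**2
    elif source == "amplitude_histogram":
        x = np.clip(_as_array(sub), -value_range, value_range)
        n_bins = int(round(2 * value_range / bin_width))
        p, _ = np.histogram(x, bins=n_bins, range=(-value_range, value_range))
        p = p.astype(float)
    else:
        raise ValueError(f"unknown probability source: {source!r}")
    s = p.sum()
    if s <= 0:
        return np.zeros_like(p)
    return p / s


def _log(x: np.ndarray, base: float) -> np.ndarray:
    out = np.log(x)
    if base != np.e:
        out = out / np.log(base)
    return out


def compute_log_energy_entropy(p: np.ndarray, base: float = float(np.e)) -> float:
    """Sum over supported bins of log(p_i)^2 (zero-probability bins excluded)."""
    p = np.asarray(p, dtype=float)
    supp = p[p > 0]
    if supp.size == 0:
        raise ValueError("probability vector has empty support")
    return float(np.sum(_log(supp, base) ** 2))


def compute_renyi_entropy(
    p: np.ndarray, alpha: float = 0.5, base: float = float(np.e)
) -> float:
    """Renyi entropy (1/(1-alpha)) log sum p_i^alpha, alpha >= 0, != 1."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 1:
        raise ValueError("alpha = 1 is the Shannon limit; use -sum(p log p)")
    p = np.asarray(p, dtype=float)
    supp = p[p > 0]
    if supp.size == 0:
        raise ValueError("probability vector has empty support")
    return float(_log(np.array(np.sum(supp**alpha)), base) / (1.0 - alpha))


def compute_feature_vector(epoch, config: Optional[FeatureConfig] = None) -> Dict[str, float]:
    """All eleven parameters for one (already band-limited) epoch.

    Scalars are averaged over the three sub-epochs; SynchFastSlow comes from
    the single three-window bispectrum estimate.  NaN sub-epoch values make
    the epoch-level feature NaN.
    """
    cfg = config or FeatureConfig()
    subs = make_subepochs(epoch)
    per_sub: Dict[str, List[float]] = {name: [] for name in FEATURE_NAMES if name != "synch_fast_slow"}
    for sub in subs:
        spec = compute_spectrum(sub, window=cfg.window)
        ratios = compute_power_ratios(spec)
        p = probability_model(
            sub, cfg.prob_source, spec=spec,
            bin_width=cfg.histogram_bin_width_uv, value_range=cfg.histogram_range_uv,
        )
        per_sub["magnitude"].append(compute_magnitude(sub))
        for k, v in ratios.items():
            per_sub[k].append(v)
        if np.any(p > 0):
            per_sub["log_energy_entropy"].append(compute_log_energy_entropy(p, cfg.log_base))
            per_sub["renyi_entropy"].append(compute_renyi_entropy(p, cfg.renyi_alpha, cfg.log_base))
        else:
            logger.warning("degenerate probability model; entropies undefined")
            per_sub["log_energy_entropy"].append(float("nan"))
            per_sub["renyi_entropy"].append(float("nan"))
    out = {name: float(np.mean(vals)) for name, vals in per_sub.items()}
    out["synch_fast_slow"] = compute_synch_fast_slow(compute_bispectrum(subs, window=cfg.window))
    return {name: out[name] for name in FEATURE_NAMES}
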