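"""Feature mathematics against independent brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import get_window

from cpreeg.config import FeatureConfig
from cpreeg.features import (
    BispectrumEstimate,
    SpectralEstimate,
    compute_bispectrum,
    compute_feature_vector,
    compute_log_energy_entropy,
    compute_magnitude,
    compute_power_ratios,
    compute_renyi_entropy,
    compute_spectrum,
    compute_synch_fast_slow,
    probability_model,
)

from _oracles import naive_band_power, naive_bispectrum_band, naive_spectrum

FS = 250.0
N = 500


def _tone(f, amp=1.0, phase=0.0, n=N):
    t = np.arange(n) / FS
    return amp * np.sin(2 * np.pi * f * t + phase)


# ---------------------------------------------------------------------------
# magnitude
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "signal,expected",
    [
        (_tone(10.0, amp=10.0, phase=np.pi / 2), 10.0),
        (np.zeros(N), 0.0),
        (np.r_[np.full(250, 7.0), np.full(250, -12.0)], 12.0),
    ],
)
def test_magnitude_peak_absolute_value(signal, expected):
    assert compute_magnitude(signal) == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------

def test_spectrum_matches_direct_dft_oracle(rng):
    x = rng.normal(size=N)
    spec = compute_spectrum(x)
    f_o, p_o = naive_spectrum(x, FS, get_window("hann", N))
    np.testing.assert_allclose(spec.power, p_o, rtol=1e-9, atol=1e-18)
    np.testing.assert_allclose(spec.frequencies, f_o)


def test_band_powers_match_oracle_selection(rng):
    x = rng.normal(size=N)
    spec = compute_spectrum(x)
    f_o, p_o = naive_spectrum(x, FS, get_window("hann", N))
    for low, high, inc in [(0.5, 47, True), (8, 13, False), (1, 4, False), (30, 47, False)]:
        assert spec.band_power(low, high, inc) == pytest.approx(
            naive_band_power(f_o, p_o, low, high, inc), rel=1e-9
        )


def test_tone_power_concentrates_at_line():
    spec = compute_spectrum(_tone(10.0))
    band = spec.band_power(9.4, 10.6)
    total = spec.band_power(0.5, 47.0, include_low=True)
    assert band / total >= 0.95


def test_parseval_normalization(rng):
    x = rng.normal(size=N)
    spec = compute_spectrum(x)
    y = x * get_window("hann", N)
    assert spec.power.sum() == pytest.approx(np.mean(y**2), rel=1e-12)


def test_white_noise_spectrum_flat_within_10pct(rng):
    acc = np.zeros(N // 2 + 1)
    for _ in range(1000):
        acc += compute_spectrum(rng.normal(size=N)).power
    sel = (np.fft.rfftfreq(N, 1 / FS) >= 2) & (np.fft.rfftfreq(N, 1 / FS) <= 45)
    band = acc[sel]
    assert np.max(np.abs(band / band.mean() - 1)) < 0.10


# ---------------------------------------------------------------------------
# power ratios
# ---------------------------------------------------------------------------

def test_pure_alpha_tone_ratios():
    r = compute_power_ratios(compute_spectrum(_tone(10.0)))
    assert r["alpha_pr"] == pytest.approx(1.0, abs=1e-3)
    assert r["beta_pr"] == pytest.approx(0.0, abs=1e-3)


def test_delta_r_closed_form_on_flat_spectrum():
    """On an exactly flat spectrum DeltaR = ln((20-8)/(4-1)) = ln 4."""
    f = np.fft.rfftfreq(N, 1 / FS)
    flat = SpectralEstimate(f, np.ones_like(f))
    r = compute_power_ratios(flat)
    assert r["delta_r"] == pytest.approx(np.log(4.0), rel=1e-12)
    assert r["beta_r"] == pytest.approx(np.log((47 - 30) / (20 - 11)), rel=1e-12)


def test_band_partition_identity(rng):
    r = compute_power_ratios(compute_spectrum(rng.normal(size=N)))
    assert r["bg_alpha_plus"] + r["delta_pr"] + r["theta_pr"] == pytest.approx(1.0, abs=1e-12)


def test_zero_signal_ratios_undefined():
    r = compute_power_ratios(compute_spectrum(np.zeros(N)))
    assert all(np.isnan(v) for v in r.values())


def test_contiguous_band_additivity(rng):
    spec = compute_spectrum(rng.normal(size=N))
    ab = spec.band_power(0.5, 4.0, include_low=True)
    bc = spec.band_power(4.0, 8.0)
    ac = spec.band_power(0.5, 8.0, include_low=True)
    assert ab + bc == pytest.approx(ac, rel=1e-12)


# ---------------------------------------------------------------------------
# bispectrum and SynchFastSlow
# ---------------------------------------------------------------------------

def _coupled_triple(phase_locked=True, seed=0, n=N):
    """f1 = 6, f2 = 10 and their sum at 16 Hz, phase coupled or random."""
    rng = np.random.default_rng(seed)
    p1, p2 = rng.uniform(0, 2 * np.pi, 2)
    p3 = p1 + p2 if phase_locked else rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / FS
    return (
        np.cos(2 * np.pi * 6 * t + p1)
        + np.cos(2 * np.pi * 10 * t + p2)
        + np.cos(2 * np.pi * 16 * t + p3)
    )


def test_zero_signal_zero_bispectrum():
    bis = compute_bispectrum([np.zeros(N)] * 3)
    assert np.all(bis.magnitude == 0)


def test_coupled_triple_peaks_at_6_10():
    subs = [_coupled_triple(seed=s) for s in range(3)]
    bis = compute_bispectrum(subs, window=None)
    f = bis.frequencies
    i6, i10 = int(6 / 0.5), int(10 / 0.5)
    peak = bis.magnitude[i6, i10]
    mask = np.ones_like(bis.magnitude, dtype=bool)
    mask[i6 - 1 : i6 + 2, i10 - 1 : i10 + 2] = False
    assert peak > 5 * bis.magnitude[mask].max()


def test_random_phases_average_toward_zero(rng):
    coupled = compute_bispectrum([_coupled_triple(seed=s) for s in range(3)], window=None)
    rand_windows = [
        np.mean(
            [_coupled_triple(phase_locked=False, seed=100 * w + s) for s in range(20)],
            axis=0,
        )
        for w in range(3)
    ]
    uncoupled = compute_bispectrum(rand_windows, window=None)
    i6, i10 = 12, 20
    assert uncoupled.magnitude[i6, i10] < 0.05 * coupled.magnitude[i6, i10]


def test_bispectral_band_sums_match_brute_force(rng):
    subs = [rng.normal(size=N) for _ in range(3)]
    bis = compute_bispectrum(subs)
    w = get_window("hann", N)
    for low, high in [(0.5, 47.0), (40.0, 47.0)]:
        assert bis.band_bispectrum(low, high) == pytest.approx(
            naive_bispectrum_band(subs, FS, w, low, high), rel=1e-9
        )


def test_synch_fast_slow_log_identities():
    f = np.arange(0, 50.0, 0.5)
    m = np.zeros((f.size, f.size))
    m[20, 24] = 5.0       # 10 + 12 = 22 Hz -> broad band only
    m[40, 44] = 5.0       # 20 + 22 = 42 Hz -> both bands
    bis = BispectrumEstimate(f, m)
    assert compute_synch_fast_slow(bis) == pytest.approx(np.log(10.0 / 5.0), rel=1e-12)
    m2 = np.zeros_like(m)
    m2[40, 44] = 5.0
    assert compute_synch_fast_slow(BispectrumEstimate(f, m2)) == pytest.approx(0.0, abs=1e-12)


def test_synch_fast_slow_brute_force_on_coupled_signal(rng):
    subs = [_coupled_triple(seed=s) + 0.1 * rng.normal(size=N) for s in range(3)]
    sfs = compute_synch_fast_slow(compute_bispectrum(subs))
    w = get_window("hann", N)
    num = naive_bispectrum_band(subs, FS, w, 0.5, 47.0)
    den = naive_bispectrum_band(subs, FS, w, 40.0, 47.0)
    assert sfs == pytest.approx(np.log(num / den), rel=1e-9)


def test_zero_denominator_gives_nan():
    subs = [_tone(5.0) for _ in range(3)]  # no 40-47 Hz bifrequency mass
    bis = compute_bispectrum(subs, window=None)
    bis.magnitude[bis.frequencies[:, None] + bis.frequencies[None, :] >= 40.0] = 0.0
    assert np.isnan(compute_synch_fast_slow(bis))


# ---------------------------------------------------------------------------
# entropies
# ---------------------------------------------------------------------------

def test_log_energy_entropy_uniform_four_bins():
    p = np.full(4, 0.25)
    assert compute_log_energy_entropy(p) == pytest.approx(4 * np.log(0.25) ** 2, rel=1e-12)


def test_log_energy_entropy_point_mass_is_zero():
    assert compute_log_energy_entropy(np.array([1.0])) == 0.0


def test_log_energy_entropy_empty_support_raises():
    with pytest.raises(ValueError, match="support"):
        compute_log_energy_entropy(np.zeros(4))


@given(st.integers(2, 6), st.integers(0, 5))
@settings(deadline=None, max_examples=20)
def test_refining_a_bin_increases_log_energy_entropy(n_bins, which):
    """Splitting any bin's mass in two strictly increases the value."""
    rng = np.random.default_rng(n_bins * 7 + which)
    p = rng.dirichlet(np.ones(n_bins))
    i = which % n_bins
    refined = np.r_[np.delete(p, i), p[i] / 2, p[i] / 2]
    assert compute_log_energy_entropy(refined) > compute_log_energy_entropy(p)


@pytest.mark.parametrize("alpha", [0.2, 0.5, 2.0])
def test_renyi_of_uniform_is_log_n(alpha):
    for n in (2, 10, 94):
        p = np.full(n, 1.0 / n)
        assert compute_renyi_entropy(p, alpha) == pytest.approx(np.log(n), rel=1e-12)


def test_renyi_worked_example():
    p = np.array([0.5, 0.25, 0.25])
    expected = 2 * np.log(np.sqrt(0.5) + np.sqrt(0.25) + np.sqrt(0.25))
    assert compute_renyi_entropy(p, 0.5) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(1.0696, abs=1e-4)


def test_renyi_alpha_to_one_limit_is_shannon(rng):
    p = rng.dirichlet(np.ones(10))
    shannon = -np.sum(p * np.log(p))
    assert compute_renyi_entropy(p, 1.0 - 1e-6) == pytest.approx(shannon, abs=1e-4)
    assert compute_renyi_entropy(p, 1.0 + 1e-6) == pytest.approx(shannon, abs=1e-4)


def test_renyi_invalid_alpha():
    p = np.array([0.5, 0.5])
    with pytest.raises(ValueError, match="Shannon"):
        compute_renyi_entropy(p, 1.0)
    with pytest.raises(ValueError, match=">= 0"):
        compute_renyi_entropy(p, -0.5)


def test_renyi_nonincreasing_in_alpha(rng):
    p = rng.dirichlet(np.ones(20))
    alphas = [0.0, 0.25, 0.5, 0.75, 0.99, 1.01, 2.0, 5.0]
    vals = [compute_renyi_entropy(p, a) for a in alphas]
    assert all(a >= b - 1e-10 for a, b in zip(vals, vals[1:]))


def test_log_base_2_option():
    p = np.full(8, 0.125)
    assert compute_renyi_entropy(p, 0.5, base=2.0) == pytest.approx(3.0, rel=1e-12)
    assert compute_log_energy_entropy(p, base=2.0) == pytest.approx(8 * 9.0, rel=1e-12)


# ---------------------------------------------------------------------------
# scale behavior and the epoch-level vector
# ---------------------------------------------------------------------------

def test_scale_behavior(rng):
    x = rng.normal(size=750)
    c = 3.7
    base = compute_feature_vector(x)
    scaled = compute_feature_vector(c * x)
    assert scaled["magnitude"] == pytest.approx(c * base["magnitude"], rel=1e-9)
    for name in ("alpha_pr", "beta_pr", "delta_pr", "theta_pr", "bg_alpha_plus",
                 "beta_r", "delta_r", "synch_fast_slow"):
        assert scaled[name] == pytest.approx(base[name], rel=1e-9)
    # entropies are scale-free under the normalized-spectrum and
    # sample-energy probability models
    for source in ("spectral_bins", "sample_energy"):
        p0 = probability_model(x[:500], source)
        p1 = probability_model(c * x[:500], source)
        assert compute_log_energy_entropy(p1) == pytest.approx(
            compute_log_energy_entropy(p0), rel=1e-9
        )
        assert compute_renyi_entropy(p1) == pytest.approx(
            compute_renyi_entropy(p0), rel=1e-9
        )


def test_periodic_epoch_gives_subepoch_value():
    """With identical sub-epochs the epoch value equals the sub-epoch value."""
    x125 = np.random.default_rng(8).normal(size=125)
    x = np.tile(x125, 6)  # 750 samples, 125-periodic => identical sub-epochs
    fv = compute_feature_vector(x)
    sub = x[:500]
    assert fv["magnitude"] == pytest.approx(compute_magnitude(sub), rel=1e-12)
    ratios = compute_power_ratios(compute_spectrum(sub))
    for k, v in ratios.items():
        assert fv[k] == pytest.approx(v, rel=1e-9)


def test_mean_of_subepoch_magnitudes():
    x = np.zeros(750)
    x[100], x[300], x[700] = 8.0, -10.0, 12.0  # per-sub peaks 10, 10, 12
    fv = compute_feature_vector(x)
    assert fv["magnitude"] == pytest.approx((10.0 + 10.0 + 12.0) / 3)


def test_feature_vector_matches_componentwise_recomputation(rng):
    from cpreeg.preprocess import make_subepochs

    cfg = FeatureConfig()
    x = rng.normal(size=750) * 10
    fv = compute_feature_vector(x, cfg)
    subs = make_subepochs(x)
    mags, ratios, lees, rens = [], [], [], []
    for s in subs:
        spec = compute_spectrum(s, window=cfg.window)
        mags.append(compute_magnitude(s))
        ratios.append(compute_power_ratios(spec))
        p = probability_model(s, cfg.prob_source,
                              bin_width=cfg.histogram_bin_width_uv,
                              value_range=cfg.histogram_range_uv)
        lees.append(compute_log_energy_entropy(p, cfg.log_base))
        rens.append(compute_renyi_entropy(p, cfg.renyi_alpha, cfg.log_base))
    assert fv["magnitude"] == pytest.approx(np.mean(mags), rel=1e-12)
    assert fv["log_energy_entropy"] == pytest.approx(np.mean(lees), rel=1e-12)
    assert fv["renyi_entropy"] == pytest.approx(np.mean(rens), rel=1e-12)
    for k in ratios[0]:
        assert fv[k] == pytest.approx(np.mean([r[k] for r in ratios]), rel=1e-12)
    assert fv["synch_fast_slow"] == pytest.approx(
        compute_synch_fast_slow(compute_bispectrum(subs, window=cfg.window)), rel=1e-12
    )


def test_nan_subepoch_propagates_to_epoch():
    fv = compute_feature_vector(np.zeros(750))
    assert np.isnan(fv["beta_r"]) and np.isnan(fv["synch_fast_slow"])
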