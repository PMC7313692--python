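# Methods

## The scenario simulator

No public dataset pairs intra-arrest EEG with carotid blood flow, so the
package ships a generator whose outputs have the statistical structure the
analysis assumes. A simulated subject follows the witnessed-arrest
protocol: a pre-VF baseline (60 s), VF induction, 60 s of untreated VF,
four BLS compression cycles, then up to ten ACLS cycles, each cycle being
120 s of compressions plus a 3.5-s rhythm-check pause ending in a
defibrillation attempt, followed by a 5-s post-shock gap. ROSC is assessed
from the last BLS shock onward (the protocol's first EMT defibrillation);
under the default `rosc_outcome="auto"` rule a shock succeeds when the
session's recovery rate exceeds 0.5, after which a 20-min monitoring phase
at baseline state closes the record. Non-ROSC subjects run the full ACLS
course and end with a termination event. One simplification is deliberate:
a rhythm-check pause and defibrillation event closes *every* BLS cycle, not
only the post-EMT ones, so that each compression session contributes one
analyzable pre-shock epoch (eight subjects yield ~60–80 epochs, matching
the scale of a pooled 32 BLS + 48 ACLS session analysis).

### EEG model

Each phase's EEG is Gaussian noise shaped in the frequency domain — a
statistical emulation of the described waveforms, not a neural-mass model.
The power envelope is a mixture of a delta-dominated low component
(corner ≈ 2 Hz) and a broadband high component (alpha bump near 10 Hz plus
beta 13–30 and low-gamma 30–46 Hz plateaus), mixed so that the fraction of
power above 8 Hz equals a monotone function of the session's recovery rate
*r*: 0.08 at *r* = 0 rising linearly to 0.55 at *r* = 1. RMS amplitude is
likewise monotone in *r*: an 0.8 µV isoelectric floor rising to 13 µV at
baseline. Those anchors place band-limited 3-s epochs inside the ±5 µV
isoelectric envelope at *r* = 0 and above ±20 µV peak at *r* = 1 — the two
qualitative amplitude anchors of the arrest/recovery EEG. During untreated
VF the baseline-state signal crossfades into the isoelectric state with a
12-s delay and an 8-s exponential time constant, so the trace is
isoelectric well before the first compression.

Epoch-to-epoch nonstationarity is emulated with per-session jitter: a
lognormal multiplier (σ = 0.10) on the recovery-dependent part of the RMS
(the isoelectric floor is hard — electrocerebral silence plus instrument
noise does not fluctuate with perfusion), a drifting alpha-peak center
(10 ± 1.2 Hz), lognormal corner jitter and Dirichlet-distributed sub-band
weights. A pink instrumentation noise floor (0.3 µV RMS, within the
device's ±3 µVp-p specification) is always present. All couplings are
validated as nondecreasing in *r*; a non-monotone curve is rejected at
construction.

### Hemodynamics and ground truth

Carotid flow targets *r* × 300 mL/min during a session (near zero in
untreated VF and the post-shock gap, full baseline after ROSC), smoothed
with a 2-s single-pole filter, plus a 100/min compression pulsation and
correlated measurement noise; arterial pressure behaves analogously around
a 90 mmHg baseline with a 20 % residual during VF. Because the epoch's
hemodynamic value is the mean over the same 3-s pre-shock window as the
EEG, the measured recovery rate reproduces the generating *r* up to noise.
The latent per-session *r* values are drawn i.i.d. from Beta(2, 4)
(median ≈ 0.31, matching a cohort whose median recovery sits near 30 % of
baseline), stored with the record as ground truth, and never read by the
feature or statistics modules outside tests.

### What the generator does and does not emulate

It reproduces: the timeline; amplitude/spectral monotone coupling to
perfusion; the isoelectric and baseline amplitude anchors; epoch-to-epoch
variability of band content; instrument noise. It does not reproduce:
compression artifacts (the analysis deliberately uses pauses), burst
suppression, anesthetic effects, ECG contamination, non-Gaussian
transients, or within-subject correlation of successive sessions (r values
are i.i.d.). Passing cohort-level tests therefore demonstrates that the
pipeline recovers a designed monotone EEG–CBF coupling from realistic
noise — not that real arrest EEG behaves this way.

## Signal processing

* Sampling: 250 Hz throughout; other source rates are polyphase-resampled.
* Bandpass: zero-phase (forward–backward) 4th-order Butterworth, 0.5–47 Hz.
  Applied once per 3-s epoch, before segmentation, so the three sub-epochs
  share identical samples. Measured attenuation ≥ 20 dB at 0.1 and 60 Hz.
* Segmentation: epochs longer than 3 s are trimmed to their final 3 s (the
  samples nearest the shock); shorter epochs are rejected.
* Spectra: Hann-windowed single-window periodograms of the 500-sample
  sub-epochs (0.5 Hz bins), one-sided, normalized so the bins sum to the
  mean square of the windowed signal.
* Band sums: a bin on a shared edge belongs to the lower band; the band at
  the 0.5 Hz analysis floor is closed below. This makes
  DeltaPR + ThetaPR + BG_Alpha+ = 1 exactly.
* Bispectrum: direct FFT estimator on the principal domain (0 < f₁ ≤ f₂,
  f₁+f₂ ≤ Nyquist); the complex triple products are averaged over the
  three sub-epochs before taking magnitudes. Three windows is a
  low-variance-limit ensemble — SynchFastSlow is accordingly the noisiest
  feature. Its bands are on the bifrequency sum f₁+f₂.
* Logs are natural by default (base 2 configurable); Rényi α = 0.5.

## The probability model behind the entropies

The source defines p(xᵢ) only as "probability distribution function of
signal xᵢ", so the model is configurable. The default is a fixed-bin-width
amplitude histogram (0.5 µV bins spanning ±40 µV, values clipped, empty
bins excluded): with fixed bins, a larger and more irregular signal
occupies more bins, so both entropies rise with background activity — the
only convention consistent with the reported joint behavior of magnitude
and the entropy indices (all strongly positively associated with
recovery), and one that also lands log-energy-entropy values on the
reported scale (hundreds to thousands). Two normalized alternatives are
provided (`spectral_bins`: the 94-bin 0.5–47 Hz spectrum; `sample_energy`:
xᵢ²/Σx²); both are amplitude-invariant by construction and measure shape
only. Under `spectral_bins`, log energy entropy is dominated by near-zero
tail bins and *decreases* as the spectrum broadens — a documented reason it
is not the default.

## Statistics

* Recovery rate: 100 × (3-s pre-shock mean CBF) / (pre-VF baseline mean).
  Quartile groups at 25/50/75 %, boundary values to the upper group. The
  median split uses the analyzed epochs' own median (a fixed threshold can
  be configured).
* Pearson r with the two-sided t-transform p-value; undefined feature
  values (zero-denominator ratios) are removed pairwise and counted in the
  run log.
* One-way ANOVA by explicit between/within decomposition; zero within-group
  variance raises as degenerate.
* Dunnett T3: Welch-type statistics with Welch–Satterthwaite degrees of
  freedom, referred to the studentized maximum modulus distribution with
  k = number of pairwise comparisons. The SMM tail has no closed form and
  is evaluated by adaptive quadrature over the chi mixture (accuracy well
  below the 1e-4 target; at k = 1 it reproduces the Welch t-test to
  ~1e-13).
* ROC: empirical threshold sweep; AUC by trapezoid (equal to the normalized
  Mann–Whitney U); Hanley–McNeil standard error; the reported cut-off
  maximizes Youden's J, ties resolved toward higher specificity. Features
  are scored with higher values predicting above-median recovery.

## Problem sizes and determinism

Cohort analyses use 8 subjects (~60–80 epochs, matching the pooled design);
calibration checks use 500 replicates at n = 80; the amplitude-anchor
checks use 200 epochs per state. One seed drives a `SeedSequence` that
spawns an independent stream per subject, so cohorts are reproducible
subject-by-subject and whole runs are byte-deterministic; every output
directory carries the seed and a configuration hash in `run_log.json`.

## Known limitations

Epochs are pooled across subjects without modeling within-animal
correlation, mirroring the pooled design the analysis reproduces; a
mixed-effects treatment is out of scope. The coupling curves at
intermediate perfusion are simulator assumptions — no quantitative data
constrain the EEG spectrum at, say, 40 % recovery. SynchFastSlow from a
three-window ensemble is high-variance by construction, and the EDF writer
covers only the single-rate, 16-bit subset of the format this package
emits.
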