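"""Configuration objects for the simulator, feature extraction and statistics.

Every tunable in the package lives in one of the dataclasses below so that a
whole run is reproducible from a single YAML/JSON document plus a seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import yaml

#: Analysis band of the single-channel EEG device (Hz).
ANALYSIS_BAND = (0.5, 47.0)

#: Fixed EEG analysis sample rate (Hz).
EEG_RATE_HZ = 250.0


@dataclass
class ScenarioConfig:
    """Timeline of one simulated cardiac-arrest experiment.

    The default timeline follows the witnessed out-of-hospital arrest
    protocol: an anesthesia-free baseline, VF induction, one minute of
    untreated VF, four bystander BLS cycles, then up to ten ACLS cycles,
    each cycle ending in a rhythm-check pause and a defibrillation attempt.
    A successful shock is followed by a 20-min monitoring phase.
    """

    sample_rate_hz: float = EEG_RATE_HZ
    baseline_s: float = 60.0
    untreated_vf_s: float = 60.0
    n_bls_cycles: int = 4
    max_acls_cycles: int = 10
    compression_s: float = 120.0      # per BLS/ACLS cycle, before the pause
    pause_s: float = 3.5              # pre-shock pause; must fit a 3-s epoch
    post_shock_gap_s: float = 5.0     # rhythm check after the shock
    monitoring_s: float = 1200.0      # post-ROSC observation
    decay_delay_s: float = 12.0       # EEG amplitude holds this long after VF onset
    decay_tau_s: float = 8.0          # then decays exponentially (isoelectric by 60 s)
    rosc_outcome: object = "auto"     # True, False or "auto" (threshold on r)
    rosc_threshold: float = 0.5
    cbf_baseline_ml_min: float = 300.0
    map_baseline_mmhg: float = 90.0
    map_residual_frac: float = 0.2    # residual arterial pressure during VF
    seed: int = 0

    def validate(self) -> None:
        if self.sample_rate_hz <= 2 * ANALYSIS_BAND[1]:
            raise ValueError(
                f"sample_rate_hz={self.sample_rate_hz} must exceed twice the "
                f"{ANALYSIS_BAND[1]} Hz analysis band edge"
            )
        if self.untreated_vf_s <= 0:
            raise ValueError("untreated_vf_s must be positive")
        if self.n_bls_cycles < 1:
            raise ValueError("n_bls_cycles must be >= 1")
        if self.pause_s < 3.0:
            raise ValueError("pause_s must be >= 3 s to fit a pre-shock epoch")
        if self.rosc_outcome not in (True, False, "auto"):
            raise ValueError("rosc_outcome must be True, False or 'auto'")


def _default_amp_curve(r: np.ndarray | float) -> np.ndarray | float:
    """Linear RMS interpolation between isoelectric and baseline, on [0, 1]."""
    return np.asarray(r, dtype=float)


@dataclass
class CouplingModel:
    """Monotone coupling from per-session CBF recovery rate r to EEG state.

    ``amp_curve`` and ``spectral_curve`` map r in [0, 1] to a normalized gain
    in [0, 1]; the model interpolates RMS amplitude between
    ``amp_isoelectric_rms_uv`` and ``amp_baseline_rms_uv``, and the fraction
    of signal power above 8 Hz between ``frac_high_isoelectric`` and
    ``frac_high_baseline``.  Both curves must be nondecreasing.

    The defaults put the isoelectric state within the +-5 uV envelope and the
    baseline state above +-20 uV peak amplitude on 3-s epochs, and sweep the
    high-frequency power fraction from delta-dominated to broadband with
    alpha/beta content.  Epoch-to-epoch variability (amplitude jitter, alpha
    peak drift, band-weight redistribution) emulates the nonstationarity of
    real frontal EEG.
    """

    amp_isoelectric_rms_uv: float = 0.8
    amp_baseline_rms_uv: float = 13.0
    frac_high_isoelectric: float = 0.08
    frac_high_baseline: float = 0.55
    amp_curve: Callable = field(default=_default_amp_curve, repr=False)
    spectral_curve: Callable = field(default=_default_amp_curve, repr=False)
    # epoch-to-epoch variability of real EEG
    amp_jitter_sd: float = 0.10           # lognormal sigma on RMS
    alpha_center_mean_hz: float = 10.0
    alpha_center_sd_hz: float = 1.2
    corner_jitter_sd: float = 0.2         # lognormal sigma on spectral corners
    band_weight_conc: float = 6.0         # Dirichlet concentration of sub-band weights
    device_noise_rms_uv: float = 0.3      # pink instrumentation noise floor

    def rms_at(self, r: float) -> float:
        g = float(self.amp_curve(r))
        return self.amp_isoelectric_rms_uv + g * (
            self.amp_baseline_rms_uv - self.amp_isoelectric_rms_uv
        )

    def frac_high_at(self, r: float) -> float:
        g = float(self.spectral_curve(r))
        return self.frac_high_isoelectric + g * (
            self.frac_high_baseline - self.frac_high_isoelectric
        )

    def validate(self) -> None:
        grid = np.linspace(0.0, 1.0, 21)
        amp = np.asarray([self.amp_curve(r) for r in grid], dtype=float)
        spec = np.asarray([self.spectral_curve(r) for r in grid], dtype=float)
        if np.any(np.diff(amp) < -1e-12):
            raise ValueError("amp_curve must be nondecreasing in r on [0, 1]")
        if np.any(np.diff(spec) < -1e-12):
            raise ValueError("spectral_curve must be nondecreasing in r on [0, 1]")
        if self.amp_isoelectric_rms_uv <= 0 or self.amp_baseline_rms_uv <= 0:
            raise ValueError("RMS anchors must be positive")
        if self.amp_isoelectric_rms_uv >= self.amp_baseline_rms_uv:
            raise ValueError("isoelectric RMS must be below baseline RMS")


@dataclass
class FeatureConfig:
    """Estimator choices for the eleven EEG parameters."""

    window: str = "hann"
    log_base: float = float(np.e)         # natural log unless overridden
    prob_source: str = "amplitude_histogram"  # | spectral_bins | sample_energy
    renyi_alpha: float = 0.5
    histogram_bin_width_uv: float = 0.5   # fixed-width amplitude bins
    histogram_range_uv: float = 40.0      # histogram spans +-range
    bandpass_low_hz: float = ANALYSIS_BAND[0]
    bandpass_high_hz: float = ANALYSIS_BAND[1]
    bandpass_order: int = 4


@dataclass
class StatsConfig:
    """Association-analysis settings."""

    alpha: float = 0.05
    group_edges: tuple = (25.0, 50.0, 75.0)   # % of baseline; edge goes to upper group
    median_split_threshold: Optional[float] = None  # None => data median
    selected_features: tuple = ("magnitude", "log_energy_entropy", "renyi_entropy")


@dataclass
class RunConfig:
    """Full pipeline configuration: simulate (or load) -> features -> stats."""

    mode: str = "simulate"                 # simulate | load
    n_subjects: int = 8
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    coupling: CouplingModel = field(default_factory=CouplingModel)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    data_dir: Optional[str] = None         # load mode: directory of subject CSVs
    out_dir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError("mode must be 'simulate' or 'load'")
        if self.mode == "load" and not self.data_dir:
            raise ValueError("load mode requires data_dir")
        self.scenario.validate()
        self.coupling.validate()


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if callable(obj):
        return getattr(obj, "__name__", repr(obj))
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_hash(cfg) -> str:
    """Stable short hash of a config dataclass, recorded in every output."""
    blob = json.dumps(_to_jsonable(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML or JSON document.

    Unknown keys raise; nested sections (``scenario``, ``coupling``,
    ``features``, ``stats``) map onto the corresponding dataclasses.
    Callable coupling curves cannot be expressed in YAML and keep their
    defaults (linear).
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    sections = {
        "scenario": ScenarioConfig,
        "coupling": CouplingModel,
        "features": FeatureConfig,
        "stats": StatsConfig,
    }
    kwargs = {}
    for key, val in doc.items():
        if key in sections:
            cls = sections[key]
            names = {f.name for f in dataclasses.fields(cls)}
            bad = set(val) - names
            if bad:
                raise ValueError(f"unknown keys in '{key}' section: {sorted(bad)}")
            if "group_edges" in val:
                val["group_edges"] = tuple(val["group_edges"])
            if "selected_features" in val:
                val["selected_features"] = tuple(val["selected_features"])
            kwargs[key] = cls(**val)
        elif key in {f.name for f in dataclasses.fields(RunConfig)}:
            kwargs[key] = val
        else:
            raise ValueError(f"unknown config key: {key}")
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg
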