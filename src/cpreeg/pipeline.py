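"""End-to-end orchestration: simulate or load -> epochs -> features -> stats.

Every run is deterministic given its seed; the run log records the seed, a
hash of the full configuration, per-stage timings and dropped-epoch counts,
and the median-split threshold actually used.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as cio
from .config import RunConfig, config_hash
from .features import FEATURE_NAMES, compute_feature_vector
from .preprocess import bandpass
from .simulate import simulate_cohort
from .stats import StatsReport, build_report, recovery_table

logger = logging.getLogger(__name__)

__all__ = ["run", "simulate_to_dir", "load_recordings", "extract_feature_table"]


def simulate_to_dir(config: RunConfig, data_dir: str | Path) -> List[Tuple[Path, Path]]:
    """Simulate the cohort and write one CSV pair per subject."""
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    records = simulate_cohort(
        config.n_subjects, config.scenario, config.coupling, seed=config.seed
    )
    paths = []
    for rec in records:
        sig = data_dir / f"{rec.subject_id}_signals.csv"
        evt = data_dir / f"{rec.subject_id}_events.csv"
        cio.write_recording_csv(rec, sig, evt)
        paths.append((sig, evt))
    return paths


def load_recordings(data_dir: str | Path) -> List[cio.Recording]:
    """Load every ``*_signals.csv`` / ``*_events.csv`` pair in a directory."""
    data_dir = Path(data_dir)
    sigs = sorted(data_dir.glob("*_signals.csv"))
    if not sigs:
        raise FileNotFoundError(f"no *_signals.csv files in {data_dir}")
    recs = []
    for sig in sigs:
        evt = sig.with_name(sig.name.replace("_signals", "_events"))
        sid = sig.name.replace("_signals.csv", "")
        recs.append(cio.read_recording(sig, evt if evt.exists() else None,
                                       format="csv", subject_id=sid))
    return recs


def _baseline_cbf(rec: cio.Recording) -> float:
    """Mean pre-VF carotid flow — the denominator of the recovery rate."""
    vf = [t for lab, t in rec.events if lab == "vf_onset"]
    if not vf:
        raise ValueError("recording has no vf_onset event; cannot set baseline")
    ch = rec.channels["cbf"]
    n = int(round(vf[0] * ch.fs))
    if n < 1:
        raise ValueError("no pre-VF samples for the CBF baseline")
    return float(np.mean(ch.data[:n]))


def extract_feature_table(
    recordings: List[cio.Recording], config: RunConfig
) -> pd.DataFrame:
    """Per-epoch feature vectors paired with raw CBF epoch values.

    Returns one row per pre-shock epoch: subject, session, epoch time, the
    eleven features (computed on the band-limited epoch), the epoch-mean CBF
    and the subject's pre-VF CBF baseline.
    """
    rows = []
    fcfg = config.features
    for rec in recordings:
        base = _baseline_cbf(rec)
        for ep in cio.extract_preshock_epochs(rec):
            filtered = bandpass(
                ep.eeg, ep.fs, fcfg.bandpass_low_hz, fcfg.bandpass_high_hz,
                fcfg.bandpass_order,
            )
            feats = compute_feature_vector(filtered, fcfg)
            cbf = cio.epoch_hemodynamic_value(rec, ep, "cbf")
            rows.append(
                {"subject": ep.subject_id, "session": ep.session,
                 "epoch_time_s": ep.linked_event_s, **feats,
                 "cbf_epoch": cbf, "cbf_baseline": base}
            )
    return pd.DataFrame(rows)


def run(config: RunConfig) -> StatsReport:
    """Execute the configured pipeline and write all artifacts to out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {"seed": config.seed, "config_hash": config_hash(config), "stages": {}}

    def stage(name):
        t0 = time.perf_counter()

        def done(**extra):
            log["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **extra}

        return done

    try:
        done = stage("data")
        if config.mode == "simulate":
            data_dir = out / "data"
            simulate_to_dir(config, data_dir)
            recordings = load_recordings(data_dir)
        else:
            recordings = load_recordings(config.data_dir)
        done(n_subjects=len(recordings))

        done = stage("features")
        table = extract_feature_table(recordings, config)
        if table.empty:
            raise ValueError("no extractable pre-shock epochs")
        table.to_csv(out / "features.csv", index=False)
        done(n_epochs=len(table))

        done = stage("stats")
        rec_df = recovery_table(
            100.0 * table["cbf_epoch"] / table["cbf_baseline"], config.stats
        )
        report = build_report(table[list(FEATURE_NAMES)], rec_df, config.stats)
        report.to_csv(out)
        rec_df.to_csv(out / "recovery.csv", index=False)
        done(median_split=rec_df.attrs["median_split_threshold"])
    except Exception as exc:
        stage_name = list(log["stages"])[-1] if log["stages"] else "init"
        raise RuntimeError(f"pipeline failed after stage '{stage_name}': {exc}") from exc

    log.update(report.log)
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return report
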