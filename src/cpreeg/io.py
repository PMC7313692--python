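"""Reading, writing, channel synchronization and pre-shock epoch extraction.

All times are seconds from the recording origin; epochs are half-open
``[start, start + duration)`` windows of the 250 Hz EEG channel ending at a
defibrillation event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import EEG_RATE_HZ

logger = logging.getLogger(__name__)

__all__ = [
    "Channel",
    "Recording",
    "Epoch",
    "read_recording",
    "write_recording_csv",
    "write_recording_edf",
    "extract_preshock_epochs",
    "epoch_hemodynamic_value",
]

#: CSV signal column -> (channel name, unit)
_CSV_CHANNELS = {
    "eeg_uv": ("eeg", "uV"),
    "cbf_ml_min": ("cbf", "mL/min"),
    "map_mmhg": ("map", "mmHg"),
}


@dataclass
class Channel:
    data: np.ndarray
    fs: float
    unit: str


@dataclass
class Recording:
    """Named sampled channels plus an ordered event list."""

    channels: Dict[str, Channel]
    events: List[Tuple[str, float]]
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        times = [t for _, t in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")

    def resample_to(self, rate: float) -> "Recording":
        """Polyphase-resample every channel to a common rate (logged)."""
        from scipy.signal import resample_poly

        out = {}
        for name, ch in self.channels.items():
            if ch.fs == rate:
                out[name] = ch
                continue
            frac = Fraction(rate / ch.fs).limit_denominator(1000)
            logger.info("resampling %s: %g Hz -> %g Hz", name, ch.fs, rate)
            out[name] = Channel(resample_poly(ch.data, frac.numerator, frac.denominator), rate, ch.unit)
        return Recording(out, list(self.events), dict(self.meta))


@dataclass
class Epoch:
    """A ~3-s EEG segment ending at the defibrillation it precedes."""

    eeg: np.ndarray
    start_time_s: float
    duration_s: float
    linked_event_s: float
    subject_id: str
    session: str
    fs: float = EEG_RATE_HZ


def _read_events_csv(path: str | Path) -> List[Tuple[str, float]]:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"label", "time_s"} <= set(df.columns):
        raise ValueError("events file must have columns label,time_s")
    times = df["time_s"].to_numpy(float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("event rows must be sorted with strictly increasing time_s")
    return list(zip(df["label"].astype(str), times))


def read_recording(
    signal_path: str | Path,
    events_path: Optional[str | Path] = None,
    format: str = "csv",
    subject_id: Optional[str] = None,
) -> Recording:
    """Read a Recording from CSV (all channels) or EDF (EEG channel).

    CSV layout is the one :func:`write_recording_csv` produces: columns
    ``time_s, eeg_uv, cbf_ml_min, map_mmhg`` (hemodynamic columns optional).
    EDF amplitudes are converted to uV from the header physical dimension.
    EEG is resampled to 250 Hz if the source rate differs.
    """
    signal_path = Path(signal_path)
    if not signal_path.exists():
        raise FileNotFoundError(signal_path)
    events = _read_events_csv(events_path) if events_path else []

    if format == "csv":
        df = pd.read_csv(signal_path, float_precision="round_trip")
        if "time_s" not in df.columns:
            raise ValueError("signal CSV must have a time_s column")
        t = df["time_s"].to_numpy(float)
        dt = np.diff(t)
        if len(t) > 1 and (np.any(dt <= 0) or np.ptp(dt) > 1e-6):
            raise ValueError("time_s must be uniform and strictly increasing")
        fs = 1.0 / dt[0] if len(t) > 1 else EEG_RATE_HZ
        channels = {}
        for col, (name, unit) in _CSV_CHANNELS.items():
            if col in df.columns:
                channels[name] = Channel(df[col].to_numpy(float), float(round(fs, 6)), unit)
        if "eeg" not in channels:
            raise ValueError("missing required channel column: eeg_uv")
    elif format == "edf":
        import mne

        raw = mne.io.read_raw_edf(signal_path, preload=True, verbose="error")
        # mne scales voltage channels to SI volts using the header dimension
        data = raw.get_data()[0] * 1e6
        channels = {"eeg": Channel(data, float(raw.info["sfreq"]), "uV")}
    else:
        raise ValueError(f"unknown format: {format!r}")

    rec = Recording(channels, events, {"subject_id": subject_id or signal_path.stem,
                                       "source": str(signal_path)})
    rec.validate()
    if rec.channels["eeg"].fs != EEG_RATE_HZ:
        rec = rec.resample_to(EEG_RATE_HZ)
    return rec


def write_recording_csv(record, signals_path: str | Path, events_path: str | Path) -> None:
    """Write a simulated subject as the package's CSV pair (signals + events)."""
    # 17 significant digits make the float64 round trip bit-exact
    record.to_frame().to_csv(signals_path, index=False, float_format="%.17g")
    record.events_frame().to_csv(events_path, index=False, float_format="%.17g")


def write_recording_edf(record, path: str | Path) -> None:
    """Write the EEG channel of a simulated subject as an EDF file (uV)."""
    from .edf import write_edf

    write_edf(path, [record.eeg], ["EEG Fp"], ["uV"], record.fs,
              recording_id=f"synthetic {record.subject_id}")


def _session_for_time(events: List[Tuple[str, float]], t: float) -> str:
    label = "unknown"
    for lab, et in events:
        if et > t:
            break
        if lab.endswith("_start"):
            label = lab[: -len("_start")]
    return label


def extract_preshock_epochs(
    rec: Recording,
    window_s: float = 3.0,
    defib_label: str = "defib",
) -> List[Epoch]:
    """One epoch per defibrillation event, ending at the event time.

    Events without ``window_s`` of EEG history are dropped with a warning.
    No defibrillation events is not an error — the list is empty.
    """
    ch = rec.channels.get("eeg")
    if ch is None:
        raise ValueError("recording has no 'eeg' channel")
    n_win = int(round(window_s * ch.fs))
    epochs = []
    for label, t in rec.events:
        if label != defib_label:
            continue
        end = int(round(t * ch.fs))
        start = end - n_win
        if start < 0 or end > len(ch.data):
            logger.warning(
                "dropping epoch at t=%.2f s: needs %d samples, has %d",
                t, n_win, min(end, len(ch.data)) - max(start, 0),
            )
            continue
        epochs.append(
            Epoch(
                eeg=ch.data[start:end].copy(),
                start_time_s=start / ch.fs,
                duration_s=n_win / ch.fs,
                linked_event_s=t,
                subject_id=rec.meta.get("subject_id", "unknown"),
                session=_session_for_time(rec.events, t),
                fs=ch.fs,
            )
        )
    return epochs


def epoch_hemodynamic_value(rec: Recording, epoch: Epoch, channel: str) -> float:
    """Mean of a hemodynamic channel over the epoch window.

    Partial overlap averages the overlapping part (warned); no overlap raises.
    """
    ch = rec.channels.get(channel)
    if ch is None:
        raise ValueError(f"no channel named {channel!r}")
    start = int(round(epoch.start_time_s * ch.fs))
    end = int(round((epoch.start_time_s + epoch.duration_s) * ch.fs))
    lo, hi = max(start, 0), min(end, len(ch.data))
    if hi <= lo:
        raise ValueError(f"channel {channel!r} does not overlap the epoch window")
    if lo > start or hi < end:
        logger.warning(
            "channel %r covers only %.2f of the %.2f s epoch window",
            channel, (hi - lo) / ch.fs, epoch.duration_s,
        )
    return float(np.mean(ch.data[lo:hi]))
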