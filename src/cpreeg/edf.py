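"""Minimal EDF writer for single-rate signal export.

Writes standard EDF (16-bit) files: one data record per second, physical
scaling derived from the data range, ASCII header per the EDF field layout.
Only what this package needs — uniform sample rate across channels, no
annotations.  Reading is delegated to :mod:`mne`.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    b = str(value)[:width].encode("ascii")
    return b + b" " * (width - len(b))


def _num(value: float, width: int) -> bytes:
    s = f"{value:.10g}"[:width]
    return _field(s, width)


def write_edf(
    path: str | Path,
    signals: Sequence[np.ndarray],
    labels: Sequence[str],
    units: Sequence[str],
    fs: float,
    patient_id: str = "X",
    recording_id: str = "synthetic",
    start: datetime | None = None,
) -> None:
    """Write channels sharing one integer sample rate to an EDF file.

    Signals are zero-padded to a whole number of 1-s data records.  Physical
    min/max are taken per channel from the data (symmetrized, with a floor of
    +-1 unit) so quantization error is below 1/32768 of the range.
    """
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sample rate")
    spr = int(fs)
    if not (len(signals) == len(labels) == len(units)):
        raise ValueError("signals, labels and units must have equal length")
    n = max(len(s) for s in signals)
    n_rec = int(np.ceil(n / spr))
    start = start or datetime(2000, 1, 1, 0, 0, 0)

    phys_min, phys_max, digital = [], [], []
    for sig in signals:
        sig = np.asarray(sig, dtype=float)
        padded = np.zeros(n_rec * spr)
        padded[: len(sig)] = sig
        amp = max(1.0, float(np.max(np.abs(padded))) * 1.0001)
        phys_min.append(-amp)
        phys_max.append(amp)
        scale = (_DIG_MAX - _DIG_MIN) / (2 * amp)
        dig = np.round((padded + amp) * scale + _DIG_MIN).astype("<i2")
        digital.append(dig)

    ns = len(signals)
    header_bytes = 256 * (1 + ns)
    head = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field(recording_id, 80),
            _field(start.strftime("%d.%m.%y"), 8),
            _field(start.strftime("%H.%M.%S"), 8),
            _num(header_bytes, 8),
            _field("", 44),
            _num(n_rec, 8),
            _num(1, 8),
            _num(ns, 4),
        ]
    )
    sig_head = b"".join(
        [
            b"".join(_field(lab, 16) for lab in labels),
            b"".join(_field("", 80) for _ in labels),
            b"".join(_field(u, 8) for u in units),
            b"".join(_num(v, 8) for v in phys_min),
            b"".join(_num(v, 8) for v in phys_max),
            b"".join(_num(_DIG_MIN, 8) for _ in labels),
            b"".join(_num(_DIG_MAX, 8) for _ in labels),
            b"".join(_field("", 80) for _ in labels),
            b"".join(_num(spr, 8) for _ in labels),
            b"".join(_field("", 32) for _ in labels),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(head + sig_head)
        for rec in range(n_rec):
            for dig in digital:
                fh.write(dig[rec * spr : (rec + 1) * spr].tobytes())
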