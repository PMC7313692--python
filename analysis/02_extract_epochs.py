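#!/usr/bin/env python
"""Extract the ~3-s pre-defibrillation pause epochs from the cohort.

Reads the recordings written by 01_simulate_cohort.py, pulls one epoch per
defibrillation event, pairs it with the epoch-mean carotid flow, and writes
results/analysis/epochs.csv.
"""

from pathlib import Path

import pandas as pd

from cpreeg.io import epoch_hemodynamic_value, extract_preshock_epochs
from cpreeg.pipeline import _baseline_cbf, load_recordings

OUT = Path("results/analysis")
DATA = Path("scratch/cohort_data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in load_recordings(DATA):
        base = _baseline_cbf(rec)
        for ep in extract_preshock_epochs(rec):
            rows.append(
                {"subject": ep.subject_id, "session": ep.session,
                 "defib_time_s": ep.linked_event_s,
                 "cbf_epoch_ml_min": epoch_hemodynamic_value(rec, ep, "cbf"),
                 "cbf_baseline_ml_min": base}
            )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "epochs.csv", index=False)
    by_kind = df["session"].str.split("_").str[0].value_counts()
    print(f"{len(df)} pre-shock epochs from {df['subject'].nunique()} subjects "
          f"({by_kind.to_dict()})")


if __name__ == "__main__":
    main()
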