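#!/usr/bin/env python
"""Simulate the eight-animal arrest cohort and write the raw recordings.

Writes per-subject signal/event CSVs (and one EDF sample of the EEG channel)
under scratch/cohort_data/ — raw traces are bulky and regenerated on demand —
and prints the session and outcome summary.
"""

from pathlib import Path

from cpreeg.config import RunConfig
from cpreeg.io import write_recording_csv, write_recording_edf
from cpreeg.simulate import simulate_cohort

DATA = Path("scratch/cohort_data")
SEED = 1


def main() -> None:
    cfg = RunConfig(seed=SEED)
    DATA.mkdir(parents=True, exist_ok=True)
    records = simulate_cohort(cfg.n_subjects, cfg.scenario, cfg.coupling, seed=SEED)
    paths = []
    for rec in records:
        sig = DATA / f"{rec.subject_id}_signals.csv"
        write_recording_csv(rec, sig, DATA / f"{rec.subject_id}_events.csv")
        paths.append(sig)
    write_recording_edf(records[0], DATA / f"{records[0].subject_id}_eeg.edf")

    n_bls = sum(sum(1 for lab, _ in r.events if lab.startswith("bls")) for r in records)
    n_acls = sum(sum(1 for lab, _ in r.events if lab.startswith("acls")) for r in records)
    n_rosc = sum(r.rosc for r in records)
    print(f"wrote {len(paths)} subjects under {DATA}")
    print(f"sessions: {n_bls} BLS + {n_acls} ACLS; sustained ROSC in {n_rosc}/{len(records)}")


if __name__ == "__main__":
    main()
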