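#!/usr/bin/env python
"""Compute the eleven EEG parameters for every pre-shock epoch.

Band-limits each epoch to 0.5-47 Hz, averages each parameter over the three
overlapping 2-s sub-epochs, and writes results/analysis/features.csv.
"""

from pathlib import Path

from cpreeg.config import RunConfig
from cpreeg.pipeline import extract_feature_table, load_recordings

OUT = Path("results/analysis")
DATA = Path("scratch/cohort_data")


def main() -> None:
    cfg = RunConfig(seed=1)
    table = extract_feature_table(load_recordings(DATA), cfg)
    table.to_csv(OUT / "features.csv", index=False)
    print(f"{len(table)} epochs featurized")
    pct = 100.0 * table["cbf_epoch"] / table["cbf_baseline"]
    lo, hi = pct < pct.median(), pct >= pct.median()
    for name in ("magnitude", "log_energy_entropy", "renyi_entropy"):
        print(f"  {name}: below-median CBF mean {table.loc[lo, name].mean():.1f}, "
              f"above-median mean {table.loc[hi, name].mean():.1f}")


if __name__ == "__main__":
    main()
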