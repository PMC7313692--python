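#!/usr/bin/env python
"""Association statistics: correlations, quartile ANOVA + Dunnett T3, ROC.

Pairs the epoch features with CBF recovery rates (percent of pre-VF
baseline), then writes correlations.csv, anova.csv, anova_posthoc.csv and
roc.csv under results/analysis/ and prints the headline pattern.
"""

from pathlib import Path

import pandas as pd

from cpreeg.config import StatsConfig
from cpreeg.features import FEATURE_NAMES
from cpreeg.stats import build_report, recovery_table

OUT = Path("results/analysis")


def main() -> None:
    table = pd.read_csv(OUT / "features.csv")
    rec = recovery_table(100.0 * table["cbf_epoch"] / table["cbf_baseline"], StatsConfig())
    report = build_report(table[list(FEATURE_NAMES)], rec, StatsConfig())
    report.to_csv(OUT)

    corr = report.correlations.copy()
    corr["absr"] = corr["r"].abs()
    top = corr.sort_values("absr", ascending=False).head(3)
    print(f"{report.log['n_epochs']} epochs; median recovery "
          f"{rec.attrs['median_split_threshold']:.1f}% of baseline")
    print("strongest correlates of CBF recovery:")
    for _, row in top.iterrows():
        print(f"  {row['feature']}: r = {row['r']:+.3f} (p = {row['p_value']:.2g})")
    print("median-split ROC:")
    for _, row in report.roc.iterrows():
        print(f"  {row['feature']}: AUC = {row['auc']:.3f} "
              f"(cut-off {row['cut_off']:.3f}, sens {row['sensitivity']:.2f})")


if __name__ == "__main__":
    main()
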