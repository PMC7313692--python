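"""Association statistics between EEG parameters and CBF recovery.

Recovery rates (percent of pre-VF baseline) are paired with the per-epoch
feature vectors and analyzed three ways: Pearson correlation per feature,
one-way ANOVA across the four recovery quartile groups with Dunnett T3
pairwise post hoc tests (Welch-type statistics referred to the studentized
maximum modulus distribution), and ROC analysis of each feature against the
median split of recovery, with the Youden-optimal cut-off and a
Hanley-McNeil standard error for the AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps
from sklearn.metrics import roc_curve

from .config import StatsConfig
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "RecoveryRate",
    "CorrelationResult",
    "PostHocResult",
    "RocResult",
    "StatsReport",
    "compute_recovery_rate",
    "recovery_table",
    "pearson",
    "one_way_anova",
    "dunnett_t3",
    "smm_sf",
    "roc_analysis",
    "build_report",
]


# ---------------------------------------------------------------------------
# recovery rates
# ---------------------------------------------------------------------------

@dataclass
class RecoveryRate:
    value_pct: float
    baseline_value: float
    quartile_group: int          # 1: [0,25) 2: [25,50) 3: [50,75) 4: [75,inf)
    above_median: Optional[bool] = None


def quartile_group(value_pct: float, edges: Sequence[float] = (25.0, 50.0, 75.0)) -> int:
    """Quartile-group label; a value on an edge goes to the upper group."""
    return int(np.searchsorted(np.asarray(edges, float), value_pct, side="right")) + 1


def compute_recovery_rate(
    epoch_value: float,
    baseline_value: float,
    median_pct: Optional[float] = None,
    edges: Sequence[float] = (25.0, 50.0, 75.0),
) -> RecoveryRate:
    """Hemodynamic epoch value as percent of the pre-VF baseline."""
    if baseline_value <= 0:
        raise ValueError("baseline value must be positive")
    pct = 100.0 * epoch_value / baseline_value
    above = None if median_pct is None else bool(pct > median_pct)
    return RecoveryRate(pct, baseline_value, quartile_group(pct, edges), above)


def recovery_table(
    values_pct: Sequence[float],
    cfg: Optional[StatsConfig] = None,
) -> pd.DataFrame:
    """Group labels and median split for a set of epoch recovery rates.

    The split threshold is the analyzed epochs' own median unless the config
    fixes one; the threshold used is recorded in the frame's attrs.
    """
    cfg = cfg or StatsConfig()
    v = np.asarray(values_pct, dtype=float)
    thr = cfg.median_split_threshold
    if thr is None:
        thr = float(np.median(v))
    df = pd.DataFrame(
        {
            "recovery_pct": v,
            "quartile_group": [quartile_group(x, cfg.group_edges) for x in v],
            "above_median": v > thr,
        }
    )
    df.attrs["median_split_threshold"] = thr
    return df


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    feature: str
    r: float
    p_value: float
    n: int


def pearson(feature: Sequence[float], recovery: Sequence[float], name: str = "") -> CorrelationResult:
    """Pearson r with two-sided p from the t transform (NaNs removed pairwise)."""
    x = np.asarray(feature, dtype=float)
    y = np.asarray(recovery, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    res = sps.pearsonr(x, y)
    return CorrelationResult(name, float(res.statistic), float(res.pvalue), int(x.size))


# ---------------------------------------------------------------------------
# ANOVA and Dunnett T3
# ---------------------------------------------------------------------------

def one_way_anova(groups: Sequence[Sequence[float]]):
    """Classical one-way ANOVA: F, p, and group means.

    The between/within sum-of-squares decomposition is computed explicitly
    (total SS = between + within by construction); degenerate inputs
    (within-group SS of zero) raise rather than returning an infinite F.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs n >= 2")
    n_tot = sum(a.size for a in arrs)
    grand = np.concatenate(arrs).mean()
    means = np.array([a.mean() for a in arrs])
    ss_between = sum(a.size * (m - grand) ** 2 for a, m in zip(arrs, means))
    ss_within = sum(((a - m) ** 2).sum() for a, m in zip(arrs, means))
    df_b, df_w = len(arrs) - 1, n_tot - len(arrs)
    if ss_within <= 0:
        raise ValueError("degenerate ANOVA: zero within-group variance")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p, means


def smm_sf(q: float, k: int, df: float) -> float:
    """Tail of the studentized maximum modulus distribution.

    P(max of k independent |t|-type ratios sharing one chi denominator with
    ``df`` degrees of freedom exceeds q), by numerical integration over the
    chi mixture.  Accurate to ~1e-6, well inside the 1e-4 target.
    """
    if q <= 0:
        return 1.0
    rt = np.sqrt(df)

    def integrand(u: float) -> float:
        return (2.0 * sps.norm.cdf(q * u) - 1.0) ** k * sps.chi.pdf(u * rt, df) * rt

    cdf, _ = integrate.quad(integrand, 0.0, np.inf, limit=200, epsabs=1e-10)
    return float(min(max(1.0 - cdf, 0.0), 1.0))


@dataclass
class PostHocResult:
    group_pair: Tuple[int, int]
    mean_difference: float
    standard_error: float
    p_value: float


def dunnett_t3(groups: Sequence[Sequence[float]]) -> List[PostHocResult]:
    """Dunnett T3 pairwise comparisons for unequal variances.

    Each pair gets a Welch-type statistic with Welch-Satterthwaite degrees
    of freedom; the adjusted p-value refers |t| to the studentized maximum
    modulus distribution with k = number of pairwise comparisons.  Pairs
    with zero pooled variance are flagged (p = NaN) rather than dropped.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs n >= 2")
    pairs = [(i, j) for i in range(len(arrs)) for j in range(i + 1, len(arrs))]
    k = len(pairs)
    out = []
    for i, j in pairs:
        a, b = arrs[i], arrs[j]
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        diff = float(a.mean() - b.mean())
        se = float(np.sqrt(va + vb))
        if se == 0:
            logger.warning("degenerate pair (%d, %d): zero variance", i + 1, j + 1)
            out.append(PostHocResult((i + 1, j + 1), diff, 0.0, float("nan")))
            continue
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p = smm_sf(abs(diff) / se, k, df)
        out.append(PostHocResult((i + 1, j + 1), diff, se, p))
    return out


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    feature: str
    auc: float
    standard_error: float
    sensitivity: float
    fpr: float                  # 1 - specificity at the cut-off
    cut_off: float


def roc_analysis(feature: Sequence[float], above_median: Sequence[bool], name: str = "") -> RocResult:
    """Empirical ROC of a feature against the median-split labels.

    AUC by the trapezoid rule (identical to the normalized Mann-Whitney U
    statistic); standard error by Hanley-McNeil; the reported cut-off
    maximizes the Youden index J = sensitivity + specificity - 1, ties
    resolved toward higher specificity.  Higher feature values are scored as
    predicting the above-median class.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(above_median, dtype=bool)
    keep = np.isfinite(x)
    x, y = x[keep], y[keep]
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    fpr, tpr, thr = roc_curve(y, x)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    pick = best[np.argmin(fpr[best])]     # tie -> higher specificity
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    se = float(
        np.sqrt(
            (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2))
            / (n1 * n0)
        )
    )
    cut = float(thr[pick]) if np.isfinite(thr[pick]) else float(x.max())
    return RocResult(name, auc, se, float(tpr[pick]), float(fpr[pick]), cut)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class StatsReport:
    """The three association tables plus the run log entries behind them."""

    correlations: pd.DataFrame
    anova: pd.DataFrame
    posthoc: pd.DataFrame
    roc: pd.DataFrame
    log: dict = field(default_factory=dict)

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.anova.to_csv(out / "anova.csv", index=False)
        self.posthoc.to_csv(out / "anova_posthoc.csv", index=False)
        self.roc.to_csv(out / "roc.csv", index=False)


def build_report(
    features_df: pd.DataFrame,
    recovery_df: pd.DataFrame,
    cfg: Optional[StatsConfig] = None,
) -> StatsReport:
    """Full association analysis of a paired feature/recovery table.

    ``features_df`` has one row per epoch with the eleven feature columns;
    ``recovery_df`` is aligned row-for-row with ``recovery_pct``,
    ``quartile_group`` and ``above_median`` columns (see
    :func:`recovery_table`).  Correlations cover all eleven features; ANOVA,
    post hoc and ROC cover the configured selection.  Undefined feature
    values are excluded pairwise and counted in the log.
    """
    cfg = cfg or StatsConfig()
    if len(features_df) == 0:
        raise ValueError("empty feature table")
    if len(features_df) != len(recovery_df):
        raise ValueError("feature and recovery tables must align row-for-row")

    rec = recovery_df["recovery_pct"].to_numpy(float)
    n_undefined: Dict[str, int] = {}
    corr_rows = []
    for name in FEATURE_NAMES:
        x = features_df[name].to_numpy(float)
        n_undefined[name] = int(np.sum(~np.isfinite(x)))
        res = pearson(x, rec, name)
        corr_rows.append({"feature": name, "r": res.r, "p_value": res.p_value, "n": res.n})
    correlations = pd.DataFrame(corr_rows)

    anova_rows, posthoc_rows, roc_rows = [], [], []
    groups_lbl = recovery_df["quartile_group"].to_numpy(int)
    above = recovery_df["above_median"].to_numpy(bool)
    for name in cfg.selected_features:
        x = features_df[name].to_numpy(float)
        ok = np.isfinite(x)
        grp = [x[ok & (groups_lbl == g)] for g in sorted(set(groups_lbl))]
        grp = [g for g in grp if g.size >= 2]
        if len(grp) >= 2:
            f, p, means = one_way_anova(grp)
            anova_rows.append(
                {"feature": name, "F": f, "p_value": p,
                 **{f"mean_g{i + 1}": m for i, m in enumerate(means)}}
            )
            for ph in dunnett_t3(grp):
                posthoc_rows.append(
                    {"feature": name, "group_i": ph.group_pair[0],
                     "group_ii": ph.group_pair[1],
                     "mean_difference": ph.mean_difference,
                     "standard_error": ph.standard_error,
                     "p_value": ph.p_value}
                )
        r = roc_analysis(x, above, name) if ok.any() else None
        if r is not None:
            roc_rows.append(
                {"feature": name, "auc": r.auc, "standard_error": r.standard_error,
                 "sensitivity": r.sensitivity, "fpr": r.fpr, "cut_off": r.cut_off}
            )

    return StatsReport(
        correlations=correlations,
        anova=pd.DataFrame(anova_rows),
        posthoc=pd.DataFrame(posthoc_rows),
        roc=pd.DataFrame(roc_rows),
        log={
            "n_epochs": int(len(features_df)),
            "median_split_threshold": recovery_df.attrs.get("median_split_threshold"),
            "alpha": cfg.alpha,
            "n_undefined": n_undefined,
        },
    )
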