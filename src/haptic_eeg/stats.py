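"""Haptic vs non-haptic statistics: paired t-tests and accuracy growth rates.

Per (feature, band, pattern) cell, subjects' haptic and non-haptic accuracies
are compared with a two-sided paired-sample t-test at alpha = 0.05, and
summarised as the across-subject mean of the per-subject relative growth
(haptic - non-haptic) / non-haptic * 100.  No multiple-testing correction is
applied by default (an optional Holm adjustment is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bands import BAND_NAMES
from .classify import AccuracyTable

__all__ = [
    "StatResult",
    "paired_ttest",
    "growth_rates",
    "stats_grid",
    "growth_grid",
    "render_tables",
    "FEATURE_ORDER",
    "BAND_ROWS",
]

FEATURE_ORDER = ("PSD", "DE", "DASM", "DCAU")
BAND_ROWS = BAND_NAMES + ("total",)
ALPHA = 0.05


@dataclass(frozen=True)
class StatResult:
    t: float
    p: float
    df: int
    alpha: float = ALPHA
    degenerate: bool = False  # zero-variance differences: statistic undefined

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p < self.alpha


def paired_ttest(acc_non: np.ndarray, acc_hap: np.ndarray,
                 alpha: float = ALPHA) -> StatResult:
    """Two-sided paired-sample t-test on per-subject accuracy differences."""
    a = np.asarray(acc_non, float)
    b = np.asarray(acc_hap, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    if len(a) < 2:
        raise ValueError("need at least two subjects for a paired test")
    diffs = b - a
    if np.allclose(diffs.std(ddof=1), 0.0):
        return StatResult(np.nan, np.nan, len(a) - 1, alpha, degenerate=True)
    res = sps.ttest_rel(b, a)
    return StatResult(float(res.statistic), float(res.pvalue), len(a) - 1, alpha)


def growth_rates(acc_non: np.ndarray, acc_hap: np.ndarray) -> float:
    """Across-subject mean of per-subject relative accuracy growth (percent)."""
    a = np.asarray(acc_non, float)
    b = np.asarray(acc_hap, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    if np.any(a <= 0):
        raise ValueError("growth rate undefined for non-positive baseline accuracy")
    return float(np.mean((b - a) / a) * 100.0)


def _paired_vectors(acc: AccuracyTable, feature: str, band: str,
                    pattern: str) -> tuple[pd.Series, pd.Series]:
    non = acc.subject_accuracies(feature, band, pattern, "non-haptic")
    hap = acc.subject_accuracies(feature, band, pattern, "haptic")
    common = non.index.intersection(hap.index)
    return non.loc[common], hap.loc[common]


def stats_grid(acc: AccuracyTable, alpha: float = ALPHA,
               holm: bool = False) -> pd.DataFrame:
    """Paired t-test per (feature, band, pattern) cell of an accuracy table."""
    rows = []
    patterns = sorted(acc.table["pattern"].dropna().unique())
    for pattern in patterns:
        for feature in FEATURE_ORDER:
            for band in BAND_ROWS:
                non, hap = _paired_vectors(acc, feature, band, pattern)
                if len(non) < 2:
                    continue
                r = paired_ttest(non.to_numpy(), hap.to_numpy(), alpha)
                rows.append({"pattern": pattern, "feature": feature, "band": band,
                             "t": r.t, "p": r.p, "df": r.df,
                             "degenerate": r.degenerate})
    df = pd.DataFrame(rows, columns=["pattern", "feature", "band", "t", "p",
                                     "df", "degenerate"])
    if holm and len(df):
        order = np.argsort(df["p"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * df["p"].iloc[i])
            adj[i] = min(running, 1.0)
        df["p_holm"] = adj
    df["significant"] = (~df["degenerate"]) & (df["p"] < alpha)
    return df


def growth_grid(acc: AccuracyTable) -> pd.DataFrame:
    """Mean relative growth per (feature, band, pattern) cell."""
    rows = []
    for pattern in sorted(acc.table["pattern"].dropna().unique()):
        for feature in FEATURE_ORDER:
            for band in BAND_ROWS:
                non, hap = _paired_vectors(acc, feature, band, pattern)
                if len(non) == 0:
                    continue
                value = (np.nan if np.any(non.to_numpy() <= 0)
                         else growth_rates(non.to_numpy(), hap.to_numpy()))
                rows.append({"pattern": pattern, "feature": feature,
                             "band": band, "growth_pct": value})
    return pd.DataFrame(rows, columns=["pattern", "feature", "band",
                                       "growth_pct"])


def _wide(df: pd.DataFrame, value: str, pattern: str) -> pd.DataFrame:
    sel = df[df["pattern"] == pattern]
    wide = sel.pivot(index="band", columns="feature", values=value)
    wide = wide.reindex(index=list(BAND_ROWS),
                        columns=[f for f in FEATURE_ORDER if f in wide.columns])
    return wide


def render_tables(acc: AccuracyTable, stats: pd.DataFrame,
                  growth: pd.DataFrame, out_dir, alpha: float = ALPHA) -> dict:
    """Write the four report tables (mean accuracies per pattern, p-values,
    growth rates) as CSV plus a human-readable summary; NA marks absent cells.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patterns = sorted(acc.table["pattern"].dropna().unique())

    mean_acc = (acc.table.groupby(["pattern", "feature", "band", "condition"],
                                  dropna=False)["accuracy"].mean().reset_index())
    files = {}
    for i, pattern in enumerate(patterns):
        sel = mean_acc[mean_acc["pattern"] == pattern]
        wide = sel.pivot(index="band", columns=["feature", "condition"],
                         values="accuracy")
        cols = [(f, c) for f in FEATURE_ORDER for c in ("non-haptic", "haptic")
                if (f, c) in wide.columns]
        wide = wide.reindex(index=list(BAND_ROWS), columns=pd.MultiIndex.from_tuples(cols))
        path = out_dir / f"accuracy_{pattern}.csv"
        wide.round(2).to_csv(path, na_rep="NA")
        files[f"accuracy_{pattern}"] = path

    pwide = pd.concat({p: _wide(stats, "p", p) for p in patterns}, axis=1)
    ppath = out_dir / "paired_ttest.csv"
    pwide.round(4).to_csv(ppath, na_rep="NA")
    files["paired_ttest"] = ppath

    gwide = pd.concat({p: _wide(growth, "growth_pct", p) for p in patterns}, axis=1)
    gpath = out_dir / "growth_rates.csv"
    gwide.round(2).to_csv(gpath, na_rep="NA")
    files["growth_rates"] = gpath

    lines = [f"Haptic vs non-haptic summary (alpha = {alpha})", ""]
    for _, row in stats.iterrows():
        mark = " *" if row["significant"] else ""
        lines.append(f"{row['pattern']:>8} {row['feature']:>5} {row['band']:>6}: "
                     f"t = {row['t']:+.3f}, p = {row['p']:.4f}{mark}")
    spath = out_dir / "summary.txt"
    spath.write_text("\n".join(lines) + "\n")
    files["summary"] = spath
    return files
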