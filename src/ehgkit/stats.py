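"""Paired nonparametric comparison of fast-wave vs enhanced channel metrics.

Channel metric differences are not normally distributed, so arms are
summarised as median and interquartile range and compared with the
two-sided Wilcoxon signed-rank test on per-channel pairs (zero differences
dropped, tied ranks averaged). The exact null distribution is used up to
n = 25 non-zero differences; above that, the normal approximation with
continuity correction. Significance is declared at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "median_iqr",
    "wilcoxon_signed_rank",
    "PairedComparison",
    "compare_bands",
]

ALPHA = 0.05
EXACT_MAX_N = 25
METRIC_COLUMNS = ("skewness", "kurtosis", "paer")


def median_iqr(values: np.ndarray) -> tuple[float, float]:
    """Median and interquartile range (linear-interpolation quantiles)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("median/IQR of an empty sample")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return float(med), float(q3 - q1)


@dataclass
class PairedComparison:
    """Wilcoxon signed-rank comparison of one metric between two arms."""

    metric: str
    group: str
    n_pairs: int
    n_nonzero: int
    statistic: float
    p_value: float
    median_fast: float
    iqr_fast: float
    median_enhanced: float
    iqr_enhanced: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def wilcoxon_signed_rank(fast: np.ndarray, enhanced: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Returns (W, p) where W is the signed-rank statistic reported by scipy.
    Zero differences are dropped; all-zero differences are an error (the
    test is undefined when the arms are identical).
    """
    fast = np.asarray(fast, dtype=float)
    enhanced = np.asarray(enhanced, dtype=float)
    if fast.shape != enhanced.shape:
        raise ValueError("paired arms must have equal length")
    d = enhanced - fast
    nz = int(np.count_nonzero(d))
    if nz == 0:
        raise ValueError("all paired differences are zero; test undefined")
    method = "exact" if nz <= EXACT_MAX_N else "approx"
    res = sps.wilcoxon(
        enhanced,
        fast,
        zero_method="wilcox",
        correction=True,
        alternative="two-sided",
        method=method,
    )
    return float(res.statistic), float(res.pvalue)


def compare_bands(
    metrics_fast: pd.DataFrame,
    metrics_enhanced: pd.DataFrame,
    group: str = "pooled",
) -> list[PairedComparison]:
    """Per-metric paired comparisons between the fast and enhanced arms.

    Both tables need ``channel_id`` plus the metric columns; with
    ``group="per-subject"`` they also need a ``subject`` column and one
    comparison is produced per metric per subject. Pooled analysis simply
    concatenates all channel pairs. Channels present in one arm only are an
    error (pairing would be broken).
    """
    if group not in ("pooled", "per-subject"):
        raise ValueError(f"unknown grouping {group!r}")
    key = ["subject", "channel_id"] if group == "per-subject" else ["channel_id"]
    for tab, name in ((metrics_fast, "fast"), (metrics_enhanced, "enhanced")):
        missing = [c for c in key + list(METRIC_COLUMNS) if c not in tab.columns]
        if missing:
            raise ValueError(f"{name} metrics table missing columns {missing}")
    kf = set(map(tuple, metrics_fast[key].astype(str).itertuples(index=False)))
    ke = set(map(tuple, metrics_enhanced[key].astype(str).itertuples(index=False)))
    if kf != ke:
        raise ValueError(f"unmatched channels between arms: {sorted(kf ^ ke)}")
    merged = metrics_fast.merge(
        metrics_enhanced, on=key, suffixes=("_fast", "_enh"), validate="1:1"
    )
    groups = (
        [(str(s), g) for s, g in merged.groupby("subject")]
        if group == "per-subject"
        else [("pooled", merged)]
    )
    out: list[PairedComparison] = []
    for gname, g in groups:
        for metric in METRIC_COLUMNS:
            f = g[f"{metric}_fast"].to_numpy()
            e = g[f"{metric}_enh"].to_numpy()
            w, p = wilcoxon_signed_rank(f, e)
            mf, if_ = median_iqr(f)
            me, ie = median_iqr(e)
            out.append(
                PairedComparison(
                    metric, gname, len(g), int(np.count_nonzero(e - f)), w, p,
                    mf, if_, me, ie,
                )
            )
    return out


def comparisons_frame(comparisons: list[PairedComparison]) -> pd.DataFrame:
    """Tabular form of :func:`compare_bands` output."""
    return pd.DataFrame(
        [
            {
                "group": c.group,
                "metric": c.metric,
                "n_pairs": c.n_pairs,
                "W": c.statistic,
                "p_value": c.p_value,
                "median_fast": c.median_fast,
                "iqr_fast": c.iqr_fast,
                "median_enhanced": c.median_enhanced,
                "iqr_enhanced": c.iqr_enhanced,
                "significant": c.significant,
            }
            for c in comparisons
        ]
    )
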