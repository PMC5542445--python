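"""Group statistics: mean ± SEM, Mann–Whitney U, Pearson correlation.

The layer mirrors how small-animal imaging studies are summarised: group
means with standard errors, unpaired two-tailed Mann–Whitney tests between
time points (group sizes are typically n = 5, so the exact U distribution
is enumerated whenever feasible), and Pearson correlations between imaging
and reference measurements, labelled with conventional strength bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "mean_sem",
    "mann_whitney",
    "pearson",
    "classify_r",
    "group_trajectory",
    "GROUP_LABELS",
]

GROUP_LABELS = ("progression", "regression", "wildtype")

#: |r| strength bands, half-open at the top of each lower band so that the
#: boundary value belongs to the weaker category (0.4 is "fair").
_BANDS = (
    (0.8, "strong"),
    (0.6, "substantial"),
    (0.4, "moderate"),
    (0.2, "fair"),
    (0.0, "almost non-existent"),
)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    category: str


def mean_sem(values) -> tuple[float, float]:
    """Sample mean and standard error of the mean (sample SD / sqrt(n))."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("mean_sem requires at least 2 values")
    return float(values.mean()), float(sps.sem(values, ddof=1))


def mann_whitney(a, b, exact_max_n: int = 8) -> tuple[float, float]:
    """Unpaired two-tailed Mann–Whitney U test.

    The exact null distribution is enumerated when the smaller group has at
    most ``exact_max_n`` observations and there are no ties; otherwise the
    tie-corrected normal approximation is used.  Returns (U of the first
    group, two-tailed p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(a.size, b.size) <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def classify_r(r: float) -> str:
    """Conventional strength label of a correlation coefficient (on |r|)."""
    mag = abs(float(r))
    if mag > 1:
        raise ValueError("|r| cannot exceed 1")
    for lo, name in _BANDS:
        if mag > lo:
            return name
    return _BANDS[-1][1]


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided p-value.

    The p-value comes from the t transform with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson requires at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("pearson requires finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for a constant variable")
    res = sps.pearsonr(x, y)
    r = float(np.clip(res.statistic, -1.0, 1.0))
    return CorrelationResult(r=r, p=float(res.pvalue), n=int(x.size), category=classify_r(r))


def group_trajectory(
    table: pd.DataFrame,
    measure: str,
    group: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-week mean ± SEM of one measure, with a Mann–Whitney test of each
    time point against the preceding one.

    ``table`` needs columns ``week`` and ``measure`` (and ``group`` when a
    group filter is given).  Returns one row per week with columns
    ``week, n, mean, sem, p_vs_previous, significant``.
    """
    if measure not in table.columns:
        raise ValueError(f"measure {measure!r} not in table")
    df = table if group is None else table[table["group"] == group]
    df = df.dropna(subset=[measure])
    weeks = sorted(df["week"].unique())
    if len(weeks) < 2:
        raise ValueError("group_trajectory requires at least 2 time points")
    rows = []
    prev_values = None
    for week in weeks:
        values = df.loc[df["week"] == week, measure].to_numpy(dtype=float)
        m, s = mean_sem(values)
        if prev_values is None:
            p = np.nan
        else:
            _, p = mann_whitney(values, prev_values)
        rows.append(
            {
                "week": week,
                "n": len(values),
                "mean": m,
                "sem": s,
                "p_vs_previous": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
        prev_values = values
    return pd.DataFrame(rows)
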