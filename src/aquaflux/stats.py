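"""Two-group statistics used across the pipeline.

Two-sample (pooled-variance by default, Welch optional) and paired t tests,
the Mann-Whitney U rank test (exact when feasible), and step-down
Bonferroni-Holm adjustment.  All tests are two-sided.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "t_test",
    "mann_whitney_u",
    "holm_adjust",
    "significance_stars",
    "group_compare",
]


@dataclass(frozen=True)
class StatResult:
    """One two-group comparison: statistic, two-sided p, sample sizes."""

    test: str
    statistic: float
    pvalue: float
    n1: int
    n2: int
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.pvalue - 1e-12:
            raise ValueError("adjusted p cannot be below the raw p")


def t_test(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
    equal_var: bool = True,
) -> StatResult:
    """Two-sided t test (classic pooled-variance unpaired, or paired).

    Degenerate case: zero variance everywhere with equal means returns
    t = 0, p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal-length samples")
        if x.size < 2:
            raise ValueError("paired test requires >= 2 pairs")
        d = x - y
        if np.all(d == d[0]) and d[0] == 0:
            return StatResult("paired t", 0.0, 1.0, x.size, y.size)
        stat, p = sps.ttest_rel(x, y)
        name = "paired t"
    else:
        if x.size < 2 or y.size < 2:
            raise ValueError("two-sample test requires >= 2 per group")
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            if x.mean() == y.mean():
                return StatResult("two-sample t", 0.0, 1.0, x.size, y.size)
        stat, p = sps.ttest_ind(x, y, equal_var=equal_var)
        name = "two-sample t" if equal_var else "Welch t"
    return StatResult(name, float(stat), float(p), x.size, y.size)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum) test.

    U is the statistic of the first sample, from rank sums with mid-ranks
    for ties.  The p value is exact (distribution enumeration) when
    n1 + n2 <= 12 and no ties are present, otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    If every value is identical, U = n1·n2/2 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each group needs >= 1 observation")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return StatResult("Mann-Whitney U", x.size * y.size / 2.0, 1.0, x.size, y.size)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and x.size + y.size <= 12) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return StatResult("Mann-Whitney U", float(res.statistic), float(min(res.pvalue, 1.0)), x.size, y.size)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Step-down Bonferroni-Holm adjusted p values, in the input order.

    adjusted_(k) = max_{j<=k} min(1, (m-j+1) * p_(j)) over the ascending
    order statistics p_(1) <= ... <= p_(m).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adjusted_sorted = np.maximum.accumulate(scaled)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def significance_stars(p: float) -> str:
    """Figure-style stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def group_compare(
    df: pd.DataFrame,
    test: str = "t",
    paired: bool = False,
) -> pd.DataFrame:
    """Compare two groups per family from a long-format table.

    ``df`` columns: ``group`` (exactly two levels per family), ``value``,
    optional ``pair_id`` (for paired tests) and ``family`` (one comparison
    per family; Holm adjustment is applied across families).  Returns one
    row per family with statistic, raw p, Holm-adjusted p, and stars.
    """
    if "family" not in df.columns:
        df = df.assign(family="all")
    rows = []
    for fam, sub in df.groupby("family", sort=False):
        groups = list(pd.unique(sub["group"]))
        if len(groups) != 2:
            raise ValueError(f"family {fam!r}: need exactly two groups, got {groups}")
        if paired:
            if "pair_id" not in sub.columns:
                raise ValueError("paired comparison requires a pair_id column")
            wide = sub.pivot(index="pair_id", columns="group", values="value").dropna()
            a, b = wide[groups[0]].to_numpy(), wide[groups[1]].to_numpy()
        else:
            a = sub.loc[sub["group"] == groups[0], "value"].to_numpy()
            b = sub.loc[sub["group"] == groups[1], "value"].to_numpy()
        if test == "t":
            res = t_test(a, b, paired=paired)
        elif test in ("mannwhitney", "mw", "u"):
            res = mann_whitney_u(a, b)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "family": fam,
                "test": res.test,
                "group1": groups[0],
                "group2": groups[1],
                "n1": res.n1,
                "n2": res.n2,
                "statistic": res.statistic,
                "pvalue": res.pvalue,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = holm_adjust(out["pvalue"].to_numpy())
    out["stars"] = [significance_stars(p) for p in out["p_adjusted"]]
    return out
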