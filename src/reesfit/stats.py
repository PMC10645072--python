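"""Group comparison and correlation statistics.

Thin, validated wrappers around the classical tests used to compare
antibody groups: one-way ANOVA (between/within mean-square F), Tukey
honestly-significant-difference post hoc pairwise comparisons, and the
Pearson correlation with its two-sided t-based p-value.  Group
comparisons of fitted REES parameters are done at replicate level;
correlations against SASA per Trp use per-sample triplicate averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedValues",
    "AnovaResult",
    "CorrelationResult",
    "one_way_anova",
    "tukey_hsd",
    "pearson",
    "group_scatter_plot",
]


@dataclass(frozen=True)
class GroupedValues:
    """One measured quantity with a group label per observation."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if len(self.labels) != values.size:
            raise ValueError("labels and values must have equal length")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", values)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_col: str, value_col: str) -> "GroupedValues":
        return cls(tuple(df[label_col].astype(str)), df[value_col].to_numpy(dtype=float))

    def by_group(self) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {}
        for lab, val in zip(self.labels, self.values):
            out.setdefault(lab, []).append(val)
        return {k: np.array(v) for k, v in out.items()}


def _check_anova_groups(groups: dict[str, np.ndarray]) -> None:
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for label, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {label!r} has fewer than two observations")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int


def one_way_anova(data: GroupedValues) -> AnovaResult:
    """Classical (non-Welch) one-way ANOVA."""
    groups = data.by_group()
    _check_anova_groups(groups)
    F, p = sps.f_oneway(*groups.values())
    k = len(groups)
    n = data.values.size
    return AnovaResult(F=float(F), p=float(p), df_between=k - 1, df_within=n - k)


def tukey_hsd(data: GroupedValues, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (studentized range).

    Returns one row per unordered pair: group_a, group_b, mean_diff,
    p_adj, ci_low, ci_high, significant (at ``alpha``).
    """
    groups = data.by_group()
    _check_anova_groups(groups)
    labels = list(groups)
    res = sps.tukey_hsd(*groups.values())
    ci = res.confidence_interval(confidence_level=1.0 - alpha)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(groups[labels[i]].mean() - groups[labels[j]].mean()),
                    "p_adj": float(res.pvalue[i, j]),
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                    "significant": bool(res.pvalue[i, j] < alpha),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations for a p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=int(x.size))


def group_scatter_plot(df: pd.DataFrame, x: str, y: str, group: str = "group", ax=None):
    """Scatter of two quantities coloured by group, with group means
    and sd error bars overlaid.

    A plain summary view of the group separation (e.g. CSM(lambda_Ex,FC)
    against the slope term); returns the matplotlib axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, sub in df.groupby(group):
        ax.scatter(sub[x], sub[y], s=18, alpha=0.6, label=str(label))
        ax.errorbar(
            sub[x].mean(), sub[y].mean(),
            xerr=sub[x].std(ddof=1) if len(sub) > 1 else 0.0,
            yerr=sub[y].std(ddof=1) if len(sub) > 1 else 0.0,
            fmt="o", color="black", capsize=3, zorder=3,
        )
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.legend()
    return ax
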