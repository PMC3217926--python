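"""Extreme-behavior groups, empirical CDFs and Kolmogorov-Smirnov ranking.

The two behavioral groups are the top fraction (default 2%) of valid
parameter sets by talin:integrin complex formation (group 1, criterion c2)
and by Dok1:integrin complex formation (group 2, criterion c1).  For every
sampled parameter three KS statistics are computed: group 1 vs the analytic
log-uniform sampling law, group 2 vs the sampling law, and group 1 vs
group 2; parameters are ranked by the largest of the three.  Characteristic
group parameter sets are geometric means (the centroid on the log scale the
sampling uses).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ensemble import ParameterSpace
from .model import ParameterSet

__all__ = [
    "GroupSelection",
    "ECDF",
    "select_groups",
    "ecdf",
    "ks_statistic",
    "ks_statistic_to_cdf",
    "rank_parameters",
    "group_mean_parameters",
]


@dataclass
class GroupSelection:
    group1: np.ndarray   # sample ids, top c2 (TAL:INT)
    group2: np.ndarray   # sample ids, top c1 (DOK:INT)
    fraction: float


def select_groups(criteria: pd.DataFrame, fraction: float = 0.02) -> GroupSelection:
    """Deterministic top-fraction selection on c2 (group 1) and c1 (group 2).

    Rows flagged invalid are excluded; ties are broken by sample id.
    """
    valid = criteria[criteria["valid"].astype(bool)]
    size = round(fraction * len(valid))
    if size < 1:
        raise ValueError(
            f"fraction {fraction} of {len(valid)} valid rows selects nothing"
        )

    def top(column: str) -> np.ndarray:
        df = valid[[column]].copy()
        df["_id"] = df.index
        df = df.sort_values([column, "_id"], ascending=[False, True], kind="mergesort")
        return df.index.to_numpy()[:size]

    return GroupSelection(group1=top("c2"), group2=top("c1"), fraction=fraction)


class ECDF:
    """Right-continuous empirical distribution function F(x) = #{v <= x}/n."""

    def __init__(self, values: Sequence[float]):
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError("ECDF of an empty sample")
        self.x = np.sort(v)
        self.n = v.size

    def __call__(self, x) -> np.ndarray:
        return np.searchsorted(self.x, np.asarray(x, dtype=float), side="right") / self.n


def ecdf(values: Sequence[float]) -> ECDF:
    return ECDF(values)


def ks_statistic(sample1: Sequence[float], sample2: Sequence[float]) -> float:
    """Two-sample KS distance: sup over the pooled jump points of |F1 - F2|,
    evaluated on both sides of each jump."""
    f1, f2 = ECDF(sample1), ECDF(sample2)
    pts = np.unique(np.concatenate([f1.x, f2.x]))
    d_right = np.abs(f1(pts) - f2(pts))
    left1 = np.searchsorted(f1.x, pts, side="left") / f1.n
    left2 = np.searchsorted(f2.x, pts, side="left") / f2.n
    d_left = np.abs(left1 - left2)
    return float(max(d_right.max(), d_left.max()))


def ks_statistic_to_cdf(sample: Sequence[float], cdf: Callable) -> float:
    """One-sample KS distance against a continuous CDF (exact sup)."""
    f = ECDF(sample)
    c = np.asarray(cdf(f.x), dtype=float)
    n = f.n
    upper = np.abs(np.arange(1, n + 1) / n - c)
    lower = np.abs(np.arange(0, n) / n - c)
    return float(max(upper.max(), lower.max()))


def rank_parameters(
    samples: pd.DataFrame,
    groups: GroupSelection,
    space: ParameterSpace,
    against: str = "analytic",
) -> pd.DataFrame:
    """Influence table: D_g1, D_g2, D_12 and rank per sampled parameter.

    ``against='analytic'`` compares the groups with the exact log-uniform
    sampling CDF; ``against='empirical'`` uses the full-sample ECDF instead.
    """
    if against not in ("analytic", "empirical"):
        raise ValueError("against must be 'analytic' or 'empirical'")
    rows = []
    for symbol in space.sampled_symbols:
        g1 = samples.loc[groups.group1, symbol].to_numpy()
        g2 = samples.loc[groups.group2, symbol].to_numpy()
        if against == "analytic":
            cdf = lambda x, s=symbol: space.log_uniform_cdf(s, x)
            d1 = ks_statistic_to_cdf(g1, cdf)
            d2 = ks_statistic_to_cdf(g2, cdf)
        else:
            full = samples[symbol].to_numpy()
            d1 = ks_statistic(g1, full)
            d2 = ks_statistic(g2, full)
        d12 = ks_statistic(g1, g2)
        rows.append(
            {"parameter": symbol, "D_g1": d1, "D_g2": d2, "D_12": d12,
             "D_max": max(d1, d2, d12)}
        )
    df = pd.DataFrame(rows).set_index("parameter")
    df["rank"] = (
        df["D_max"].rank(ascending=False, method="first").astype(int)
    )
    return df.sort_values("rank")


def group_mean_parameters(
    samples: pd.DataFrame, group: np.ndarray, space: ParameterSpace | None = None
) -> ParameterSet:
    """The characteristic parameter set of a group: per-parameter geometric
    mean (the arithmetic mean on the sampling's log scale)."""
    if len(group) == 0:
        raise ValueError("empty group")
    sub = samples.loc[group]
    vals = np.exp(np.log(sub.to_numpy()).mean(axis=0))
    return ParameterSet(dict(zip(samples.columns, vals)))
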