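"""Reporting statistics: correlation, regression, ANOVA/Tukey letters, paired summaries.

Thin wrappers over scipy/statsmodels that return results in the shapes a
horticultural table expects: r^2 with significance stars, OLS slope with
its standard error, group means with compact letter displays from the
Tukey studentized-range test, and paired treatment/control summaries for
same-fruit comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)


def significance_stars(p_value: float) -> str:
    """Conventional star coding: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class CorrelationResult:
    r2: float
    p_value: float
    stars: str
    n: int


@dataclass(frozen=True)
class LinearFit:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r2: float
    n: int


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Squared Pearson correlation with significance stars."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("inputs must not be constant")
    res = scipy.stats.pearsonr(x, y)
    return CorrelationResult(
        r2=float(res.statistic**2),
        p_value=float(res.pvalue),
        stars=significance_stars(float(res.pvalue)),
        n=int(x.size),
    )


def linear_fit(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares y = slope * x + intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFit(
        slope=float(model.params[1]),
        slope_se=float(model.bse[1]),
        intercept=float(model.params[0]),
        intercept_se=float(model.bse[0]),
        r2=float(model.rsquared),
        n=int(x.size),
    )


def _compact_letters(
    names_by_mean: Sequence[str], distinct: set[frozenset]
) -> dict[str, str]:
    """Compact letter display by the insert-absorb algorithm.

    ``distinct`` holds the pairs found significantly different.  Letters
    are assigned in ascending-mean order starting at 'a'; groups sharing a
    letter are not significantly different.
    """
    columns: list[set[str]] = [set(names_by_mean)]
    for pair in distinct:
        i, j = tuple(pair)
        new_cols: list[set[str]] = []
        for col in columns:
            if i in col and j in col:
                new_cols.append(col - {i})
                new_cols.append(col - {j})
            else:
                new_cols.append(col)
        # absorb columns that are subsets of another
        columns = [
            c
            for idx, c in enumerate(new_cols)
            if c
            and not any(
                c < other or (c == other and idx > jdx)
                for jdx, other in enumerate(new_cols)
            )
        ]
    rank = {name: i for i, name in enumerate(names_by_mean)}
    columns.sort(key=lambda c: min(rank[n] for n in c))
    letters: dict[str, str] = {name: "" for name in names_by_mean}
    for li, col in enumerate(columns):
        letter = chr(ord("a") + li)
        for name in col:
            letters[name] += letter
    return {name: "".join(sorted(v)) for name, v in letters.items()}


def _to_long(g) -> pd.DataFrame:
    if isinstance(g, pd.DataFrame):
        if not {"group", "value"} <= set(g.columns):
            raise ValueError("DataFrame input needs 'group' and 'value' columns")
        return g[["group", "value"]].copy()
    rows = [
        {"group": str(name), "value": float(v)}
        for name, values in g.items()
        for v in np.asarray(values, dtype=float)
    ]
    return pd.DataFrame(rows)


def anova_tukey_letters(
    groups: Mapping[str, Sequence[float]] | pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-group mean +/- SE with Tukey HSD compact letters.

    Accepts a mapping ``{group: values}`` or a long DataFrame with
    ``group`` and ``value`` columns.  Groups sharing a letter are not
    significantly different under the Tukey studentized-range test at
    ``alpha``.  If every group has zero variance the test is degenerate
    and all groups share 'a' (with a warning).
    """
    df = _to_long(groups)
    counts = df.groupby("group")["value"].count()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 values")

    summary = (
        df.groupby("group")["value"]
        .agg(
            n="count",
            mean="mean",
            se=lambda v: v.std(ddof=1) / math.sqrt(len(v)),
        )
        .sort_values("mean")
        .reset_index()
    )
    names_by_mean = list(summary["group"])

    pooled_var = df.groupby("group")["value"].var(ddof=1).sum()
    if pooled_var == 0:
        logger.warning("all groups have zero variance; Tukey test degenerate")
        summary["letter"] = "a"
        return summary

    tukey = pairwise_tukeyhsd(df["value"].to_numpy(), df["group"].to_numpy(), alpha)
    group_names = [str(gname) for gname in tukey.groupsunique]
    distinct = {
        frozenset((group_names[i], group_names[j]))
        for (i, j), reject in zip(
            combinations(range(len(group_names)), 2), tukey.reject
        )
        if reject
    }
    letters = _compact_letters(names_by_mean, distinct)
    summary["letter"] = summary["group"].map(letters)
    return summary


def paired_effect(
    df: pd.DataFrame,
    value: str = "value",
    time: str = "dafb",
    pair: str = "pair_id",
    arm: str = "arm",
    treatment: str = "treated",
    control: str = "control",
) -> pd.DataFrame:
    """Per-time treatment/control means +/- SE and mean paired difference.

    Expects long data with one treated and one control row per pair and
    time point (the two cheeks of the same fruit).  An incomplete pair
    raises an error naming it.  Output rows are indexed by time with
    treated/control summaries, the mean within-pair difference and its SE.
    """
    required = {value, time, pair, arm}
    if not required <= set(df.columns):
        raise ValueError(f"input needs columns {sorted(required)}")
    out_rows = []
    for t_val, chunk in sorted(df.groupby(time), key=lambda kv: kv[0]):
        wide = chunk.pivot_table(
            index=pair, columns=arm, values=value, aggfunc="first"
        )
        for arm_name in (treatment, control):
            if arm_name not in wide.columns:
                raise ValueError(f"no {arm_name!r} records at {time}={t_val}")
        bad = wide.index[wide[[treatment, control]].isna().any(axis=1)]
        if len(bad):
            raise ValueError(
                f"unpaired record: pair {bad[0]!r} incomplete at {time}={t_val}"
            )
        tr = wide[treatment].to_numpy(dtype=float)
        ct = wide[control].to_numpy(dtype=float)
        diff = tr - ct
        n = diff.size
        se = lambda v: float(np.std(v, ddof=1) / math.sqrt(len(v))) if n >= 2 else np.nan
        out_rows.append(
            {
                time: t_val,
                "n_pairs": n,
                "treated_mean": float(tr.mean()),
                "treated_se": se(tr),
                "control_mean": float(ct.mean()),
                "control_se": se(ct),
                "mean_diff": float(diff.mean()),
                "diff_se": se(diff),
            }
        )
    return pd.DataFrame(out_rows).set_index(time)
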