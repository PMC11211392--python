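"""Two-group statistical comparison of per-image parameter tables.

For each of the twelve parameters: D'Agostino-Pearson normality per
group, an unpaired two-sided Student's t-test (pooled variance; Welch
optional), 95% confidence half-widths of the group means, and a star
significance tier at the conventional cutpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .image_io import PARAMETER_NAMES

logger = logging.getLogger(__name__)

TIER_CUTPOINTS = [
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
]

COMPARISON_COLUMNS = [
    "parameter", "n1", "n2", "mean1", "mean2", "ci95_1", "ci95_2",
    "t_stat", "p_value", "normal1", "normal2", "tier",
]


def significance_tier(p: float) -> str:
    """Star tier for a p-value: **** / *** / ** / * / ns."""
    if not np.isfinite(p):
        return "ns"
    for cut, stars in TIER_CUTPOINTS:
        if p < cut:
            return stars
    return "ns"


def dagostino_pearson(sample) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus normality test.

    K2 combines the skewness and kurtosis z-transforms; the p-value is
    two-sided from chi-square with 2 degrees of freedom. Requires n >= 20
    for the z-approximations to hold.
    """
    x = np.asarray(sample, dtype=np.float64)
    if x.size < 20:
        raise ValueError(f"insufficient sample for normality test (n={x.size} < 20)")
    if np.var(x) == 0:
        raise ValueError("zero-variance sample: normality test undefined")
    k2, p = stats.normaltest(x)
    return float(k2), float(p)


def students_t(group_a, group_b, welch: bool = False) -> tuple[float, float, float]:
    """Unpaired two-sided Student's t-test; returns (t, p, df).

    Pooled variance by default (df = n1 + n2 - 2); Welch's unequal
    variance correction behind the ``welch`` flag.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not welch and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, float(a.size + b.size - 2)
        raise ValueError("zero pooled variance with unequal means: t is undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue), float(res.df)


def mean_ci_halfwidth(sample, confidence: float = 0.95) -> float:
    """t-distribution confidence half-width of a sample mean."""
    x = np.asarray(sample, dtype=np.float64)
    if x.size < 2:
        return np.nan
    sem = x.std(ddof=1) / np.sqrt(x.size)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=x.size - 1)
    return float(tcrit * sem)


@dataclass
class ComparisonTable:
    """Per-parameter comparison rows plus the headline significance count."""

    rows: pd.DataFrame
    n_significant: int
    alpha: float = 0.05
    n_evaluated: int = field(default=len(PARAMETER_NAMES))

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.12g")

    def summary(self) -> str:
        return (
            f"{self.n_significant} of {self.n_evaluated} parameters significant "
            f"at p < {self.alpha:g}"
        )


def compare_parameter_tables(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    alpha: float = 0.05,
    welch: bool = False,
    correction: str | None = None,
) -> ComparisonTable:
    """Compare two parameter tables parameter-by-parameter.

    Rows with undefined (NaN) values are dropped per parameter with a
    logged count. A parameter with fewer than 3 defined values in either
    group is flagged insufficient and excluded from the significance
    denominator. ``correction`` may be 'bonferroni' or 'holm' (off by
    default: each parameter is tested at ``alpha``).
    """
    records = []
    usable = []
    for name in PARAMETER_NAMES:
        a = pd.to_numeric(table_a[name], errors="coerce").to_numpy(dtype=np.float64)
        b = pd.to_numeric(table_b[name], errors="coerce").to_numpy(dtype=np.float64)
        a_clean, b_clean = a[np.isfinite(a)], b[np.isfinite(b)]
        dropped = (a.size - a_clean.size) + (b.size - b_clean.size)
        if dropped:
            logger.info("parameter %s: dropped %d undefined value(s)", name, dropped)
        rec = {
            "parameter": name,
            "n1": int(a_clean.size),
            "n2": int(b_clean.size),
            "mean1": float(a_clean.mean()) if a_clean.size else np.nan,
            "mean2": float(b_clean.mean()) if b_clean.size else np.nan,
            "ci95_1": mean_ci_halfwidth(a_clean),
            "ci95_2": mean_ci_halfwidth(b_clean),
        }
        if a_clean.size < 3 or b_clean.size < 3:
            logger.warning("parameter %s: insufficient data, excluded", name)
            rec.update(t_stat=np.nan, p_value=np.nan, normal1=None, normal2=None,
                       tier="insufficient data")
            records.append(rec)
            continue
        usable.append(name)
        try:
            t_stat, p_value, _ = students_t(a_clean, b_clean, welch=welch)
        except ValueError:
            t_stat, p_value = np.nan, np.nan

        def _normal_flag(x):
            try:
                _, p_norm = dagostino_pearson(x)
            except ValueError:
                return None
            return bool(p_norm > 0.05)

        rec.update(
            t_stat=t_stat,
            p_value=p_value,
            normal1=_normal_flag(a_clean),
            normal2=_normal_flag(b_clean),
        )
        records.append(rec)

    df = pd.DataFrame.from_records(records)
    pvals = df.set_index("parameter").loc[usable, "p_value"]
    adjusted = pvals.copy()
    if correction == "bonferroni":
        adjusted = np.minimum(pvals * len(usable), 1.0)
    elif correction == "holm":
        order = np.argsort(pvals.to_numpy())
        m = len(usable)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min((m - rank) * pvals.iloc[idx], 1.0))
            adj[idx] = running
        adjusted = pd.Series(adj, index=pvals.index)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")

    tier_map = {name: significance_tier(adjusted[name]) for name in usable}
    df["tier"] = df.apply(
        lambda row: tier_map.get(row["parameter"], row.get("tier", "ns")), axis=1
    )
    n_significant = int(sum(adjusted[name] < alpha for name in usable))
    return ComparisonTable(
        rows=df[COMPARISON_COLUMNS],
        n_significant=n_significant,
        alpha=alpha,
        n_evaluated=len(usable),
    )
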