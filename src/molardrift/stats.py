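"""Cohort and repeatability statistics for tooth-level drift outcomes.

Covers the statistics used in clinical overeruption studies: one-sample
t-tests of each outcome against zero, one-way ANOVA across molar types,
descriptive frequency tables, the Dahlberg combined method error for
duplicate measurement sessions, and the two-way mixed single-measure
consistency ICC (ICC(3,1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "AnovaResult",
    "one_sample_t",
    "one_sample_t_from_summary",
    "one_way_anova",
    "dahlberg_error",
    "icc_two_way_mixed",
    "descriptive_table",
    "round_percent",
]

MOLAR_TYPES = ("upper-first", "upper-second", "lower-first", "lower-second")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float

    @property
    def significant(self) -> bool:
        """Decision at the study's alpha = 0.05."""
        return self.p < 0.05


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """Two-sided one-sample t-test of ``values`` against ``mu0``."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance; t statistic is undefined")
    res = sps.ttest_1samp(x, popmean=mu0)
    return TTestResult(float(res.statistic), int(len(x) - 1), float(res.pvalue))


def one_sample_t_from_summary(mean: float, sd: float, n: int, mu0: float = 0.0) -> TTestResult:
    """Same test recomputed from summary statistics (mean, sd, n)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    t = (mean - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p))


def one_way_anova(table: pd.DataFrame, outcome: str, group: str = "molar_type") -> AnovaResult:
    """One-way ANOVA of ``outcome`` across the levels of ``group``.

    Groups with fewer than two observations are excluded with a warning.
    All-equal data (zero within-group variance and zero between-group
    variance) leaves F undefined and raises.
    """
    groups = []
    for level, sub in table.groupby(group, observed=True):
        vals = np.asarray(sub[outcome].dropna(), dtype=float)
        if len(vals) < 2:
            warnings.warn(f"group {level!r} has < 2 observations; excluded")
            continue
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError("need at least two groups with >= 2 observations")
    pooled = np.concatenate(groups)
    if np.allclose(pooled, pooled[0]):
        raise ValueError("all observations identical; F is undefined")
    F, p = sps.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return AnovaResult(float(F), df1, df2, float(p))


def dahlberg_error(m1, m2) -> float:
    """Dahlberg combined method error sqrt(sum d_i^2 / 2n) of paired
    duplicate measurements, in the units of the input."""
    d = np.asarray(m1, dtype=float) - np.asarray(m2, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one measurement pair")
    return float(np.sqrt(np.sum(d**2) / (2.0 * d.size)))


def icc_two_way_mixed(m1, m2) -> float:
    """Two-way mixed, single-measure, consistency ICC — ICC(3,1).

    Subjects are random rows, the two measurement occasions fixed columns:
    ICC = (MS_rows - MS_error) / (MS_rows + (k-1) MS_error), k = 2.
    Consistency form: a constant offset between occasions is absorbed by
    the occasion effect and does not lower the ICC.
    """
    x = np.column_stack(
        [np.asarray(m1, dtype=float), np.asarray(m2, dtype=float)]
    )
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows <= 0:
        raise ValueError("zero between-subject variance; ICC is undefined")
    return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))


def round_percent(count: int, total: int, ndigits: int = 2) -> float:
    """Percentage of ``total``, rounded half-up to ``ndigits`` decimals."""
    pct = Decimal(count) / Decimal(total) * Decimal(100)
    q = Decimal(1).scaleb(-ndigits)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def descriptive_table(
    table: pd.DataFrame,
    categorical=("sex", "arch", "molar_type"),
    numeric=("age_years", "t_n_months", "OE_mean", "OE_max", "cBLT", "cMDT"),
) -> pd.DataFrame:
    """Tooth-level descriptive summary: counts/percentages for categorical
    variables, mean +/- sd for numeric ones.

    Percentages are of the tooth-level n, rounded half-up to 2 decimals;
    the unrounded value is kept alongside.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    n = len(table)
    rows = []
    for var in categorical:
        if var not in table.columns:
            continue
        counts = table[var].value_counts()
        for level, c in counts.items():
            rows.append(
                {
                    "variable": var,
                    "level": level,
                    "count": int(c),
                    "percent": round_percent(int(c), n),
                    "percent_raw": 100.0 * c / n,
                    "mean": np.nan,
                    "sd": np.nan,
                }
            )
    for var in numeric:
        if var not in table.columns:
            continue
        vals = np.asarray(table[var].dropna(), dtype=float)
        rows.append(
            {
                "variable": var,
                "level": "",
                "count": len(vals),
                "percent": np.nan,
                "percent_raw": np.nan,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
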