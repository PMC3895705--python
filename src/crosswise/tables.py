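"""Descriptive frequency tables and generic two-group tests.

Frequency tables use per-variable complete-case denominators (each
variable's percentages are taken over its own non-missing total), with an
option to count missing as an explicit "no response" category.  Percentages
are printed to one decimal, rounding half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FrequencyTable",
    "frequency_table",
    "frequency_table_from_counts",
    "crosstab_chi_square",
    "two_sample_t",
    "ChiSquareResult",
    "TTestResult",
]

MISSING_LABEL = "No response"


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (so 62.05 -> 62.1, not banker's 62.0)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class FrequencyTable:
    """Counts and one-decimal percents of one categorical variable."""

    variable: str
    rows: tuple[tuple[str, int, float], ...]  # (category, count, percent)
    denominator: int
    include_missing_row: bool

    def __post_init__(self) -> None:
        if sum(c for _, c, _ in self.rows) != self.denominator:
            raise ValueError("counts do not sum to the denominator")
        if self.rows and abs(sum(p for _, _, p in self.rows) - 100.0) > 0.3:
            raise ValueError("percents stray more than rounding slack from 100")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["category", "count", "percent"])


def frequency_table_from_counts(
    variable: str,
    counts: dict[str, int],
    include_missing_row: bool = False,
    missing_count: int = 0,
) -> FrequencyTable:
    """Build a :class:`FrequencyTable` from pre-tabulated category counts.

    ``missing_count`` enters the denominator (as a ``"No response"`` row)
    only when ``include_missing_row`` is set, mirroring the per-variable
    complete-case convention.
    """
    items = [(str(k), int(v)) for k, v in counts.items()]
    if any(v < 0 for _, v in items):
        raise ValueError("negative count")
    if include_missing_row and missing_count > 0:
        items.append((MISSING_LABEL, int(missing_count)))
    denom = sum(v for _, v in items)
    if denom == 0:
        raise ValueError(f"variable {variable!r} has no observations")
    rows = tuple((k, v, round_half_away(100.0 * v / denom)) for k, v in items)
    return FrequencyTable(variable=variable, rows=rows, denominator=denom,
                          include_missing_row=include_missing_row)


def frequency_table(
    data: pd.DataFrame, variable: str, include_missing: bool = False
) -> FrequencyTable:
    """Tabulate one variable of a respondent-level data frame.

    The denominator is the variable's non-missing count unless
    ``include_missing`` is set, in which case missing responses form their
    own category and enter the denominator.
    """
    if variable not in data.columns:
        raise KeyError(f"unknown variable {variable!r}")
    col = data[variable]
    counts = col.dropna().astype(str).value_counts().sort_index()
    return frequency_table_from_counts(
        variable, counts.to_dict(), include_missing_row=include_missing,
        missing_count=int(col.isna().sum()),
    )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame
    expected: pd.DataFrame
    low_expected: bool  # any expected cell count below 5


def crosstab_chi_square(
    data: pd.DataFrame, row_var: str, col_var: str
) -> ChiSquareResult:
    """Pearson chi-square test of independence on the complete-case crosstab.

    No continuity correction.  Degenerate tables (an expected count of
    zero, i.e. an empty margin) raise; expected counts below 5 only set the
    ``low_expected`` flag.
    """
    for v in (row_var, col_var):
        if v not in data.columns:
            raise KeyError(f"unknown variable {v!r}")
    sub = data[[row_var, col_var]].dropna()
    table = pd.crosstab(sub[row_var], sub[col_var])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate table: need at least 2x2 non-empty margins")
    return chi_square_from_table(table)


def chi_square_from_table(table: pd.DataFrame) -> ChiSquareResult:
    """Pearson chi-square on an already-tabulated contingency table."""
    arr = np.asarray(table, dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a margin is empty")
    res = stats.chi2_contingency(arr, correction=False)
    expected = pd.DataFrame(res.expected_freq, index=table.index,
                            columns=table.columns)
    return ChiSquareResult(
        statistic=float(res.statistic), df=int(res.dof),
        p_value=float(res.pvalue), table=pd.DataFrame(table),
        expected=expected, low_expected=bool((res.expected_freq < 5).any()),
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float
    mean_diff: float
    groups: tuple[str, str]


def two_sample_t(data: pd.DataFrame, value_var: str, group_var: str) -> TTestResult:
    """Welch two-sample t test between the two levels of ``group_var``.

    Groups are ordered by sorted label; ``t`` is mean(first) - mean(second)
    over the Welch standard error, with Welch-Satterthwaite degrees of
    freedom and a two-sided p-value.
    """
    for v in (value_var, group_var):
        if v not in data.columns:
            raise KeyError(f"unknown variable {v!r}")
    sub = data[[value_var, group_var]].dropna()
    labels = sorted(map(str, sub[group_var].unique()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    g1 = pd.to_numeric(sub.loc[sub[group_var].astype(str) == labels[0], value_var])
    g2 = pd.to_numeric(sub.loc[sub[group_var].astype(str) == labels[1], value_var])
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least 2 observations per group")
    if g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0:
        if g1.mean() == g2.mean():
            return TTestResult(t=0.0, df=float(len(g1) + len(g2) - 2),
                               p_value=1.0, mean_diff=0.0,
                               groups=(labels[0], labels[1]))
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(g1, g2, equal_var=False)
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p_value=float(res.pvalue),
                       mean_diff=float(g1.mean() - g2.mean()),
                       groups=(labels[0], labels[1]))
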