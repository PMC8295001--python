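"""Two-group inference from printed summary statistics.

Clinical comparisons in the source setting are reported only as group
summaries (mean +/- SD with group size) and 2x2 counts.  This module
reconstructs the corresponding two-sided tests: a two-sample t-test computed
directly from (mean, sd, n) pairs — pooled-variance Student by default, Welch
by flag — and the Pearson chi-square test (optionally Yates-corrected) on 2x2
contingency tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    """One group's printed summary: mean +/- sd with n subjects."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 group-by-category counts."""

    counts: tuple  # ((a, b), (c, d))

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts",
                           tuple(tuple(int(v) for v in row) for row in arr))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str
    degenerate: bool = False

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def t_test_from_summary(a: GroupSummary, b: GroupSummary,
                        variant: str = "student") -> TestResult:
    """Two-sided two-sample t-test from group summaries.

    ``student`` pools the variances (df = n_a + n_b - 2); ``welch`` uses the
    Satterthwaite degrees of freedom.  Two zero-SD groups are degenerate:
    equal means give (t=0, p=1), unequal means (p=0, degenerate flag).
    """
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    method = "student_t" if variant == "student" else "welch_t"
    if a.sd == 0 and b.sd == 0:
        df = a.n + b.n - 2
        if a.mean == b.mean:
            return TestResult(0.0, df, 1.0, method, degenerate=True)
        return TestResult(np.inf if a.mean > b.mean else -np.inf, df, 0.0,
                          method, degenerate=True)
    res = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                     equal_var=(variant == "student"))
    if variant == "student":
        df = a.n + b.n - 2
    else:
        va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
        df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    return TestResult(float(res.statistic), float(df), float(res.pvalue), method)


def chi_square_test(table: ContingencyTable, yates: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table (df = 1), optional Yates correction."""
    arr = table.array
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("chi-square test requires all margins > 0")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=yates)
    method = "chi_square_yates" if yates else "chi_square"
    return TestResult(float(stat), float(df), float(p), method)


Row = Union[Tuple[str, GroupSummary, GroupSummary], Tuple[str, ContingencyTable]]


def compare_groups_table(rows: Sequence[Row], variant: str = "student",
                         yates: bool = False) -> pd.DataFrame:
    """Run the appropriate test per row; flag significance at 0.05 and 0.01.

    Each row is ``(label, GroupSummary, GroupSummary)`` for a continuous
    measure or ``(label, ContingencyTable)`` for counts.
    """
    if not rows:
        raise ValueError("no rows to compare")
    out = []
    for row in rows:
        label = row[0]
        if len(row) == 3 and isinstance(row[1], GroupSummary):
            res = t_test_from_summary(row[1], row[2], variant=variant)
        elif len(row) == 2 and isinstance(row[1], ContingencyTable):
            res = chi_square_test(row[1], yates=yates)
        else:
            raise ValueError(f"row {label!r} is neither a summary pair nor a table")
        out.append({
            "label": label, "method": res.method,
            "statistic": res.statistic, "df": res.df, "p_value": res.p_value,
            "significant_0.05": res.p_value < 0.05,
            "significant_0.01": res.p_value < 0.01,
        })
    return pd.DataFrame(out)
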