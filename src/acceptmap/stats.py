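"""Contingency tables, test selection, exact tests and report replicas.

Differences between the observed measures composing distinct
acceptability scores (over time, or across age groups) are assessed per
observational variable on the category x group contingency table.  Test
choice follows Cochran-style expected-count screening: Pearson's
chi-squared test when at least 80% of the expected cell counts are 5 or
more and none is zero; otherwise the Freeman-Halton generalization of
Fisher's exact test, whose p-value sums the probabilities (multivariate
hypergeometric with both margins fixed) of every table no more probable
than the observed one.

Reports mirror the published layout: per variable and group, counts with
integer-rounded percentages computed on non-missing denominators,
missing-data rows, and the selected test with its p-value.  Rows that are
zero everywhere are kept for display but dropped before testing (their
expected counts would be zero, leaving both tests undefined); variables
with no variation at all get no test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .codebook import DEFAULT_CODEBOOK
from .schema import ADHERENCE_BANDS, AGE_GROUPS, EvaluationSet

__all__ = [
    "ContingencyTable",
    "TestResult",
    "adherence_report",
    "fisher_exact_rxc",
    "pearson_chi2",
    "pct",
    "run_selected_test",
    "select_test",
    "table_report",
    "tabulate",
]

MIN_EXPECTED = 5.0
EXPECTED_FRACTION = 0.8


class EnumerationError(RuntimeError):
    """Exact-test enumeration would exceed the configured capacity."""


def pct(count: float, denom: float) -> int:
    """Percentage rounded to the nearest integer (half away from zero)."""
    if denom == 0:
        return 0
    return int(np.floor(100.0 * count / denom + 0.5))


@dataclass
class ContingencyTable:
    """r x c counts with per-column missing tallies."""

    counts: pd.DataFrame  # rows = categories, cols = groups
    missing_per_col: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("contingency counts must be non-negative")
        if self.missing_per_col is None:
            self.missing_per_col = pd.Series(0, index=self.counts.columns)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def drop_zero_rows(self) -> "ContingencyTable":
        keep = self.counts.sum(axis=1) > 0
        return ContingencyTable(self.counts.loc[keep], self.missing_per_col)

    def expected(self) -> np.ndarray:
        obs = self.counts.to_numpy(dtype=float)
        return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()


@dataclass(frozen=True)
class TestResult:
    test: str  # "chi_square" | "fisher_exact"
    p_value: float
    statistic: float | None = None
    df: int | None = None


def tabulate(
    evalset: EvaluationSet, variable: str, grouping: str = "timepoint"
) -> ContingencyTable:
    """Cross-classify one variable's non-missing counts by group.

    ``grouping`` is ``"timepoint"`` or ``"age_group"`` (derived from
    age_years at analysis time).  Missing values are tallied separately
    per column; all-zero category rows are retained for display.
    """
    codebook = evalset.codebook
    if variable not in codebook.variable_names:
        raise KeyError(f"unknown variable {variable!r}")
    joined = evalset.with_age_groups()
    if grouping == "timepoint":
        groups, levels = joined["timepoint"], [1, 2, 3]
    elif grouping == "age_group":
        groups, levels = joined["age_group"], list(AGE_GROUPS)
    else:
        raise KeyError(f"unknown grouping {grouping!r}")
    cats = list(codebook.categories(variable))
    col = joined[variable]
    counts = pd.DataFrame(0, index=cats, columns=levels)
    missing = pd.Series(0, index=levels)
    for level in levels:
        in_group = groups == level
        vals = col[in_group]
        missing[level] = int(vals.isna().sum())
        vc = vals.value_counts()
        for cat in cats:
            counts.loc[cat, level] = int(vc.get(cat, 0))
    return ContingencyTable(counts=counts, missing_per_col=missing)


def select_test(table: ContingencyTable) -> str:
    """The published selection rule.

    Chi-squared iff at least 80% of expected counts are >= 5 and no
    expected count is zero, else Fisher's exact test.  All-zero rows are
    dropped first; tables without at least a 2 x 2 core are untestable.
    """
    trimmed = table.drop_zero_rows()
    counts = trimmed.counts.to_numpy(dtype=float)
    nonzero_cols = counts.sum(axis=0) > 0
    counts = counts[:, nonzero_cols]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("degenerate table: needs >= 2 non-zero rows and columns")
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()
    if (expected > 0).all() and (expected >= MIN_EXPECTED).mean() >= EXPECTED_FRACTION:
        return "chi_square"
    return "fisher_exact"


def pearson_chi2(table: ContingencyTable) -> TestResult:
    """Pearson chi-squared test, no continuity correction."""
    trimmed = table.drop_zero_rows()
    counts = trimmed.counts.to_numpy(dtype=float)
    counts = counts[:, counts.sum(axis=0) > 0]
    stat, p, df, _ = chi2_contingency(counts, correction=False)
    return TestResult(test="chi_square", p_value=float(p), statistic=float(stat), df=int(df))


def fisher_exact_rxc(
    table: ContingencyTable, max_tables: int = 2_000_000, tie_tol: float = 1e-12
) -> TestResult:
    """Freeman-Halton exact test for an r x c table.

    Enumerates every table with the observed margins; the p-value is the
    total multivariate-hypergeometric probability of tables whose
    probability does not exceed the observed one (relative tie tolerance
    ``tie_tol``).  Raises :class:`EnumerationError` when more than
    ``max_tables`` tables would be visited.
    """
    trimmed = table.drop_zero_rows()
    counts = trimmed.counts.to_numpy(dtype=np.int64)
    counts = counts[:, counts.sum(axis=0) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("degenerate table: needs >= 2 non-zero rows and columns")
    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    N = int(counts.sum())
    log_const = (
        sum(lgamma(m + 1) for m in row_m)
        + sum(lgamma(m + 1) for m in col_m)
        - lgamma(N + 1)
    )
    log_p_obs = log_const - sum(lgamma(v + 1) for v in counts.ravel())
    threshold = log_p_obs + np.log1p(tie_tol)

    r, c = counts.shape
    p_total = 0.0
    visited = 0

    def recurse(row: int, col_left: np.ndarray, log_acc: float) -> None:
        nonlocal p_total, visited
        visited += 1
        if visited > max_tables:
            raise EnumerationError(
                f"Freeman-Halton enumeration exceeded {max_tables} tables"
            )
        if row == r - 1:
            # last row forced by the column margins
            lp = log_const + log_acc - sum(lgamma(v + 1) for v in col_left)
            if lp <= threshold:
                p_total += np.exp(lp)
            return
        target = row_m[row]

        def fill(col: int, remaining: int, left: np.ndarray, lacc: float) -> None:
            if col == c - 1:
                if remaining <= left[col]:
                    left2 = left.copy()
                    left2[col] -= remaining
                    recurse(row + 1, left2, lacc - lgamma(remaining + 1))
                return
            hi = min(remaining, left[col])
            for v in range(hi + 1):
                left2 = left.copy()
                left2[col] -= v
                fill(col + 1, remaining - v, left2, lacc - lgamma(v + 1))

        fill(0, target, col_left, log_acc)

    recurse(0, col_m.copy(), 0.0)
    return TestResult(test="fisher_exact", p_value=float(min(p_total, 1.0)))


def run_selected_test(table: ContingencyTable) -> TestResult | None:
    """Apply the selection rule and run the chosen test.

    Returns ``None`` for untestable tables (no variation), as the
    published reports leave those cells blank.
    """
    try:
        chosen = select_test(table)
    except ValueError:
        return None
    if chosen == "chi_square":
        return pearson_chi2(table)
    return fisher_exact_rxc(table)


# -- report replicas -----------------------------------------------------


def _format_test(result: TestResult | None) -> str:
    if result is None:
        return ""
    flag = "chi2" if result.test == "chi_square" else "F"
    if result.p_value < 0.001:
        return f"{flag}: p < 0.001"
    return f"{flag}: p = {result.p_value:.2g}"


def table_report(
    tables: dict[str, ContingencyTable], codebook=None
) -> pd.DataFrame:
    """Outcome report from per-variable contingency tables.

    One row per category: "n (pct)" per group column, percentages on
    non-missing denominators; *missing data* rows where applicable; the
    selected test and p-value on the variable's first row.
    """
    codebook = codebook or DEFAULT_CODEBOOK
    rows = []
    for var in codebook.variable_names:
        if var not in tables:
            continue
        table = tables[var]
        denoms = table.counts.sum(axis=0)
        result = run_selected_test(table)
        first = True
        for cat in table.counts.index:
            row = {"variable": var, "category": cat}
            for col in table.counts.columns:
                n = int(table.counts.loc[cat, col])
                row[str(col)] = f"{n} ({pct(n, denoms[col])})"
            row["test"] = _format_test(result) if first else ""
            rows.append(row)
            first = False
        if table.missing_per_col is not None and table.missing_per_col.sum() > 0:
            row = {"variable": var, "category": "missing data"}
            for col in table.counts.columns:
                m = int(table.missing_per_col[col])
                row[str(col)] = str(m) if m else ""
            row["test"] = ""
            rows.append(row)
    return pd.DataFrame(rows)


def table1_report(evalset: EvaluationSet) -> pd.DataFrame:
    """Observer-reported outcomes over time (counts, percentages, tests)."""
    tables = {
        var: tabulate(evalset, var, "timepoint")
        for var in evalset.codebook.variable_names
    }
    return table_report(tables, evalset.codebook)


def table2_report(evalset: EvaluationSet) -> pd.DataFrame:
    """Observer-reported outcomes by age group."""
    tables = {
        var: tabulate(evalset, var, "age_group")
        for var in evalset.codebook.variable_names
    }
    return table_report(tables, evalset.codebook)


def adherence_report(evalset: EvaluationSet) -> pd.DataFrame:
    """End-of-treatment adherence: counts and percentages per band.

    Percentages use the number of patients with adherence information as
    denominator; a final row counts patients reporting difficulty.
    """
    if evalset.adherence is None or len(evalset.adherence) == 0:
        warnings.warn("no adherence records; returning empty report", stacklevel=2)
        return pd.DataFrame(columns=["band", "n", "pct"])
    adh = evalset.adherence
    n_total = len(adh)
    rows = [
        {
            "band": band,
            "n": int((adh["band"] == band).sum()),
            "pct": pct(int((adh["band"] == band).sum()), n_total),
        }
        for band in ADHERENCE_BANDS
    ]
    rows.append(
        {
            "band": "difficulty reported",
            "n": int(adh["difficulty"].sum()),
            "pct": pct(int(adh["difficulty"].sum()), n_total),
        }
    )
    return pd.DataFrame(rows)
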