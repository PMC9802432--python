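"""Stratum-comparison statistics: Pearson chi-square, one-way ANOVA, t-test.

Conventions match common claims-study reporting: the chi-square carries no
continuity correction; the two-sample t-test pools variances by default (so
that on two groups ``t**2`` equals the one-way ANOVA ``F``); p-values are
two-sided and unadjusted.  Each test also exists in a summary-statistics form
(counts, or per-group ``(n, mean, SD)`` triplets) so that results printed in
publications can be recomputed without patient-level data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    warning: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class GroupSummary:
    """Per-group (n, mean, SD) for one continuous variable."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")


def chi_square_test(table) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction.  Degenerate (all-zero) rows or columns raise;
    an expected count below 5 only attaches a warning (asymptotic test kept,
    as in standard statistical-software output).
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if (counts < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    row_margins = counts.sum(axis=1)
    col_margins = counts.sum(axis=0)
    for axis, margins in (("row", row_margins), ("column", col_margins)):
        zero = np.flatnonzero(margins == 0)
        if len(zero):
            raise ValueError(f"degenerate contingency table: {axis} {zero[0]} has zero margin")
    statistic, p, dof, expected = sps.chi2_contingency(counts, correction=False)
    warning = None
    if (expected < 5).any():
        warning = f"{int((expected < 5).sum())} cell(s) with expected count < 5; asymptotic p may be inaccurate"
    return TestResult("pearson_chi2", float(statistic), float(dof), float(p), warning)


def anova_oneway_from_summary(groups: Sequence[GroupSummary | tuple]) -> TestResult:
    """One-way fixed-effects ANOVA reconstructed from (n, mean, SD) triplets.

    Identical to the observation-level ANOVA when the summaries are computed
    from the same data: the between-group sum of squares uses the
    sample-size-weighted grand mean and the within-group sum of squares is
    ``sum((n_i - 1) * sd_i**2)``.
    """
    groups = [g if isinstance(g, GroupSummary) else GroupSummary(*g) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    s = np.array([g.sd for g in groups], dtype=float)
    k, total = len(groups), n.sum()
    grand_mean = (n * m).sum() / total
    ss_between = (n * (m - grand_mean) ** 2).sum()
    ss_within = ((n - 1) * s**2).sum()
    df1, df2 = k - 1, total - k
    if ss_within == 0:
        statistic = 0.0 if ss_between == 0 else float("inf")
        return TestResult("anova_oneway", statistic, (df1, df2), 1.0 if ss_between == 0 else 0.0)
    statistic = (ss_between / df1) / (ss_within / df2)
    return TestResult("anova_oneway", float(statistic), (float(df1), float(df2)), float(sps.f.sf(statistic, df1, df2)))


def _summarize(values: Iterable[float]) -> GroupSummary:
    arr = np.asarray(list(values), dtype=float)
    return GroupSummary(len(arr), float(arr.mean()), float(arr.std(ddof=1)))


def anova_oneway(*groups: Iterable[float]) -> TestResult:
    """Observation-level one-way ANOVA (delegates to the summary form)."""
    return anova_oneway_from_summary([_summarize(g) for g in groups])


def t_test_two_sample(
    group_a: GroupSummary | tuple | Iterable[float],
    group_b: GroupSummary | tuple | Iterable[float],
    *more,
    pooled: bool = True,
) -> TestResult:
    """Two-sample two-sided t-test from summaries or raw values.

    ``pooled=True`` (default) uses the equal-variance statistic; set
    ``pooled=False`` for Welch.
    """
    if more:
        raise ValueError("t-test compares exactly 2 groups; use anova_oneway for more")

    def as_summary(g) -> GroupSummary:
        if isinstance(g, GroupSummary):
            return g
        if isinstance(g, tuple) and len(g) == 3:
            return GroupSummary(*g)
        return _summarize(g)

    a, b = as_summary(group_a), as_summary(group_b)
    res = sps.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=pooled)
    df = a.n + b.n - 2 if pooled else float(res.df) if hasattr(res, "df") else a.n + b.n - 2
    name = "t_test_pooled" if pooled else "t_test_welch"
    return TestResult(name, float(res.statistic), float(df), float(res.pvalue))


STRATUM_ORDER = ("high", "intermediate", "low")


def compare_strata(
    data: pd.DataFrame,
    stratum_col: str = "stratum",
    binary_outcomes: Sequence[str] = (),
    continuous_outcomes: Sequence[str] = (),
) -> pd.DataFrame:
    """Cross-stratum comparison table (the published-table layout).

    For each binary outcome: per-stratum ``n (%)`` and a Pearson chi-square
    across strata.  For each continuous outcome: per-stratum ``mean (SD)``
    and a one-way ANOVA (3+ strata) or pooled t-test (2 strata).  Strata with
    zero patients are dropped; with fewer than two strata present an empty
    table is returned with a warning.
    """
    values = list(data[stratum_col].dropna().unique())
    present = [s for s in STRATUM_ORDER if s in values] + sorted(v for v in values if v not in STRATUM_ORDER)
    groups = {s: data[data[stratum_col] == s] for s in present}
    columns = ["variable", "kind", "test", "statistic", "p_value", *(f"{s}_summary" for s in present)]
    if len(present) < 2:
        warnings.warn("fewer than 2 non-empty strata; nothing to compare", stacklevel=2)
        return pd.DataFrame(columns=columns)

    rows = []
    for var in binary_outcomes:
        counts = np.array([[int(g[var].sum()), int((~g[var].astype(bool)).sum())] for g in groups.values()])
        summaries = {
            f"{s}_summary": f"{c[0]} ({100.0 * c[0] / (c[0] + c[1]):.1f})" for s, c in zip(groups, counts)
        }
        try:
            result = chi_square_test(counts)
        except ValueError as exc:
            warnings.warn(f"{var}: {exc}; skipped", stacklevel=2)
            continue
        rows.append({"variable": var, "kind": "binary", "test": result.test,
                     "statistic": result.statistic, "p_value": result.p_value, **summaries})
    for var in continuous_outcomes:
        summaries = {}
        group_summaries = []
        for s, g in groups.items():
            vals = g[var].dropna().to_numpy(dtype=float)
            if len(vals) < 2:
                break
            gs = _summarize(vals)
            group_summaries.append(gs)
            summaries[f"{s}_summary"] = f"{gs.mean:.1f} ({gs.sd:.1f})"
        if len(group_summaries) < len(groups):
            warnings.warn(f"{var}: a stratum has fewer than 2 observations; skipped", stacklevel=2)
            continue
        if len(group_summaries) == 2:
            result = t_test_two_sample(group_summaries[0], group_summaries[1])
        else:
            result = anova_oneway_from_summary(group_summaries)
        rows.append({"variable": var, "kind": "continuous", "test": result.test,
                     "statistic": result.statistic, "p_value": result.p_value, **summaries})
    return pd.DataFrame(rows, columns=columns)
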