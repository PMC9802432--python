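"""Recompute the published study's derivable numbers from its printed tables.

The packaged fixture ``data/reported_values.json`` transcribes the printed
baseline table (counts and per-stratum (n, mean, SD) summaries), the printed
cost table, and the headline low/high cost ratio, each entry labelled with
its source table, row and cohort column.  :func:`verify_reported` recomputes
every derivable quantity with this package's own statistics routines —
percentages from counts, Pearson chi-square p-values from count tables,
ANOVA / pooled-t p-values from summary triplets, the cost ratio from means —
and compares each against the printed value at its printed precision
(tolerance: one unit in the last printed digit; printed bounds like "<0.001"
check as strict inequalities).

A few printed p-values are flagged non-derivable in the fixture: recomputing
them from summaries rounded to one decimal cannot reach the printed
precision.  They are reported with their recomputed values but excluded from
the pass/fail accounting.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .stats import GroupSummary, anova_oneway_from_summary, chi_square_test, t_test_two_sample


def load_reported_values() -> dict:
    with resources.files("cdst_hru").joinpath("data/reported_values.json").open("r", encoding="utf-8") as fh:
        return json.load(fh)


def _parse_printed_p(text: str) -> tuple[float, bool, float]:
    """Return (value, is_bound, tolerance) for a printed p-value string."""
    text = text.strip()
    bound = text.startswith("<")
    number = text[1:] if bound else text
    decimals = len(number.split(".")[1]) if "." in number else 0
    return float(number), bound, 10.0 ** (-decimals)


def _p_check(recomputed: float, printed: str) -> tuple[bool, float, float]:
    value, bound, tol = _parse_printed_p(printed)
    if bound:
        return recomputed < value, value, tol
    return abs(recomputed - value) <= tol + 1e-12, value, tol


def verify_reported(fixture: dict | None = None) -> pd.DataFrame:
    """One row per recomputable printed value; ``passed`` is null for entries
    the fixture marks non-derivable."""
    fx = fixture or load_reported_values()
    cohorts = fx["cohorts"]
    rows: list[dict] = []

    def add(check: str, kind: str, recomputed: float, reported, passed: bool | None, note: str = ""):
        rows.append(
            {
                "check": check,
                "kind": kind,
                "recomputed": recomputed,
                "reported": reported,
                "passed": passed,
                "note": note,
            }
        )

    for entry in fx["categorical"]:
        ns = cohorts[entry["cohort"]]["n"]
        strata = cohorts[entry["cohort"]]["strata"]
        base = f"{entry['table']}/{entry['row']}/{entry['cohort']}"
        for stratum, count, n, printed in zip(strata, entry["counts"], ns, entry["pct"]):
            pct = 100.0 * count / n
            add(f"{base}/{stratum}/pct", "percentage", round(pct, 1), printed, abs(pct - printed) <= 0.05 + 1e-9)
        table = np.array([[c, n - c] for c, n in zip(entry["counts"], ns)])
        p = chi_square_test(table).p_value
        passed, printed_val, _ = _p_check(p, entry["p"])
        add(f"{base}/p", "chi2_p", p, entry["p"], passed if entry.get("derivable", True) else None, entry.get("note", ""))

    for entry in fx["multilevel"]:
        ns = cohorts[entry["cohort"]]["n"]
        strata = cohorts[entry["cohort"]]["strata"]
        base = f"{entry['table']}/{entry['row']}/{entry['cohort']}"
        for level, counts_level, pcts in zip(entry["levels"], entry["counts"], entry["pct"]):
            for stratum, count, n, printed in zip(strata, counts_level, ns, pcts):
                pct = 100.0 * count / n
                add(f"{base}/{level}/{stratum}/pct", "percentage", round(pct, 1), printed, abs(pct - printed) <= 0.05 + 1e-9)
        table = np.array(entry["counts"])  # levels x strata
        p = chi_square_test(table).p_value
        passed, _, _ = _p_check(p, entry["p"])
        add(f"{base}/p", "chi2_p", p, entry["p"], passed if entry.get("derivable", True) else None, entry.get("note", ""))

    for entry in fx["continuous"]:
        ns = cohorts[entry["cohort"]]["n"]
        base = f"{entry['table']}/{entry['row']}/{entry['cohort']}"
        groups = [GroupSummary(n, m, s) for n, m, s in zip(ns, entry["mean"], entry["sd"])]
        if len(groups) == 2:
            result = t_test_two_sample(groups[0], groups[1])
        else:
            result = anova_oneway_from_summary(groups)
        passed, _, _ = _p_check(result.p_value, entry["p"])
        add(
            f"{base}/p",
            result.test + "_p",
            result.p_value,
            entry["p"],
            passed if entry.get("derivable", True) else None,
            entry.get("note", ""),
        )

    ratio_spec = fx["cost_ratio"]
    cohort = ratio_spec["cohort"]
    strata = cohorts[cohort]["strata"]
    means = next(
        e["mean"] for e in fx["continuous"] if e["cohort"] == cohort and e["row"] == ratio_spec["row"]
    )
    ratio = means[strata.index("low")] / means[strata.index("high")]
    add(
        f"{ratio_spec['source']}/{ratio_spec['row']}/{cohort}/low_over_high_ratio",
        "ratio",
        round(ratio, 1),
        ratio_spec["ratio_low_over_high"],
        abs(round(ratio, 1) - ratio_spec["ratio_low_over_high"]) < 1e-9,
        ratio_spec.get("note", ""),
    )

    return pd.DataFrame(rows, columns=["check", "kind", "recomputed", "reported", "passed", "note"])
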