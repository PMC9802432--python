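"""CD-related expenditures: 2017-USD conversion and annualization.

Each in-window claim is billed to at most one of six categories
(hospitalization, surgery, ED visit, office visit, endoscopy/scan,
laboratory test) under a fixed precedence, consistent with the
ED-reclassification rule used for events.  Amounts are converted to 2017 USD
with a per-service-year CPI factor table and then annualized:

* if the interval from index to the end of continuous insurance eligibility
  exceeds 12 months, the actual expenditure is reported unchanged;
* otherwise the expenditure is scaled by ``365.25 / (days_between + 1)``.

The default CPI table maps every year to 1.0; study-specific deflators are
user-supplied configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .cohort import CohortConfig
from .outcomes import OutcomeRecord

CATEGORIES = ("hospitalization", "surgery", "ed_visit", "office_visit", "endoscopy_scan", "lab_test")

#: category precedence when a claim's codes match several categories
DEFAULT_PRECEDENCE = ("surgery", "hospitalization", "ed_visit", "endoscopy_scan", "office_visit", "lab_test")


class ConfigError(ValueError):
    pass


class CPITable(dict):
    """Mapping of service year -> multiplicative conversion factor to 2017 USD.

    An empty table (the default) is the identity: factor 1.0 for every year.
    A non-empty table must include ``2017 -> 1.0`` and is strict: a service
    year it does not list raises :class:`ConfigError`.
    """

    def __init__(self, factors: Mapping[int, float] | None = None):
        super().__init__(dict(factors) if factors else {})
        for year, factor in self.items():
            if factor <= 0:
                raise ConfigError(f"CPI factor for {year} must be positive, got {factor}")
        if self and self.get(2017) != 1.0:
            raise ConfigError("CPI factor for the reference year 2017 must be 1.0")

    def factor(self, year: int) -> float:
        if not self:
            return 1.0
        if year in self:
            return self[year]
        raise ConfigError(f"no CPI conversion factor configured for service year {year}")

    @classmethod
    def from_yaml(cls, path) -> "CPITable":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls({int(k): float(v) for k, v in raw.items()})


def to_2017_usd(amount: float, service_year: int, cpi: CPITable) -> float:
    """Convert a paid amount to 2017 USD via the year's CPI factor."""
    if amount < 0:
        raise ValueError(f"paid amount must be non-negative, got {amount}")
    return amount * cpi.factor(service_year)


def annualize(total_2017usd: float, index_date: pd.Timestamp, eligibility_end: pd.Timestamp) -> float:
    """Annualize an expenditure observed from index to the eligibility end.

    Returns the input unchanged when the observed interval exceeds 12 months
    (``days_between + 1 > 365.25``), else ``total / (days_between + 1) * 365.25``.
    """
    days_between = (pd.Timestamp(eligibility_end) - pd.Timestamp(index_date)).days
    if days_between < 0:
        raise ValueError("eligibility end precedes the index date")
    observed = days_between + 1
    if observed > 365.25:
        return float(total_2017usd)
    return float(total_2017usd) / observed * 365.25


@dataclass(frozen=True)
class AnnualizedCost:
    patient_id: str
    hospitalization: float
    surgery: float
    ed_visit: float
    office_visit: float
    endoscopy_scan: float
    lab_test: float
    eligibility_days: int
    annualized: bool  # True iff the observed interval was <= 12 months and scaling applied

    @property
    def total(self) -> float:
        return sum(getattr(self, c) for c in CATEGORIES)


def categorize_claims(
    claims: pd.DataFrame,
    config: CohortConfig,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> pd.Series:
    """Assign each claim row to one cost category (or ``None``).

    Matching is by code set (surgery procedures, ED/lab revenue codes, office
    and endoscopy CPT codes) and, for hospitalization, inpatient setting with
    a CD diagnosis; ties resolve by ``precedence``.
    """
    cs = config.code_sets
    matchers = {
        "surgery": claims["code"].isin(cs["surgery_procedures"]),
        "hospitalization": (claims["setting"] == "inpatient")
        & (claims["code_type"] == "diagnosis")
        & claims["code"].isin(cs["cd_diagnosis"]),
        "ed_visit": (claims["code_type"] == "revenue") & claims["code"].isin(cs["ed_revenue"]),
        "endoscopy_scan": claims["code"].isin(cs["endoscopy_scan_cpt"]),
        "office_visit": claims["code"].isin(cs["office_visit_cpt"]),
        "lab_test": (claims["code_type"] == "revenue") & claims["code"].isin(cs["lab_revenue"]),
    }
    category = pd.Series([None] * len(claims), index=claims.index, dtype=object)
    for cat in reversed(precedence):
        category[matchers[cat]] = cat
    return category


def aggregate_costs(
    claims: pd.DataFrame,
    index_date: pd.Timestamp,
    eligibility_end: pd.Timestamp,
    record: OutcomeRecord,
    config: CohortConfig | None = None,
    cpi: CPITable | None = None,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> AnnualizedCost:
    """Per-category annualized 2017-USD expenditure for one patient.

    ED claims that the outcomes stage reclassified into hospitalization or
    surgery carry their cost into that category, so the cost partition stays
    consistent with the event counts.
    """
    config = config or CohortConfig()
    cpi = cpi or CPITable()
    window_end = index_date + pd.Timedelta(days=365)
    w = claims[
        (claims["service_date"] >= index_date)
        & (claims["service_date"] < window_end)
        & (claims["service_date"] <= eligibility_end)
    ].copy()
    category = categorize_claims(w, config, precedence)
    reclass = dict(record.reclassified_ed)
    if reclass:
        ed_mask = category == "ed_visit"
        for idx in w.index[ed_mask]:
            target = reclass.get(w.at[idx, "service_date"])
            if target is not None:
                category.at[idx] = target

    sums = {cat: 0.0 for cat in CATEGORIES}
    if len(w):
        if (w["paid_amount"] < 0).any():
            raise ValueError("paid amount must be non-negative")
        factors = w["service_year"].map(lambda y: cpi.factor(int(y)))
        converted = w["paid_amount"].to_numpy(dtype=float) * factors.to_numpy(dtype=float)
        for cat, amount in zip(category, converted):
            if cat is not None:
                sums[cat] += amount

    days_between = (pd.Timestamp(eligibility_end) - pd.Timestamp(index_date)).days
    scaled = {cat: annualize(v, index_date, eligibility_end) for cat, v in sums.items()}
    return AnnualizedCost(
        patient_id=record.patient_id,
        eligibility_days=days_between + 1,
        annualized=(days_between + 1) <= 365.25,
        **scaled,
    )


def compute_costs(
    claims: pd.DataFrame,
    cohort: pd.DataFrame,
    records: Mapping[str, OutcomeRecord],
    config: CohortConfig | None = None,
    cpi: CPITable | None = None,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> pd.DataFrame:
    """Annualized cost table for a whole cohort (one row per patient)."""
    config = config or CohortConfig()
    cpi = cpi or CPITable()
    by_pid = dict(iter(claims.groupby("patient_id"))) if len(claims) else {}
    empty = claims.iloc[0:0]
    rows = []
    for _, row in cohort.iterrows():
        pid = row["patient_id"]
        cost = aggregate_costs(
            by_pid.get(pid, empty), row["index_date"], row["eligibility_end"], records[pid], config, cpi, precedence
        )
        rows.append(
            {
                "patient_id": pid,
                **{cat: getattr(cost, cat) for cat in CATEGORIES},
                "total": cost.total,
                "eligibility_days": cost.eligibility_days,
                "annualized": cost.annualized,
            }
        )
    columns = ["patient_id", *CATEGORIES, "total", "eligibility_days", "annualized"]
    return pd.DataFrame(rows, columns=columns)


def cost_summary(costs: pd.DataFrame, strata: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum mean (SD) of each cost category and the total."""
    joined = costs.merge(strata[["patient_id", "stratum"]], on="patient_id", how="inner")
    rows = []
    for stratum, grp in joined.groupby("stratum", sort=False):
        for cat in (*CATEGORIES, "total"):
            rows.append(
                {
                    "stratum": stratum,
                    "category": cat,
                    "n": len(grp),
                    "mean": float(grp[cat].mean()),
                    "sd": float(grp[cat].std(ddof=1)) if len(grp) > 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["stratum", "category", "n", "mean", "sd"])
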