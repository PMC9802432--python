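"""12-month post-index events: hospitalization, surgery, ED visits.

Event definitions over the window ``[index, index + 365d)``:

* hospitalization — an inpatient-setting claim carrying a CD diagnosis;
  line-items on the same or consecutive days merge into one episode;
* surgery — a claim with a bowel-surgery procedure code (one event per day);
* ED visit — a claim with an emergency-department revenue code
  (0450-0459, 0981).

An ED claim followed within the linkage window (default: same day or next
day) by a hospitalization or surgery is *reclassified* into that category and
not counted as an ED visit — an ED visit that results in admission is an
admission.  Surgery takes precedence over hospitalization when both link.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CohortConfig

EVENT_TYPES = ("hospitalization", "surgery", "ed_visit")


@dataclass(frozen=True)
class OutcomeRecord:
    patient_id: str
    index_date: pd.Timestamp
    n_hospitalizations: int
    n_surgeries: int
    n_ed_visits: int
    followup_days: int
    # (date, target category) for each ED claim absorbed by the linkage rule;
    # the costs module bills these claims to the target category
    reclassified_ed: tuple[tuple[pd.Timestamp, str], ...] = field(default_factory=tuple)

    @property
    def had_hospitalization(self) -> bool:
        return self.n_hospitalizations >= 1

    @property
    def had_surgery(self) -> bool:
        return self.n_surgeries >= 1

    @property
    def had_ed_visit(self) -> bool:
        return self.n_ed_visits >= 1


def _merge_dates_into_episodes(dates: np.ndarray, max_gap_days: int = 1) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Collapse sorted unique dates into episodes, merging gaps <= max_gap_days."""
    episodes: list[list[pd.Timestamp]] = []
    for d in dates:
        if episodes and (d - episodes[-1][1]).days <= max_gap_days:
            episodes[-1][1] = d
        else:
            episodes.append([d, d])
    return [tuple(e) for e in episodes]


def extract_events(
    claims: pd.DataFrame,
    index_date: pd.Timestamp,
    config: CohortConfig | None = None,
    eligibility_end: pd.Timestamp | None = None,
) -> OutcomeRecord:
    """Extract one patient's 12-month event record from their claims."""
    config = config or CohortConfig()
    cs = config.code_sets
    window_end = index_date + pd.Timedelta(days=365)
    w = claims[(claims["service_date"] >= index_date) & (claims["service_date"] < window_end)]
    if eligibility_end is not None:
        out_of_span = w[w["service_date"] > eligibility_end]
        if len(out_of_span):
            warnings.warn(
                f"patient {claims['patient_id'].iloc[0] if len(claims) else '?'}: "
                f"{len(out_of_span)} claim(s) after enrollment end ignored",
                stacklevel=2,
            )
            w = w[w["service_date"] <= eligibility_end]

    hosp_dates = np.sort(
        w.loc[
            (w["setting"] == "inpatient") & (w["code_type"] == "diagnosis") & w["code"].isin(cs["cd_diagnosis"]),
            "service_date",
        ].unique()
    )
    episodes = _merge_dates_into_episodes(pd.DatetimeIndex(hosp_dates), max_gap_days=1)
    surg_dates = pd.DatetimeIndex(np.sort(w.loc[w["code"].isin(cs["surgery_procedures"]), "service_date"].unique()))
    ed_dates = pd.DatetimeIndex(
        np.sort(w.loc[(w["code_type"] == "revenue") & w["code"].isin(cs["ed_revenue"]), "service_date"].unique())
    )

    link = pd.Timedelta(days=config.ed_linkage_days)
    reclassified: list[tuple[pd.Timestamp, str]] = []
    n_ed = 0
    for d in ed_dates:
        if len(surg_dates) and ((surg_dates >= d) & (surg_dates <= d + link)).any():
            reclassified.append((d, "surgery"))  # surgery precedence
        elif any(start - link <= d <= end for start, end in episodes):
            reclassified.append((d, "hospitalization"))
        else:
            n_ed += 1

    if eligibility_end is not None:
        followup = min(365, (min(eligibility_end, window_end - pd.Timedelta(days=1)) - index_date).days + 1)
    else:
        followup = 365
    pid = claims["patient_id"].iloc[0] if len(claims) else ""
    return OutcomeRecord(
        patient_id=pid,
        index_date=index_date,
        n_hospitalizations=len(episodes),
        n_surgeries=len(surg_dates),
        n_ed_visits=n_ed,
        followup_days=followup,
        reclassified_ed=tuple(reclassified),
    )


def extract_outcomes(
    claims: pd.DataFrame,
    cohort: pd.DataFrame,
    config: CohortConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, OutcomeRecord]]:
    """Per-patient outcome table for a whole cohort.

    Returns ``(outcomes, records)`` — the tidy DataFrame plus the underlying
    :class:`OutcomeRecord` objects keyed by patient (the costs module needs
    the reclassification details).
    """
    config = config or CohortConfig()
    by_pid = dict(iter(claims.groupby("patient_id"))) if len(claims) else {}
    empty = claims.iloc[0:0]
    records: dict[str, OutcomeRecord] = {}
    rows = []
    for _, row in cohort.iterrows():
        pid = row["patient_id"]
        rec = extract_events(
            by_pid.get(pid, empty),
            row["index_date"],
            config,
            eligibility_end=row.get("eligibility_end"),
        )
        rec = OutcomeRecord(
            patient_id=pid,
            index_date=rec.index_date,
            n_hospitalizations=rec.n_hospitalizations,
            n_surgeries=rec.n_surgeries,
            n_ed_visits=rec.n_ed_visits,
            followup_days=rec.followup_days,
            reclassified_ed=rec.reclassified_ed,
        )
        records[pid] = rec
        rows.append(
            {
                "patient_id": pid,
                "had_hospitalization": rec.had_hospitalization,
                "had_surgery": rec.had_surgery,
                "had_ed_visit": rec.had_ed_visit,
                "n_hospitalizations": rec.n_hospitalizations,
                "n_surgeries": rec.n_surgeries,
                "n_ed_visits": rec.n_ed_visits,
                "followup_days": rec.followup_days,
            }
        )
    columns = [
        "patient_id", "had_hospitalization", "had_surgery", "had_ed_visit",
        "n_hospitalizations", "n_surgeries", "n_ed_visits", "followup_days",
    ]
    outcomes = pd.DataFrame(rows, columns=columns)
    return outcomes, records


def event_proportions(outcomes: pd.DataFrame, strata: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum event proportions and incidence rates.

    ``strata`` maps patient_id -> stratum.  For each stratum and event type
    the table reports the numerator (patients with >=1 event), denominator,
    percentage, and the incidence rate in events per person-year (person-time
    from ``followup_days``).  Empty strata yield missing proportions.
    """
    joined = outcomes.merge(strata[["patient_id", "stratum"]], on="patient_id", how="inner")
    rows = []
    for stratum, grp in joined.groupby("stratum", sort=False):
        person_years = grp["followup_days"].sum() / 365.25
        for event in EVENT_TYPES:
            flag = {"hospitalization": "had_hospitalization", "surgery": "had_surgery", "ed_visit": "had_ed_visit"}[event]
            count_col = {"hospitalization": "n_hospitalizations", "surgery": "n_surgeries", "ed_visit": "n_ed_visits"}[event]
            denom = len(grp)
            num = int(grp[flag].sum())
            rows.append(
                {
                    "stratum": stratum,
                    "event": event,
                    "n_patients": denom,
                    "n_with_event": num,
                    "proportion_pct": round(100.0 * num / denom, 1) if denom else float("nan"),
                    "events_per_person_year": float(grp[count_col].sum() / person_years) if person_years > 0 else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["stratum", "event", "n_patients", "n_with_event", "proportion_pct", "events_per_person_year"])
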