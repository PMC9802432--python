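"""Cohort construction: eligibility filters, index dates, baseline features.

The study design is a standard new-user claims cohort: the index date is the
first claim for the index drug inside the accrual window; patients must be
adults with two Crohn's-disease diagnoses at least 30 days apart before
index (and after 2000-01-01), and must hold one continuous insurance
enrollment span covering 6 months (183 days) on either side of index.
Baseline features cover the three CDST clinical risk factors (lifetime
pre-index history), the most recent pre-index albumin/CRP, prior-year event
flags, and first-year concomitant medication.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .codes import default_code_sets
from .dataset import ClaimsDataset


class DataError(ValueError):
    """Input data inconsistent with the cohort contract (not an eligibility failure)."""


class CohortConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    index_drug: str = "vedolizumab"  # key into code_sets naming the index-drug code list
    index_window: tuple[dt.date, dt.date] = (dt.date(2014, 5, 1), dt.date(2018, 3, 31))
    min_age_years: int = Field(default=18, gt=0)
    dx_separation_days: int = Field(default=30, gt=0)
    dx_earliest: dt.date = dt.date(2000, 1, 1)
    pre_enroll_days: int = Field(default=183, gt=0)
    post_enroll_days: int = Field(default=183, gt=0)
    baseline_lab_lookback_days: int = Field(default=90, gt=0)
    enrollment_gap_days: int = Field(default=0, ge=0)
    ed_linkage_days: int = Field(default=1, ge=0)
    code_sets: dict[str, frozenset[str]] = Field(default_factory=default_code_sets)

    @field_validator("code_sets")
    @classmethod
    def _non_empty(cls, v: dict[str, frozenset[str]]) -> dict[str, frozenset[str]]:
        for name, codes in v.items():
            if not codes:
                raise ValueError(f"code_sets['{name}'] must be non-empty")
        return v

    @property
    def index_drug_codes(self) -> frozenset[str]:
        return self.code_sets[self.index_drug]

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "code_sets" in raw:
            merged = default_code_sets()
            merged.update({k: frozenset(v) for k, v in raw["code_sets"].items()})
            raw["code_sets"] = merged
        return cls.model_validate(raw)


def merge_enrollment_spans(spans: pd.DataFrame, gap_days: int = 0) -> tuple[pd.DataFrame, int]:
    """Merge overlapping (or gap-tolerated) spans; returns (merged, n_merges)."""
    spans = spans.sort_values("start_date")
    merged: list[list[pd.Timestamp]] = []
    n_merges = 0
    for _, row in spans.iterrows():
        if merged and row["start_date"] <= merged[-1][1] + pd.Timedelta(days=gap_days + 1):
            if row["end_date"] > merged[-1][1]:
                merged[-1][1] = row["end_date"]
            n_merges += 1
        else:
            merged.append([row["start_date"], row["end_date"]])
    return pd.DataFrame(merged, columns=["start_date", "end_date"]), n_merges


def find_index_date(claims: pd.DataFrame, config: CohortConfig) -> pd.Timestamp | None:
    """Earliest index-drug claim date inside the accrual window, else ``None``."""
    w0, w1 = (pd.Timestamp(d) for d in config.index_window)
    hits = claims[
        (claims["code_type"] == "drug")
        & claims["code"].isin(config.index_drug_codes)
        & (claims["service_date"] >= w0)
        & (claims["service_date"] <= w1)
    ]
    if not len(hits):
        return None
    return hits["service_date"].min()


def check_eligibility(
    patient: Mapping,
    claims: pd.DataFrame,
    enrollment: pd.DataFrame,
    index_date: pd.Timestamp,
    config: CohortConfig,
) -> tuple[bool, list[str]]:
    """Evaluate the eligibility criteria; returns (eligible, failed criteria).

    Failure labels, in application order: ``age``, ``dx_separation``,
    ``pre_enrollment``, ``post_enrollment``.
    """
    if not len(enrollment):
        raise DataError(f"patient {patient['patient_id']} absent from enrollment table")
    failed: list[str] = []

    age = index_date.year - int(patient["birth_year"])
    if age < config.min_age_years:
        failed.append("age")

    dx = claims[
        (claims["code_type"] == "diagnosis")
        & claims["code"].isin(config.code_sets["cd_diagnosis"])
        & (claims["service_date"] < index_date)
        & (claims["service_date"] >= pd.Timestamp(config.dx_earliest))
    ]["service_date"].sort_values()
    # two diagnoses at least dx_separation_days apart (inclusive boundary)
    if len(dx) < 2 or (dx.iloc[-1] - dx.iloc[0]).days < config.dx_separation_days:
        failed.append("dx_separation")

    merged, _ = merge_enrollment_spans(enrollment, config.enrollment_gap_days)
    pre_target = index_date - pd.Timedelta(days=config.pre_enroll_days)
    post_target = index_date + pd.Timedelta(days=config.post_enroll_days)
    covering = merged[(merged["start_date"] <= index_date) & (merged["end_date"] >= index_date)]
    if not len(covering) or (covering["start_date"] > pre_target).all():
        failed.append("pre_enrollment")
    if not len(covering) or (covering["end_date"] < post_target).all():
        failed.append("post_enrollment")
    return (not failed), failed


def derive_baseline_features(
    patient: Mapping,
    claims: pd.DataFrame,
    labs: pd.DataFrame,
    enrollment: pd.DataFrame,
    index_date: pd.Timestamp,
    config: CohortConfig,
) -> dict:
    """Baseline covariates for one eligible patient.

    The three CDST risk factors use full pre-index history; ``prior_year_*``
    flags use the 365 days before index; baseline labs are the most recent
    value in the lookback window (same-day duplicates averaged); concomitant
    medication is any claim in the first post-index year.
    """
    cs = config.code_sets
    pre = claims[claims["service_date"] < index_date]
    year_pre = pre[pre["service_date"] >= index_date - pd.Timedelta(days=365)]
    post_year = claims[(claims["service_date"] >= index_date) & (claims["service_date"] < index_date + pd.Timedelta(days=365))]

    def any_code(frame: pd.DataFrame, codes: frozenset[str], code_type: str | None = None) -> bool:
        sel = frame["code"].isin(codes)
        if code_type is not None:
            sel &= frame["code_type"] == code_type
        return bool(sel.any())

    tnf_agents = set(pre.loc[(pre["code_type"] == "drug") & pre["code"].isin(cs["anti_tnf_drugs"]), "code"])

    def baseline_lab(analyte: str) -> float | None:
        window = labs[
            (labs["analyte"] == analyte)
            & (labs["collection_date"] < index_date)
            & (labs["collection_date"] >= index_date - pd.Timedelta(days=config.baseline_lab_lookback_days))
        ]
        if not len(window):
            return None
        latest = window[window["collection_date"] == window["collection_date"].max()]
        return float(latest["value"].mean())  # same-day duplicates: mean

    cd_dx = pre[(pre["code_type"] == "diagnosis") & pre["code"].isin(cs["cd_diagnosis"])]
    first_dx = cd_dx["service_date"].min()

    merged, _ = merge_enrollment_spans(enrollment, config.enrollment_gap_days)
    span = merged[(merged["start_date"] <= index_date) & (merged["end_date"] >= index_date)]
    eligibility_end = span["end_date"].max()

    prior_year_hosp = bool(
        (
            (year_pre["setting"] == "inpatient")
            & (year_pre["code_type"] == "diagnosis")
            & year_pre["code"].isin(cs["cd_diagnosis"])
        ).any()
    )

    return {
        "patient_id": patient["patient_id"],
        "index_date": index_date,
        "age_at_index": index_date.year - int(patient["birth_year"]),
        "sex": patient["sex"],
        "prior_bowel_surgery": any_code(pre, cs["surgery_procedures"], "procedure"),
        "prior_fistulizing_disease": any_code(pre, cs["fistula_diagnosis"], "diagnosis"),
        "prior_anti_tnf_exposure": len(tnf_agents) >= 1,
        "n_anti_tnf_agents": len(tnf_agents),
        "baseline_albumin": baseline_lab("albumin"),
        "baseline_crp": baseline_lab("crp"),
        "prior_year_hospitalization": prior_year_hosp,
        "prior_year_surgery": any_code(year_pre, cs["surgery_procedures"], "procedure"),
        "prior_year_fistula": any_code(year_pre, cs["fistula_diagnosis"], "diagnosis"),
        "prior_year_stricture": any_code(year_pre, cs["stricture_diagnosis"], "diagnosis"),
        "concomitant_imm": any_code(post_year, cs["immunomodulators"], "drug"),
        "concomitant_cs": any_code(post_year, cs["corticosteroids"], "drug"),
        "disease_duration_years": float((index_date - first_dx).days / 365.25) if pd.notna(first_dx) else None,
        "eligibility_end": eligibility_end,
    }


EXCLUSION_ORDER = ("no_index_claim", "age", "dx_separation", "pre_enrollment", "post_enrollment")


def build_cohort(dataset: ClaimsDataset, config: CohortConfig | None = None) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the eligibility cascade to every patient in the dataset.

    Returns ``(cohort, exclusion_log)`` where the cohort has one
    baseline-feature row per eligible patient and the log counts patients
    removed by the *first* criterion they fail, in application order.
    The result is independent of input row order.
    """
    config = config or CohortConfig()
    log = {k: 0 for k in EXCLUSION_ORDER}
    rows: list[dict] = []

    patients = dataset.patients.sort_values("patient_id")
    claims_by_pid = dict(iter(dataset.claims.groupby("patient_id"))) if len(dataset.claims) else {}
    labs_by_pid = dict(iter(dataset.labs.groupby("patient_id"))) if len(dataset.labs) else {}
    enroll_by_pid = dict(iter(dataset.enrollment.groupby("patient_id"))) if len(dataset.enrollment) else {}
    empty_claims = dataset.claims.iloc[0:0]
    empty_labs = dataset.labs.iloc[0:0]

    for _, patient in patients.iterrows():
        pid = patient["patient_id"]
        claims = claims_by_pid.get(pid, empty_claims)
        index_date = find_index_date(claims, config)
        if index_date is None:
            log["no_index_claim"] += 1
            continue
        enrollment = enroll_by_pid.get(pid, dataset.enrollment.iloc[0:0])
        eligible, failed = check_eligibility(patient, claims, enrollment, index_date, config)
        if not eligible:
            log[failed[0]] += 1
            continue
        rows.append(
            derive_baseline_features(patient, claims, labs_by_pid.get(pid, empty_labs), enrollment, index_date, config)
        )

    if not rows:
        cohort = pd.DataFrame(
            columns=[
                "patient_id", "index_date", "age_at_index", "sex", "prior_bowel_surgery",
                "prior_fistulizing_disease", "prior_anti_tnf_exposure", "n_anti_tnf_agents",
                "baseline_albumin", "baseline_crp", "prior_year_hospitalization", "prior_year_surgery",
                "prior_year_fistula", "prior_year_stricture", "concomitant_imm", "concomitant_cs",
                "disease_duration_years", "eligibility_end",
            ]
        )
    else:
        cohort = pd.DataFrame(rows)
    log = {k: v for k, v in log.items() if v}
    return cohort.reset_index(drop=True), log
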