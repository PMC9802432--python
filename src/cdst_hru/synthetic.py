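"""Synthetic longitudinal-claims generator.

Emulates the statistical structure of an administrative claims extract for a
biologic-treated Crohn's-disease cohort: each simulated patient carries a
latent response-probability stratum (high / intermediate / low) that drives
their pre-index risk-factor history, baseline laboratory values, 12-month
post-index event draws (hospitalization, surgery, ED visit) and right-skewed
(log-normal) claim costs.  The latent stratum is returned in a separate truth
table and never appears inside the :class:`~cdst_hru.dataset.ClaimsDataset`,
so downstream stages cannot peek at it.

Every generated patient is constructed to satisfy the cohort-eligibility
filters (index drug claim inside the index window, two CD diagnoses >=30 days
apart before index, adult age, continuous pre/post enrollment), so a default
simulation yields a cohort of exactly ``n_patients``; eligibility edge cases
are exercised by perturbing the output tables in tests rather than by the
generator itself.

Default parameters reproduce the published study conditions where those are
stated (index window, stratum mix, high/low event rates) and field-realistic
values elsewhere; see ``docs/methods.md`` for the full rationale.
"""

from __future__ import annotations

import datetime as dt
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .dataset import CLAIM_COLUMNS, ClaimsDataset, empty_dataset

STRATA = ("high", "intermediate", "low")
COST_CATEGORIES = ("hospitalization", "surgery", "ed_visit", "office_visit", "endoscopy_scan", "lab_test")


class StratumEventProbs(BaseModel):
    """12-month event probabilities for one latent stratum."""

    model_config = ConfigDict(frozen=True)
    hospitalization: float = Field(ge=0.0, le=1.0)
    surgery: float = Field(ge=0.0, le=1.0)
    ed_visit: float = Field(ge=0.0, le=1.0)


class CostParams(BaseModel):
    """Log-normal location/scale for one cost category, 2017 USD per claim."""

    model_config = ConfigDict(frozen=True)
    log_mean: float
    log_sd: float = Field(gt=0.0)

    @property
    def mean(self) -> float:
        return float(np.exp(self.log_mean + self.log_sd**2 / 2))


class StratumLabParams(BaseModel):
    """Baseline laboratory model: albumin ~ Normal, CRP drawn by band.

    ``crp_band_probs`` are the probabilities of the <3, 3-10 and >10 mg/L
    bands (the bands the 5-variable CDST penalizes).
    """

    model_config = ConfigDict(frozen=True)
    albumin_mean: float = Field(gt=0.0)
    albumin_sd: float = Field(gt=0.0)
    crp_band_probs: tuple[float, float, float]

    @model_validator(mode="after")
    def _bands_sum_to_one(self) -> "StratumLabParams":
        if any(p < 0 or p > 1 for p in self.crp_band_probs):
            raise ValueError("crp_band_probs: probabilities must be in [0, 1]")
        if abs(sum(self.crp_band_probs) - 1.0) > 1e-9:
            raise ValueError("crp_band_probs: must sum to 1")
        return self


class StratumFeatureProbs(BaseModel):
    """Probabilities of the three CDST risk factors for one stratum."""

    model_config = ConfigDict(frozen=True)
    prior_surgery: float = Field(ge=0.0, le=1.0)
    prior_fistula: float = Field(ge=0.0, le=1.0)
    prior_anti_tnf: float = Field(ge=0.0, le=1.0)


class EnrollmentSlack(BaseModel):
    """Uniform ranges (days) for pre- and post-index enrollment length."""

    model_config = ConfigDict(frozen=True)
    # lower bounds keep every generated patient constructible as eligible
    # (two CD diagnoses fit before index; 6-month pre/post enrollment holds)
    pre_min: int = Field(default=400, ge=183)
    pre_max: int = Field(default=1500, gt=0)
    post_min: int = Field(default=366, ge=183)
    post_max: int = Field(default=1095, gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "EnrollmentSlack":
        if self.pre_max < self.pre_min or self.post_max < self.post_min:
            raise ValueError("enrollment_slack: max must be >= min")
        return self


def _default_event_probs() -> dict[str, StratumEventProbs]:
    return {
        "high": StratumEventProbs(hospitalization=0.190, surgery=0.084, ed_visit=0.15),
        "intermediate": StratumEventProbs(hospitalization=0.310, surgery=0.190, ed_visit=0.22),
        "low": StratumEventProbs(hospitalization=0.481, surgery=0.444, ed_visit=0.30),
    }


def _default_cost_params() -> dict[str, CostParams]:
    return {
        "hospitalization": CostParams(log_mean=9.9, log_sd=1.2),
        "surgery": CostParams(log_mean=7.6, log_sd=1.0),
        "ed_visit": CostParams(log_mean=8.9, log_sd=1.1),
        "office_visit": CostParams(log_mean=4.9, log_sd=0.5),
        "endoscopy_scan": CostParams(log_mean=7.2, log_sd=0.6),
        "lab_test": CostParams(log_mean=4.0, log_sd=0.4),
    }


def _default_lab_params() -> dict[str, StratumLabParams]:
    return {
        "high": StratumLabParams(albumin_mean=42.0, albumin_sd=3.0, crp_band_probs=(0.70, 0.25, 0.05)),
        "intermediate": StratumLabParams(albumin_mean=38.0, albumin_sd=3.0, crp_band_probs=(0.40, 0.40, 0.20)),
        "low": StratumLabParams(albumin_mean=32.0, albumin_sd=3.0, crp_band_probs=(0.10, 0.40, 0.50)),
    }


def _default_feature_probs() -> dict[str, StratumFeatureProbs]:
    return {
        "high": StratumFeatureProbs(prior_surgery=0.05, prior_fistula=0.08, prior_anti_tnf=0.60),
        "intermediate": StratumFeatureProbs(prior_surgery=0.30, prior_fistula=0.40, prior_anti_tnf=0.90),
        "low": StratumFeatureProbs(prior_surgery=0.70, prior_fistula=0.80, prior_anti_tnf=1.00),
    }


class SimulationConfig(BaseModel):
    """Full parameterization of one simulated claims extract."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(default=358, ge=0)
    seed: int = 0
    date_window: tuple[dt.date, dt.date] = (dt.date(2014, 5, 1), dt.date(2018, 3, 31))
    stratum_mix: dict[str, float] = Field(
        default_factory=lambda: {"high": 0.50, "intermediate": 0.425, "low": 0.075}
    )
    event_probs: dict[str, StratumEventProbs] = Field(default_factory=_default_event_probs)
    cost_params: dict[str, CostParams] = Field(default_factory=_default_cost_params)
    lab_params: dict[str, StratumLabParams] = Field(default_factory=_default_lab_params)
    feature_probs: dict[str, StratumFeatureProbs] = Field(default_factory=_default_feature_probs)
    enrollment_slack: EnrollmentSlack = Field(default_factory=EnrollmentSlack)
    dropout_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    # ancillary utilization shared by all strata
    office_visit_rate: float = Field(default=4.0, ge=0.0)  # expected visits / 12 months
    lab_test_rate: float = Field(default=6.0, ge=0.0)
    endoscopy_prob: float = Field(default=0.5, ge=0.0, le=1.0)
    ed_linked_fraction: float = Field(default=0.3, ge=0.0, le=1.0)  # hospitalizations arriving via the ED
    concomitant_imm_prob: float = Field(default=0.27, ge=0.0, le=1.0)
    concomitant_cs_prob: float = Field(default=0.53, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _validate(self) -> "SimulationConfig":
        if set(self.stratum_mix) != set(STRATA):
            raise ValueError(f"stratum_mix: must have exactly the keys {STRATA}")
        if any(p < 0 or p > 1 for p in self.stratum_mix.values()):
            raise ValueError("stratum_mix: proportions must be in [0, 1]")
        if abs(sum(self.stratum_mix.values()) - 1.0) > 1e-9:
            raise ValueError("stratum_mix: proportions must sum to 1")
        for field in ("event_probs", "lab_params", "feature_probs"):
            if set(getattr(self, field)) != set(STRATA):
                raise ValueError(f"{field}: must have exactly the keys {STRATA}")
        if set(self.cost_params) != set(COST_CATEGORIES):
            raise ValueError(f"cost_params: must have exactly the keys {COST_CATEGORIES}")
        if self.date_window[1] < self.date_window[0]:
            raise ValueError("date_window: end before start")
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def expected_annual_cost(config: SimulationConfig, stratum: str) -> float:
    """Planted mean annualized total cost for one stratum (no-dropout analysis).

    Closed form: each event category contributes ``P(event) * E[log-normal]``;
    an ED claim attached to a hospitalization is billed to the hospitalization
    category (mirroring the downstream reclassification rule); office visits
    and laboratory tests contribute ``rate * E[cost]``.
    """
    ep = config.event_probs[stratum]
    cp = {k: v.mean for k, v in config.cost_params.items()}
    return (
        ep.hospitalization * (cp["hospitalization"] + config.ed_linked_fraction * cp["ed_visit"])
        + ep.surgery * cp["surgery"]
        + ep.ed_visit * cp["ed_visit"]
        + config.office_visit_rate * cp["office_visit"]
        + config.lab_test_rate * cp["lab_test"]
        + config.endoscopy_prob * cp["endoscopy_scan"]
    )


_CRP_BAND_RANGES = ((0.2, 2.9), (3.0, 10.0), (10.1, 40.0))


def generate_dataset(config: SimulationConfig, seed: int | None = None) -> tuple[ClaimsDataset, pd.DataFrame]:
    """Generate a claims extract plus its latent-stratum truth table.

    Returns ``(dataset, truth)`` where ``truth`` has columns ``patient_id``
    and ``stratum``.  Identical ``(config, seed)`` reproduce identical output.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    if n == 0:
        return empty_dataset(), pd.DataFrame(columns=["patient_id", "stratum"])

    pid = np.array([f"P{i:06d}" for i in range(n)], dtype=object)
    mix = np.array([config.stratum_mix[s] for s in STRATA])
    stratum = rng.choice(np.array(STRATA, dtype=object), size=n, p=mix)

    w0, w1 = (pd.Timestamp(d) for d in config.date_window)
    index_date = w0 + pd.to_timedelta(rng.integers(0, (w1 - w0).days + 1, size=n), unit="D")

    age = rng.integers(18, 81, size=n)
    birth_year = index_date.year.to_numpy() - age
    sex = rng.choice(np.array(["F", "M"], dtype=object), size=n, p=[0.57, 0.43])

    es = config.enrollment_slack
    pre_days = rng.integers(es.pre_min, es.pre_max + 1, size=n)
    dropout = rng.random(n) < config.dropout_prob
    post_full = rng.integers(es.post_min, es.post_max + 1, size=n)
    post_short = rng.integers(183, 365, size=n)
    post_days = np.where(dropout, post_short, post_full)
    enroll_start = index_date - pd.to_timedelta(pre_days, unit="D")
    enroll_end = index_date + pd.to_timedelta(post_days, unit="D")

    def pick(field: str, sub: str | None = None) -> np.ndarray:
        table = getattr(config, field)
        if sub is None:
            return np.array([table[s] for s in stratum])
        return np.array([getattr(table[s], sub) for s in stratum])

    claim_blocks: list[pd.DataFrame] = []

    def add_claims(mask, dates, code_type, code, setting, paid):
        """Append one block of claims; every argument may be scalar or array."""
        idx = np.flatnonzero(mask) if mask is not None else np.arange(n)
        if len(idx) == 0:
            return
        dates = pd.DatetimeIndex(dates)
        block = pd.DataFrame(
            {
                "patient_id": pid[idx],
                "service_date": dates,
                "code_type": code_type if isinstance(code_type, str) else np.asarray(code_type, dtype=object),
                "code": code if isinstance(code, str) else np.asarray(code, dtype=object),
                "setting": setting if isinstance(setting, str) else np.asarray(setting, dtype=object),
                "paid_amount": np.round(np.broadcast_to(np.asarray(paid, dtype=float), (len(idx),)), 2),
            }
        )
        claim_blocks.append(block)

    def lognormal(category: str, size: int) -> np.ndarray:
        p = config.cost_params[category]
        return rng.lognormal(p.log_mean, p.log_sd, size=size)

    # --- index drug claim (vedolizumab initiation), anchors everything ---
    add_claims(None, index_date, "drug", "RX_VEDO", "pharmacy", np.zeros(n))

    # --- two qualifying CD diagnoses, >=30 days apart, before index ---
    dx1 = index_date - pd.to_timedelta(pre_days - rng.integers(0, 30, size=n), unit="D")
    dx2 = dx1 + pd.to_timedelta(30 + rng.integers(0, 120, size=n), unit="D")
    add_claims(None, dx1, "diagnosis", "DX_CD", "outpatient", lognormal("office_visit", n))
    add_claims(None, dx2, "diagnosis", "DX_CD", "outpatient", lognormal("office_visit", n))

    # --- pre-index risk-factor history driven by the latent stratum ---
    p_surg = pick("feature_probs", "prior_surgery")
    p_fist = pick("feature_probs", "prior_fistula")
    p_tnf = pick("feature_probs", "prior_anti_tnf")
    has_surg = rng.random(n) < p_surg
    has_fist = rng.random(n) < p_fist
    has_tnf = rng.random(n) < p_tnf
    lookback = np.minimum(pre_days - 30, 1000)
    surg_off = rng.integers(60, 1001, size=n) % np.maximum(lookback - 60, 1) + 60
    fist_off = rng.integers(60, 1001, size=n) % np.maximum(lookback - 60, 1) + 60
    add_claims(
        has_surg,
        index_date[has_surg] - pd.to_timedelta(surg_off[has_surg], unit="D"),
        "procedure", "PX_BOWEL_SURG", "inpatient", lognormal("surgery", int(has_surg.sum())),
    )
    add_claims(
        has_fist,
        index_date[has_fist] - pd.to_timedelta(fist_off[has_fist], unit="D"),
        "diagnosis", "DX_FISTULA", "outpatient", lognormal("office_visit", int(has_fist.sum())),
    )
    tnf_codes = np.array(sorted({"RX_TNF_IFX", "RX_TNF_ADA", "RX_TNF_CZP"}), dtype=object)
    second_agent = rng.random(n) < 0.4
    first_code = rng.choice(tnf_codes, size=n)
    shift = rng.integers(1, 3, size=n)
    second_code = tnf_codes[(np.searchsorted(tnf_codes, first_code) + shift) % 3]
    tnf_off1 = 30 + rng.integers(0, 271, size=n) % np.maximum(pre_days - 30, 1)
    tnf_off2 = 30 + rng.integers(0, 271, size=n) % np.maximum(pre_days - 30, 1)
    add_claims(has_tnf, index_date[has_tnf] - pd.to_timedelta(tnf_off1[has_tnf], unit="D"),
               "drug", first_code[has_tnf], "pharmacy", np.zeros(int(has_tnf.sum())))
    both = has_tnf & second_agent
    add_claims(both, index_date[both] - pd.to_timedelta(tnf_off2[both], unit="D"),
               "drug", second_code[both], "pharmacy", np.zeros(int(both.sum())))

    # --- concomitant medications in the post-index year ---
    for code, prob in (("RX_IMM", config.concomitant_imm_prob), ("RX_CS", config.concomitant_cs_prob)):
        has = rng.random(n) < prob
        off = rng.integers(0, 180, size=n)
        add_claims(has, index_date[has] + pd.to_timedelta(off[has], unit="D"),
                   "drug", code, "pharmacy", np.zeros(int(has.sum())))

    # --- baseline labs inside the 90-day pre-index lookback ---
    alb_mean = pick("lab_params", "albumin_mean")
    alb_sd = pick("lab_params", "albumin_sd")
    alb = np.round(rng.normal(alb_mean, alb_sd), 1)
    alb_off = rng.integers(7, 61, size=n)
    crp_u = rng.random(n)
    band_probs = np.array([config.lab_params[s].crp_band_probs for s in stratum])
    cum = band_probs.cumsum(axis=1)
    band = (crp_u[:, None] > cum).sum(axis=1)
    lo = np.array([_CRP_BAND_RANGES[b][0] for b in band])
    hi = np.array([_CRP_BAND_RANGES[b][1] for b in band])
    crp = np.round(lo + rng.random(n) * (hi - lo), 1)
    crp_off = rng.integers(7, 61, size=n)
    labs = pd.DataFrame(
        {
            "patient_id": np.concatenate([pid, pid]),
            "collection_date": pd.DatetimeIndex(
                np.concatenate(
                    [
                        (index_date - pd.to_timedelta(alb_off, unit="D")).to_numpy(),
                        (index_date - pd.to_timedelta(crp_off, unit="D")).to_numpy(),
                    ]
                )
            ),
            "analyte": np.array(["albumin"] * n + ["crp"] * n, dtype=object),
            "value": np.concatenate([alb, crp]),
            "unit": np.array(["g/L"] * n + ["mg/L"] * n, dtype=object),
        }
    )

    # --- 12-month post-index events; dates censored at the enrollment end ---
    ep_hosp = pick("event_probs", "hospitalization")
    ep_surg = pick("event_probs", "surgery")
    ep_ed = pick("event_probs", "ed_visit")
    ev_hosp = rng.random(n) < ep_hosp
    ev_surg = rng.random(n) < ep_surg
    ev_ed = rng.random(n) < ep_ed
    hosp_off = rng.integers(7, 351, size=n)
    surg_off_post = rng.integers(7, 351, size=n)
    # standalone ED visits must not sit in the reclassification window of a
    # hospitalization or surgery, or they would be absorbed by the linkage rule
    ed_off = rng.integers(7, 351, size=n)
    for _ in range(8):
        clash = ev_ed & (
            (ev_hosp & (np.abs(ed_off - hosp_off) <= 1)) | (ev_surg & (np.abs(ed_off - surg_off_post) <= 1))
        )
        if not clash.any():
            break
        ed_off[clash] = rng.integers(7, 351, size=int(clash.sum()))

    in_span = lambda off: off <= post_days  # censoring by dropout
    m = ev_hosp & in_span(hosp_off)
    hosp_dates = index_date[m] + pd.to_timedelta(hosp_off[m], unit="D")
    add_claims(m, hosp_dates, "diagnosis", "DX_CD", "inpatient", lognormal("hospitalization", int(m.sum())))
    linked = m & (rng.random(n) < config.ed_linked_fraction)
    add_claims(
        linked,
        index_date[linked] + pd.to_timedelta(hosp_off[linked], unit="D"),
        "revenue", "0450", "ED", lognormal("ed_visit", int(linked.sum())),
    )
    m = ev_surg & in_span(surg_off_post)
    add_claims(m, index_date[m] + pd.to_timedelta(surg_off_post[m], unit="D"),
               "procedure", "PX_BOWEL_SURG", "inpatient", lognormal("surgery", int(m.sum())))
    m = ev_ed & in_span(ed_off)
    ed_codes = np.array(sorted({f"{c:04d}" for c in range(450, 460)} | {"0981"}), dtype=object)
    add_claims(m, index_date[m] + pd.to_timedelta(ed_off[m], unit="D"),
               "revenue", rng.choice(ed_codes, size=int(m.sum())), "ED", lognormal("ed_visit", int(m.sum())))

    # --- ancillary utilization: office visits, lab tests, endoscopy/scan ---
    office_cpt = np.array([str(c) for c in range(99211, 99216)], dtype=object)
    lab_rev = np.array(sorted(f"{c:04d}" for c in range(300, 320)), dtype=object)
    for rate, codes, category, setting, ctype in (
        (config.office_visit_rate, office_cpt, "office_visit", "outpatient", "procedure"),
        (config.lab_test_rate, lab_rev, "lab_test", "outpatient", "revenue"),
    ):
        counts = rng.poisson(rate, size=n)
        rep = np.repeat(np.arange(n), counts)
        if len(rep):
            offs = rng.integers(0, 351, size=len(rep))
            keep = offs <= post_days[rep]
            rep, offs = rep[keep], offs[keep]
            dates = index_date[rep] + pd.to_timedelta(offs, unit="D")
            claim_blocks.append(
                pd.DataFrame(
                    {
                        "patient_id": pid[rep],
                        "service_date": pd.DatetimeIndex(dates),
                        "code_type": ctype,
                        "code": rng.choice(codes, size=len(rep)),
                        "setting": setting,
                        "paid_amount": np.round(lognormal(category, len(rep)), 2),
                    }
                )
            )
    has_endo = rng.random(n) < config.endoscopy_prob
    endo_off = rng.integers(0, 351, size=n)
    m = has_endo & in_span(endo_off)
    endo_codes = np.array(["PX_ENDOSCOPY", "PX_SCAN"], dtype=object)
    add_claims(m, index_date[m] + pd.to_timedelta(endo_off[m], unit="D"),
               "procedure", rng.choice(endo_codes, size=int(m.sum())), "outpatient",
               lognormal("endoscopy_scan", int(m.sum())))

    claims = pd.concat(claim_blocks, ignore_index=True)
    claims["service_year"] = claims["service_date"].dt.year.astype("int64")
    claims = claims.sort_values(
        ["patient_id", "service_date", "code_type", "code", "setting", "paid_amount"],
        kind="mergesort",
    ).reset_index(drop=True)[CLAIM_COLUMNS]
    labs = labs.sort_values(["patient_id", "collection_date", "analyte"], kind="mergesort").reset_index(drop=True)

    dataset = ClaimsDataset(
        patients=pd.DataFrame({"patient_id": pid, "birth_year": birth_year, "sex": sex}),
        enrollment=pd.DataFrame({"patient_id": pid, "start_date": enroll_start, "end_date": enroll_end}),
        claims=claims,
        labs=labs,
    )
    truth = pd.DataFrame({"patient_id": pid, "stratum": stratum})
    return dataset, truth
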