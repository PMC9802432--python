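"""Vedolizumab CDST scoring: 5-variable and modified 3-variable variants.

The 5-variable score awards points for the *absence* of three clinical risk
factors — no prior bowel surgery (+2), no prior fistulizing disease (+2), no
prior anti-TNF exposure (+3) — plus two laboratory terms: +0.4 points per g/L
of albumin, and a CRP penalty of -0.5 points for CRP in [3.0, 10.0] mg/L or
-3 points for CRP > 10.0 mg/L.  Strata: high if score > 19, intermediate if
13 < score <= 19, low if score <= 13.

The modified 3-variable score keeps only the clinical points (so it needs no
laboratory data); scores lie in {0, 2, 3, 4, 5, 7} and the high/low cutoff is
3 points (high ⇔ score > 3, i.e. at least two of the three favorable
factors).

Patients missing a baseline albumin or CRP cannot be scored with the
5-variable tool; they are flagged ``inputs_complete = False`` and excluded
from 5-variable analyses rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

Variant = Literal["five_var", "three_var"]


@dataclass(frozen=True)
class CDSTWeights:
    no_prior_surgery_pts: float = 2.0
    no_prior_fistula_pts: float = 2.0
    no_prior_antitnf_pts: float = 3.0
    albumin_pts_per_g_l: float = 0.4
    crp_mid_penalty: float = -0.5  # CRP in [crp_mid_low, crp_mid_high] mg/L
    crp_high_penalty: float = -3.0  # CRP > crp_mid_high mg/L
    crp_mid_low: float = 3.0
    crp_mid_high: float = 10.0
    cut_high_5var: float = 19.0
    cut_low_5var: float = 13.0
    cut_3var: float = 3.0

    def __post_init__(self) -> None:
        if self.cut_high_5var <= self.cut_low_5var:
            raise ValueError("cut_high_5var must exceed cut_low_5var")
        for name in ("no_prior_surgery_pts", "no_prior_fistula_pts", "no_prior_antitnf_pts", "albumin_pts_per_g_l"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CDSTResult:
    patient_id: str
    variant: Variant
    score: float | None
    stratum: str | None  # high / intermediate / low (five_var); high / low (three_var)
    inputs_complete: bool


def crp_penalty(crp: float, weights: CDSTWeights) -> float:
    """Piecewise-constant CRP term; the band [3.0, 10.0] is closed on both ends."""
    if crp > weights.crp_mid_high:
        return weights.crp_high_penalty
    if crp >= weights.crp_mid_low:
        return weights.crp_mid_penalty
    return 0.0


def clinical_points(features: Mapping, weights: CDSTWeights) -> float:
    return (
        (0.0 if features["prior_bowel_surgery"] else weights.no_prior_surgery_pts)
        + (0.0 if features["prior_fistulizing_disease"] else weights.no_prior_fistula_pts)
        + (0.0 if features["prior_anti_tnf_exposure"] else weights.no_prior_antitnf_pts)
    )


def classify_5var(score: float, weights: CDSTWeights) -> str:
    if score > weights.cut_high_5var:
        return "high"
    if score > weights.cut_low_5var:
        return "intermediate"
    return "low"


def classify_3var(score: float, weights: CDSTWeights) -> str:
    return "high" if score > weights.cut_3var else "low"


def score_5var(features: Mapping, weights: CDSTWeights | None = None) -> CDSTResult:
    weights = weights or CDSTWeights()
    albumin = features.get("baseline_albumin")
    crp = features.get("baseline_crp")
    if albumin is None or crp is None or pd.isna(albumin) or pd.isna(crp):
        return CDSTResult(features["patient_id"], "five_var", None, None, inputs_complete=False)
    score = clinical_points(features, weights) + weights.albumin_pts_per_g_l * float(albumin) + crp_penalty(float(crp), weights)
    return CDSTResult(features["patient_id"], "five_var", score, classify_5var(score, weights), True)


def score_3var(features: Mapping, weights: CDSTWeights | None = None) -> CDSTResult:
    weights = weights or CDSTWeights()
    score = clinical_points(features, weights)
    return CDSTResult(features["patient_id"], "three_var", score, classify_3var(score, weights), True)


def score_cohort(cohort: pd.DataFrame, variant: Variant, weights: CDSTWeights | None = None) -> pd.DataFrame:
    """Score every cohort row; returns patient_id / variant / score / stratum /
    inputs_complete.  For ``five_var``, rows with missing labs keep a null
    score and stratum (``inputs_complete == False``)."""
    if variant not in ("five_var", "three_var"):
        raise ValueError(f"unknown CDST variant: {variant!r} (expected 'five_var' or 'three_var')")
    weights = weights or CDSTWeights()
    if not len(cohort):
        return pd.DataFrame(columns=["patient_id", "variant", "score", "stratum", "inputs_complete"])

    clin = (
        np.where(cohort["prior_bowel_surgery"], 0.0, weights.no_prior_surgery_pts)
        + np.where(cohort["prior_fistulizing_disease"], 0.0, weights.no_prior_fistula_pts)
        + np.where(cohort["prior_anti_tnf_exposure"], 0.0, weights.no_prior_antitnf_pts)
    )
    if variant == "three_var":
        score = pd.Series(clin, index=cohort.index)
        stratum = np.where(score > weights.cut_3var, "high", "low")
        complete = np.ones(len(cohort), dtype=bool)
    else:
        albumin = pd.to_numeric(cohort["baseline_albumin"], errors="coerce")
        crp = pd.to_numeric(cohort["baseline_crp"], errors="coerce")
        complete = albumin.notna().to_numpy() & crp.notna().to_numpy()
        penalty = np.select(
            [crp > weights.crp_mid_high, crp >= weights.crp_mid_low],
            [weights.crp_high_penalty, weights.crp_mid_penalty],
            default=0.0,
        )
        score = pd.Series(clin + weights.albumin_pts_per_g_l * albumin + penalty, index=cohort.index)
        stratum = np.select(
            [score > weights.cut_high_5var, score > weights.cut_low_5var],
            ["high", "intermediate"],
            default="low",
        ).astype(object)
        score = score.where(complete)
        stratum = np.where(complete, stratum, None)
    return pd.DataFrame(
        {
            "patient_id": cohort["patient_id"].to_numpy(),
            "variant": variant,
            "score": score.to_numpy(),
            "stratum": stratum,
            "inputs_complete": complete,
        }
    )
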