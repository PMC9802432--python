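"""Cohort construction: index dates, eligibility cascade, baseline features."""

import pandas as pd
import pytest

from cdst_hru.cohort import (
    CohortConfig,
    build_cohort,
    check_eligibility,
    derive_baseline_features,
    find_index_date,
)
from cdst_hru.dataset import ClaimsDataset, empty_dataset
from cdst_hru.synthetic import SimulationConfig, generate_dataset
from conftest import claims_frame, enrollment_frame, labs_frame

CFG = CohortConfig()
PATIENT = {"patient_id": "P1", "birth_year": 1975, "sex": "F"}


class TestFindIndexDate:
    def test_earliest_index_drug_claim_wins(self):
        claims = claims_frame(
            [
                ("P1", "2015-06-01", "drug", "RX_VEDO", "pharmacy", 0.0),
                ("P1", "2015-03-01", "drug", "RX_VEDO", "pharmacy", 0.0),
            ]
        )
        assert find_index_date(claims, CFG) == pd.Timestamp("2015-03-01")

    def test_claim_before_accrual_window_is_ignored(self):
        claims = claims_frame([("P1", "2014-04-30", "drug", "RX_VEDO", "pharmacy", 0.0)])
        assert find_index_date(claims, CFG) is None

    def test_no_index_drug_claims(self):
        claims = claims_frame([("P1", "2015-03-01", "diagnosis", "DX_CD", "outpatient", 10.0)])
        assert find_index_date(claims, CFG) is None


def _eligible_claims(index="2015-06-01", dx_gap_days=30):
    d1 = pd.Timestamp("2014-01-01")
    d2 = d1 + pd.Timedelta(days=dx_gap_days)
    return claims_frame(
        [
            ("P1", d1, "diagnosis", "DX_CD", "outpatient", 10.0),
            ("P1", d2, "diagnosis", "DX_CD", "outpatient", 10.0),
            ("P1", index, "drug", "RX_VEDO", "pharmacy", 0.0),
        ]
    )


class TestEligibility:
    def test_diagnoses_exactly_30_days_apart_are_eligible(self):
        enroll = enrollment_frame([("P1", "2013-01-01", "2019-12-31")])
        ok, failed = check_eligibility(PATIENT, _eligible_claims(dx_gap_days=30), enroll, pd.Timestamp("2015-06-01"), CFG)
        assert ok and failed == []

    def test_diagnoses_29_days_apart_fail_dx_separation(self):
        enroll = enrollment_frame([("P1", "2013-01-01", "2019-12-31")])
        ok, failed = check_eligibility(PATIENT, _eligible_claims(dx_gap_days=29), enroll, pd.Timestamp("2015-06-01"), CFG)
        assert not ok and failed == ["dx_separation"]

    def test_short_post_index_enrollment_fails(self):
        enroll = enrollment_frame([("P1", "2013-01-01", "2015-09-09")])  # 100 days post-index
        ok, failed = check_eligibility(PATIENT, _eligible_claims(), enroll, pd.Timestamp("2015-06-01"), CFG)
        assert not ok and failed == ["post_enrollment"]

    def test_diagnosis_before_2000_does_not_count(self):
        claims = claims_frame(
            [
                ("P1", "1999-06-01", "diagnosis", "DX_CD", "outpatient", 10.0),
                ("P1", "2014-01-01", "diagnosis", "DX_CD", "outpatient", 10.0),
                ("P1", "2015-06-01", "drug", "RX_VEDO", "pharmacy", 0.0),
            ]
        )
        enroll = enrollment_frame([("P1", "1998-01-01", "2019-12-31")])
        ok, failed = check_eligibility(PATIENT, claims, enroll, pd.Timestamp("2015-06-01"), CFG)
        assert not ok and "dx_separation" in failed

    def test_monotone_in_enrollment_and_diagnoses(self):
        """Extending enrollment or adding diagnoses never revokes eligibility."""
        enroll = enrollment_frame([("P1", "2013-01-01", "2019-12-31")])
        claims = _eligible_claims()
        assert check_eligibility(PATIENT, claims, enroll, pd.Timestamp("2015-06-01"), CFG)[0]
        wider = enrollment_frame([("P1", "2010-01-01", "2025-12-31")])
        more_dx = pd.concat(
            [claims, claims_frame([("P1", "2014-06-01", "diagnosis", "DX_CD", "outpatient", 5.0)])],
            ignore_index=True,
        )
        assert check_eligibility(PATIENT, more_dx, wider, pd.Timestamp("2015-06-01"), CFG)[0]


class TestBaselineFeatures:
    enroll = enrollment_frame([("P1", "2010-01-01", "2019-12-31")])
    index = pd.Timestamp("2015-06-01")

    def test_surgery_years_before_index_flags_lifetime_but_not_prior_year(self):
        claims = pd.concat(
            [_eligible_claims(), claims_frame([("P1", "2012-06-01", "procedure", "PX_BOWEL_SURG", "inpatient", 5000.0)])],
            ignore_index=True,
        )
        feats = derive_baseline_features(PATIENT, claims, labs_frame([]), self.enroll, self.index, CFG)
        assert feats["prior_bowel_surgery"] is True
        assert feats["prior_year_surgery"] is False

    def test_most_recent_albumin_wins_and_same_day_duplicates_average(self):
        labs = labs_frame(
            [
                ("P1", "2015-04-01", "albumin", 30.0, "g/L"),
                ("P1", "2015-05-01", "albumin", 42.0, "g/L"),
                ("P1", "2015-05-01", "albumin", 44.0, "g/L"),
            ]
        )
        feats = derive_baseline_features(PATIENT, _eligible_claims(), labs, self.enroll, self.index, CFG)
        assert feats["baseline_albumin"] == pytest.approx(43.0)
        assert feats["baseline_crp"] is None  # no CRP in lookback

    def test_lab_outside_lookback_is_missing(self):
        labs = labs_frame([("P1", "2014-01-01", "crp", 4.0, "mg/L")])
        feats = derive_baseline_features(PATIENT, _eligible_claims(), labs, self.enroll, self.index, CFG)
        assert feats["baseline_crp"] is None

    def test_anti_tnf_agent_count_matches_exposure_flag(self):
        claims = pd.concat(
            [
                _eligible_claims(),
                claims_frame(
                    [
                        ("P1", "2014-06-01", "drug", "RX_TNF_IFX", "pharmacy", 0.0),
                        ("P1", "2014-09-01", "drug", "RX_TNF_ADA", "pharmacy", 0.0),
                    ]
                ),
            ],
            ignore_index=True,
        )
        feats = derive_baseline_features(PATIENT, claims, labs_frame([]), self.enroll, self.index, CFG)
        assert feats["prior_anti_tnf_exposure"] is True
        assert feats["n_anti_tnf_agents"] == 2


class TestBuildCohort:
    def test_constructed_eligible_dataset_keeps_everyone(self, small_sim, small_cohort):
        cfg, dataset, _ = small_sim
        cohort, log = small_cohort
        assert len(cohort) == cfg.n_patients
        assert log == {}
        assert (cohort["age_at_index"] >= 18).all()

    def test_underage_patient_is_excluded_and_logged(self, small_sim):
        _, dataset, _ = small_sim
        patients = dataset.patients.copy()
        idx0 = patients.index[0]
        patients.loc[idx0, "birth_year"] = 2010
        modified = ClaimsDataset(patients, dataset.enrollment, dataset.claims, dataset.labs)
        cohort, log = build_cohort(modified)
        assert len(cohort) == len(patients) - 1
        assert log == {"age": 1}

    def test_empty_dataset_gives_empty_cohort(self):
        cohort, log = build_cohort(empty_dataset())
        assert len(cohort) == 0
        assert log == {}

    def test_row_order_invariance(self, small_sim, small_cohort):
        _, dataset, _ = small_sim
        cohort, _ = small_cohort
        shuffled = ClaimsDataset(
            dataset.patients.sample(frac=1, random_state=1),
            dataset.enrollment.sample(frac=1, random_state=2),
            dataset.claims.sample(frac=1, random_state=3),
            dataset.labs.sample(frac=1, random_state=4),
        )
        cohort2, _ = build_cohort(shuffled)
        pd.testing.assert_frame_equal(
            cohort.sort_values("patient_id").reset_index(drop=True),
            cohort2.sort_values("patient_id").reset_index(drop=True),
        )
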