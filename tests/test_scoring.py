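"""CDST scoring: point arithmetic, stratum cutoffs, structural properties."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from cdst_hru.scoring import (
    CDSTWeights,
    classify_5var,
    crp_penalty,
    score_3var,
    score_5var,
    score_cohort,
)

W = CDSTWeights()


def features(surgery=False, fistula=False, anti_tnf=False, albumin=None, crp=None, pid="P1"):
    return {
        "patient_id": pid,
        "prior_bowel_surgery": surgery,
        "prior_fistulizing_disease": fistula,
        "prior_anti_tnf_exposure": anti_tnf,
        "baseline_albumin": albumin,
        "baseline_crp": crp,
    }


class TestFiveVariable:
    @pytest.mark.parametrize(
        "kwargs,score,stratum",
        [
            # all favorable: 2+2+3 + 0.4*40 + 0 = 23
            (dict(albumin=40.0, crp=2.0), 23.0, "high"),
            # all risk factors, low albumin, high CRP: 0.4*30 - 3 = 9
            (dict(surgery=True, fistula=True, anti_tnf=True, albumin=30.0, crp=15.0), 9.0, "low"),
            # CRP exactly 3.0 sits in the -0.5 band: 7 + 0.4*30 - 0.5 = 18.5
            (dict(albumin=30.0, crp=3.0), 18.5, "intermediate"),
            # CRP exactly 10.0 still in the -0.5 band
            (dict(albumin=30.0, crp=10.0), 18.5, "intermediate"),
            # CRP just above 10.0 takes the -3 penalty
            (dict(albumin=30.0, crp=10.1), 16.0, "intermediate"),
            # score exactly 19 -> intermediate (high requires > 19)
            (dict(albumin=30.0, crp=0.5), 19.0, "intermediate"),
            # score exactly 13 -> low (intermediate requires > 13)
            (dict(surgery=True, fistula=True, anti_tnf=True, albumin=32.5, crp=0.5), 13.0, "low"),
        ],
    )
    def test_hand_computed_scores_and_strata(self, kwargs, score, stratum):
        result = score_5var(features(**kwargs), W)
        assert result.score == pytest.approx(score)
        assert result.stratum == stratum
        assert result.inputs_complete

    def test_missing_lab_flags_incomplete(self):
        result = score_5var(features(albumin=None, crp=2.0), W)
        assert not result.inputs_complete
        assert result.score is None and result.stratum is None

    def test_score_increases_with_albumin_and_never_with_crp(self):
        albumin_grid = np.arange(20.0, 55.0, 0.5)
        scores = [score_5var(features(albumin=a, crp=1.0), W).score for a in albumin_grid]
        assert all(b > a for a, b in zip(scores, scores[1:]))
        crp_grid = np.arange(0.0, 25.0, 0.1)
        scores = [score_5var(features(albumin=40.0, crp=c), W).score for c in crp_grid]
        assert all(b <= a for a, b in zip(scores, scores[1:]))
        assert {crp_penalty(c, W) for c in crp_grid} == {0.0, -0.5, -3.0}

    def test_clinical_part_equals_three_variable_score(self):
        for surgery, fistula, anti_tnf in product([False, True], repeat=3):
            f = features(surgery, fistula, anti_tnf, albumin=38.0, crp=5.0)
            five = score_5var(f, W).score
            labs_part = W.albumin_pts_per_g_l * 38.0 + W.crp_mid_penalty
            assert five - labs_part == pytest.approx(score_3var(f, W).score)


class TestThreeVariable:
    def test_enumeration_of_all_factor_combinations(self):
        cohort = pd.DataFrame(
            [
                {
                    "patient_id": f"P{i}",
                    "prior_bowel_surgery": s,
                    "prior_fistulizing_disease": f,
                    "prior_anti_tnf_exposure": t,
                    "baseline_albumin": None,
                    "baseline_crp": None,
                }
                for i, (s, f, t) in enumerate(product([False, True], repeat=3))
            ]
        )
        scores = score_cohort(cohort, "three_var")
        assert sorted(scores["score"]) == [0, 2, 2, 3, 4, 5, 5, 7]
        assert set(scores["score"]) <= {0, 2, 3, 4, 5, 7}
        # high stratum iff at least two of the three favorable factors
        for _, row in cohort.merge(scores, on="patient_id").iterrows():
            n_favorable = sum(
                not row[c] for c in ("prior_bowel_surgery", "prior_fistulizing_disease", "prior_anti_tnf_exposure")
            )
            assert (row["stratum"] == "high") == (n_favorable >= 2)

    def test_boundary_score_three_is_low(self):
        only_tnf_naive = features(surgery=True, fistula=True, anti_tnf=False)
        result = score_3var(only_tnf_naive, W)
        assert result.score == 3 and result.stratum == "low"

    def test_works_without_laboratory_data(self):
        result = score_3var(features(albumin=None, crp=None), W)
        assert result.score == 7 and result.stratum == "high" and result.inputs_complete


class TestScoreCohort:
    def test_empty_cohort(self):
        assert len(score_cohort(pd.DataFrame(columns=["patient_id"]), "three_var")) == 0

    def test_unknown_variant_raises(self, small_cohort):
        with pytest.raises(ValueError, match="variant"):
            score_cohort(small_cohort[0], "four_var")

    def test_all_labs_missing_scores_nobody_for_5var(self, small_cohort):
        cohort = small_cohort[0].copy()
        cohort["baseline_albumin"] = None
        scores = score_cohort(cohort, "five_var")
        assert (~scores["inputs_complete"]).all()
        assert scores["stratum"].isna().all()

    def test_vectorized_agrees_with_scalar_scoring(self, small_cohort):
        cohort = small_cohort[0]
        table = score_cohort(cohort, "five_var").set_index("patient_id")
        for _, row in cohort.head(25).iterrows():
            single = score_5var(row, W)
            assert table.loc[row["patient_id"], "score"] == pytest.approx(single.score)
            assert table.loc[row["patient_id"], "stratum"] == single.stratum
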