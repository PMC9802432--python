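# cdst-hru

Claims-based analysis of the **vedolizumab clinical decision support tool
(CDST)** for Crohn's disease (CD): score and stratify patients from
longitudinal administrative-claims tables, extract 12-month
healthcare-resource-utilization (HRU) outcomes and annualized costs, and
compare response-probability strata with the standard tests used in claims
studies.  A bundled synthetic-claims generator makes every stage testable
without access to proprietary claims extracts.

## Who it is for

Outcomes researchers and biostatisticians working with administrative claims
(Optum/Truven-style extracts: enrollment spans, dated coded claims with paid
amounts, laboratory results) who want a reproducible implementation of the
CDST stratification and its downstream HRU/cost analysis — or a synthetic
testbed for it.

## The score

For a patient initiating vedolizumab, with baseline albumin *A* (g/L) and
C-reactive protein *C* (mg/L), the 5-variable CDST score is

```
S5 = 2·[no prior bowel surgery] + 2·[no prior fistulizing disease]
   + 3·[no prior anti-TNF exposure] + 0.4·A + pen(C)

pen(C) = 0      if C < 3.0
       = −0.5   if 3.0 ≤ C ≤ 10.0
       = −3     if C > 10.0
```

with response-probability strata **high** (S5 > 19), **intermediate**
(13 < S5 ≤ 19) and **low** (S5 ≤ 13).  The modified 3-variable CDST keeps
only the three clinical terms (scores in {0, 2, 3, 4, 5, 7}) with **high**
defined as S3 > 3 — equivalently, at least two of the three favorable
factors.  Patients without baseline labs cannot be scored with the
5-variable tool and are excluded from those analyses rather than imputed.

Downstream, 12-month CD-related hospitalization, surgery and
emergency-department (ED) visits are extracted per patient (an ED visit that
results in admission or surgery is counted as that event, not as an ED
visit), costs are converted to 2017 USD and annualized by
`total / (days_between + 1) × 365.25` when eligibility ends within 12 months
of index, and strata are compared with Pearson χ² (categorical), one-way
ANOVA (3 strata) or pooled two-sample *t*-tests (2 strata) — including
summary-statistics variants that work from printed `(n, mean, SD)` triplets.

## Worked example

```python
from cdst_hru import (SimulationConfig, generate_dataset, build_cohort,
                      score_cohort, extract_outcomes, compute_costs, compare_strata)

config = SimulationConfig(n_patients=500, seed=7)
dataset, truth = generate_dataset(config)          # synthetic claims tables
cohort, exclusions = build_cohort(dataset)         # eligibility + baseline features
scores = score_cohort(cohort, "five_var")
print(scores["stratum"].value_counts().to_dict())

outcomes, records = extract_outcomes(dataset.claims, cohort)
costs = compute_costs(dataset.claims, cohort, records)
strata = scores[scores["inputs_complete"]][["patient_id", "stratum"]]
events = compare_strata(outcomes.merge(strata, on="patient_id"),
                        binary_outcomes=["had_hospitalization", "had_surgery", "had_ed_visit"])
print(events[["variable", "high_summary", "low_summary", "p_value"]].round(4))
```

prints

```
{'high': 261, 'intermediate': 208, 'low': 31}
           variable high_summary low_summary  p_value
had_hospitalization    63 (24.1)   12 (38.7)   0.1205
        had_surgery    29 (11.1)    9 (29.0)   0.0139
       had_ed_visit    37 (14.2)    4 (12.9)   0.2948
```

All 500 simulated patients pass the eligibility filters by construction; the
5-variable CDST stratifies them 261/208/31.  Surgery risk rises monotonically
from the high- to the low-probability-of-response stratum (11.1% vs 29.0%,
χ² p = 0.014) — the planted association the generator encodes; with only 31
low-stratum patients the hospitalization trend (24.1% vs 38.7%) does not
reach significance at this sample size.  Column summaries are `n (%)` for
events and `mean (SD)` in 2017 USD for costs.

The same stages are available from a shell:

```bash
cdst-hru simulate --out data/ --seed 7
cdst-hru build-cohort --data data/ --out cohort.csv
cdst-hru score --cohort cohort.csv --variant five_var --out scores.csv
cdst-hru run-all --out run/ --seed 7 --n-patients 500   # everything + report
cdst-hru verify-reported                                # check published numbers
```

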