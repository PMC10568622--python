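# gtt-ade

Trigger-tool screening for adverse drug events (ADEs) in elderly inpatients.

Elderly patients on many concurrent medications experience adverse drug
events at high rates, and spontaneous reporting systems miss most of them.
The Global Trigger Tool (GTT) approach screens inpatient records for
*triggers* — abnormal laboratory values, antidote or rescue treatments,
clinical symptoms, and abrupt medication stops — that flag a chart for
focused ADE review. `gtt-ade` implements a complete GTT pipeline for a
geriatric inpatient setting over plain tabular EHR extracts:

- **records** — a validated data model for admissions, medication
  administrations, laboratory results, clinical events and comorbidity
  context (five CSV files), plus the eligibility filter (age ≥ 65, stay
  > 1 day, no malignancy/transplant/palliative-care/ICU-transfer exclusions).
- **triggers** — a rule engine with 36 screening rules: 17 laboratory
  indexes (L1–L17), 10 treatments (T1–T10), 8 clinical symptoms (C1–C8) and
  1 intervention measure (I1), shipped as an editable YAML registry. Each
  rule couples a predicate with a drug-context requirement (a drug of the
  implicated class active within a configurable window) and exclusion
  clauses for non-drug explanations.
- **adjudication** — reviewer decisions as data: the 10-item Naranjo
  causality scale (definite ≥ 9, probable 5–8, possible 1–4, doubtful ≤ 0;
  only definite/probable events are analysed), CTCAE v5 severity grades 1–5,
  onset-time binning, and ADE-to-trigger linkage.
- **metrics** — positive predictive value per trigger and overall
  (PPV = 100 × detected ADEs / positive firings), the three surveillance
  rates (occurrence rate, ADEs per 100 admissions, ADEs per 1,000
  patient-days), distribution tables, a monthly rate series, and the
  proportion sample-size formula N = Z²P(1−P)/δ².
- **riskmodels** — rank-sum and chi-square group comparisons and a binary
  logistic regression of ADE occurrence on utilisation covariates, fit by
  iteratively reweighted least squares with Wald intervals.
- **synth** — a seeded synthetic-cohort generator that emulates the cohort's
  marginals and plants trigger conditions and adjudicated ADEs with known
  ground truth, so the whole pipeline is testable without patient data.

## Worked example

```bash
gtt simulate --seed 7 --out demo --n-admissions 200
gtt screen --cohort demo --out demo/hits.csv
gtt adjudicate --cohort demo --hits demo/hits.csv \
    --adjudications demo/adjudications.csv --out demo/ades.csv
gtt report --hits demo/hits.csv --ades demo/ades.csv --cohort demo --out demo/report
```

On this 200-admission simulation the stages log:

```
wrote 200 admissions, 137 planted trigger conditions, 27 ADEs to demo
eligibility: retained 200, excluded 0
137 positive triggers over 108 admissions; 23/36 rules fired
causality: {'definite': 6, 'probable': 21, 'possible': 5, 'doubtful': 0}; detected 27/27 ADEs, 35 pairs
report written to demo/report
```

Reading: the engine recovered exactly the 137 planted trigger conditions on
108 distinct admissions (23 of the 36 rules fired at least once); of the 32
candidate events in the adjudication file, 27 were judged definite or
probable and kept, and every one was flagged by at least one trigger (35
ADE–trigger pairs, since one event can be found by several rules).
`demo/report/rates.json` then holds the cohort's occurrence rate, ADEs per
100 admissions and ADEs per 1,000 patient-days; `demo/report/ppv.csv` the
per-rule PPV table.

The same pipeline is available as a library:

```python
from gtt_ade import (SynthConfig, generate_cohort, evaluate_cohort,
                     load_registry, generate_study_counts_fixture,
                     summary_from_counts)

cohort, truth = generate_cohort(SynthConfig(seed=7, n_admissions=200))
hits = evaluate_cohort(cohort, load_registry())

print(summary_from_counts(generate_study_counts_fixture()))
# {'overall_ppv_percent': 23.84, 'incidence_percent': 10.62,
#  'ades_per_100_admissions': 11.67, 'ades_per_1000_patient_days': 13.04, ...}
```

`generate_study_counts_fixture()` is a summary-level fixture — screening
counts only, no patient rows — from which every headline rate of a
480-admission geriatric screening study is recomputed: an overall PPV of
23.84% (67 detection pairs / 281 positive triggers), a 10.62% ADE occurrence
rate, 11.67 ADEs per 100 admissions and 13.04 per 1,000 patient-days.

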