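# Methods

## Screening model

The package implements trigger-tool surveillance for adverse drug events
(ADEs) in elderly inpatients. A *trigger* is a rule over an admission's
records whose firing flags the chart for focused review; it is a screening
instrument, not a diagnosis. The registry holds 36 rules in four modules:
laboratory indexes (L1–L17), treatments (T1–T10), clinical symptoms (C1–C8)
and one intervention measure (I1, abrupt medication stop). A hit requires
three things simultaneously:

1. the **core predicate** (a lab value crossing a threshold, a marker
   treatment ordered, a symptom event recorded, an order stopped abruptly);
2. the **drug context**, where the rule names one: a drug of the implicated
   class active in the window before the observation. An order is *active*
   at time `t` within window `w` when its half-open interval
   `[start, stop)` intersects `(t − w, t]`; an order without a stop
   timestamp is treated as ongoing. The default window is **7 days**,
   configurable; most drug-induced events in this setting occur within two
   days of administration, so 7 days is deliberately permissive;
3. the **absence of exclusion clauses** — comorbidities or context that
   explain the abnormality without a drug (e.g. hyperuricaemia history for
   the uric-acid rule, thyroid dysfunction for the TSH rule, parenteral
   nutrition or hepatobiliary disease for the liver-enzyme rule). Missing
   context is treated as all-false flags: exclusion requires explicit
   positive evidence.

Comparison operators are taken literally from the rule definitions: `<` and
`>` are strict, `≥`/`≤` inclusive. Under the default **per-stay counting
policy** an admission contributes at most one hit per trigger (the earliest
occurrence); a per-occurrence policy is available. Timestamps are ISO-8601
at minute resolution; a 48-hour pre-admission lookback is accepted so that
baseline laboratory values drawn shortly before admission count.

Rule parameters that are site-specific are configuration, not constants:
the liver-enzyme upper limits of normal (ALT 40 U/L, ALP 150 U/L; the rule
fires at ≥ 2 × ULN for both enzymes), the coagulation cut-offs
(PT > 12.1 s, APTT > 36.5 s, INR > 3.5), and the creatine-kinase ULN
(200 U/L, rule at > 10 ×). The kidney-injury rule (L7) defines the
creatinine baseline as the minimum of the admission value (within the
lookback) and the in-stay minimum — equivalently the series minimum — and
fires on a value above twice that baseline; the relative-eGFR and
sustained-oliguria clauses are evaluated only when those series exist.

Two rules needed interpretation where the definitions are underspecified.
The hyperglycaemia rule's clause for diabetics ("glucose higher than in the
past") is implemented as *any glucose value exceeding the admission-period
minimum by a configurable margin* (default 3.0 mmol/L); this is flagged as
an interpretation, and the margin is a registry parameter. The
medication-stop rule fires only on abrupt stops by default; an optional
toggle extends it to dose reductions (a proposed refinement kept off to
preserve the primary list). Drug classes with no slot in the controlled
medication vocabulary (antihistamines, antihypertensives) are matched by
drug-name lists or by the nearest class set, documented in the registry.

## Adjudication

Causality review is human work; the package represents it as data and
implements the scoring instruments. Each candidate event carries the ten
Naranjo-scale answers (yes/no/unknown); the published item weights
(+2/+1/0/−1) are shipped as a data file and the total maps to
definite (≥ 9), probable (5–8), possible (1–4) or doubtful (≤ 0). Only
definite and probable events enter the analysis. Severity uses the CTCAE
v5 grade descriptors (1 mild … 5 death), a bijective five-value mapping.
Onset time is binned on `onset − first administration` with half-open
(lower, upper] bins — ≤ 5 h, 5 h–1 d, 1–2 d, 2–4 d, 4–8 d — plus
`prior_to_admission` when onset precedes admission, and an `>8 d` bin for
completeness. One ADE may be linked to several triggers; a *detection pair*
is one (ADE, trigger) link, so pairs ≥ detected ADEs.

## Metrics

PPV per trigger is 100 × detections / positives, undefined (rendered "—")
for rules that never fired; the overall PPV uses the summed counts, and is
therefore the positive-count-weighted mean of the per-rule PPVs. The rate
panel reports the occurrence rate (% of admissions with ≥ 1 ADE), ADEs per
100 admissions, and ADEs per 1,000 patient-days, with patient-days = Σ
length of stay (or admissions × mean stay when working from summary
counts). All computation is full precision; rounding to two decimals
happens only at rendering and uses **half-even** (banker's) rounding, which
reproduces the reference rates exactly (e.g. 51/480 → 10.62). The monthly
series attributes each admission's patient-days and ADEs to its admission
month; months with no admissions are reported as missing. The sample-size
operation is the standard proportion formula N = Z²P(1−P)/δ², rounded to
the nearest integer (P = 0.10, Z = 1.96, δ = 0.03 gives 384).

A summary-level **study-counts fixture** ships with the package: per-trigger
positive/detection counts, distribution tables and cohort totals for a
480-admission screening study, from which every headline percentage is
recomputable without patient rows. One internal inconsistency in the
source tabulation is resolved in favour of the percentage column: the
organ-system table's metabolic/nutritional row is carried as 15 entries
(the value consistent with the printed percentage 24.59% and the table
total of 61), not the printed row count of 8. Two cumulative onset
conventions are computable (≤ 1 day: 53.57%; ≤ 2 days: 75.00%); the
abstract-level "71.43% within 2 days" figure is not reproducible from the
onset table and both values are reported.

## Risk models

Group comparisons between ADE and non-ADE admissions use the two-sample
rank-sum (Mann–Whitney) test for continuous covariates and the chi-square
test for binary ones, **without** Yates continuity correction by default
(the variant is a documented toggle). The logistic regression enters five
covariates simultaneously — length of stay, number of diagnoses, number of
distinct medications, antibacterial use, antibacterial hours — and is fit
by iteratively reweighted least squares: log-likelihood convergence
tolerance 1e-8, maximum 50 iterations, Wald standard errors from the
observed information, 95% CIs as exp(β ± 1.96 SE). Quasi-complete
separation (fitted probabilities pinned to the outcome, runaway
coefficients, or non-convergence) is flagged on the returned fit rather
than silently reported. Age and sex appear in the group comparisons only,
mirroring the reference analysis; the omission from the regression is
deliberate. Complete-case analysis throughout; the generator never emits
missing covariates.

## Synthetic cohort generator

The generator emulates the study conditions: 480 admissions by default;
age ~ truncated normal (72.61, 5.94) on [65, 91]; length of stay (8.95,
4.57) on [2, 27] days; distinct medications per stay (18.26, 6.42) on
[5, 40]; diagnoses (5.38, 2.80) on [1, 19]; 45.62% female; 30.83%
antibacterial exposure with duration (53.42, 103.24) h on [3, 528]; 14.38%
drug-allergy history. Truncation shifts realized means slightly above the
location parameter (about +0.8 years for age); calibration tests compare
against the analytic truncated moments. ADE occurrence follows a logistic
model in the number of medications with log-odds 0.087 per drug; the
intercept is solved numerically (Brent's method on the discretised
truncated-normal medication distribution) so the expected prevalence is
10.62%. Patients with events carry 1/2/3 ADEs with probabilities
47/51, 3/51, 1/51; severity, onset-bin and organ-system draws follow the
reference distributions, and about one ADE in eleven carries a second
organ-system entry so symptom-level tabulations exceed the ADE count.

Trigger conditions are planted constructively: per admission and rule, a
Bernoulli draw with rate proportional to the reference positive counts
(e.g. the uric-acid rule at 73/480), then for each planted pair the
generator emits exactly the rows that satisfy the rule — the abnormal
value, the context drug started beforehand, the event, the abrupt stop —
and clears any exclusion flag that would veto it. Background rows are
drawn from safe reference ranges and a marker-free formulary so they can
never fire a rule: e.g. background potassium in [3.6, 5.2] mmol/L, PT
≤ 12.0 s, and background glucose is withheld entirely on admissions where
a glucose rule is planted (the diabetic clause keys on the in-stay
minimum). Detected ADEs link to triggers already planted on their
admission (force-planting one when necessary); ~7% of ADEs are left
trigger-undetected and ~29% of detected ones carry a second link,
matching the reference detection-pair ratio. The adjudication file also
contains possible/doubtful candidates that the causality filter must
remove. At generation time the engine is run on the output and the hit
set is required to equal the planted set exactly (zero-noise default); a
configurable noise rate plants additional conditions recorded as noise.

What the generator does **not** emulate: correlations between covariates
(medications × diagnoses independence is assumed), pharmacokinetics,
repeat firings of one rule in a stay, seasonal admission structure, and
free-text clinical narrative. Passing tests therefore demonstrate that the
pipeline computes the intended quantities on data with known structure —
not that the rule thresholds have any particular sensitivity on real
records, where background values do cross thresholds for non-drug reasons.

## Numerical and design choices

- Intervals half-open `[start, stop)`; timestamps floored to minutes.
- Per-stay hits keep the earliest occurrence; ties broken by evidence order.
- The onset sampler falls back to the 5 h–1 d bin when a drawn bin cannot
  fit inside a short stay, slightly overweighting that bin at small n.
- Rank-sum on identical samples returns p = 1 (tie-corrected normal
  approximation with z = 0); chi-square on a constant column returns p = 1.
- Statistical power note: a +3 shift in medications between groups of
  51 vs 429 is detected by the rank-sum test at α = 0.01 in only ~72% of
  replicates (SE of the mean difference ≈ 0.95); ≥ 95% detection requires
  balanced groups at the same total n. The tests assert both computed
  values.
- Default problem sizes: shared test cohort 100 admissions; oracle
  equivalence at 20 admissions × 3 seeds; the acceptance script screens a
  200-admission cohort and refits the outcome model on 20 replicates of
  n = 2000. These sizes give stable Monte-Carlo bands while keeping the
  suite quick to run.

## Known limitations

- The engine evaluates one admission at a time and is pure Python/pandas;
  it is built for cohorts of hundreds to thousands of admissions, not
  millions.
- Exact per-coefficient values of the reference study's regression (and its
  group-comparison p-values) depend on unavailable patient-level data; they
  are covered by parameter-recovery and calibration properties, not by
  value reproduction.
- The treatment rules match marker drug names by substring against a
  configurable list; real formularies will need site-specific name lists.
- Monthly rates attribute whole stays to the admission month; stays
  spanning month boundaries are not split.
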