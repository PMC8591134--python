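# Methods

## Problem and scope

`pneumotox` models the identification and health-economic description of
treatment-related pneumonitis from routinely collected cancer-centre EHR
data: free-text CT thorax reports, structured ICI administration and
radiotherapy course records, and dated clinical events. The package
covers cohort identification, aetiology attribution, CTCAE v5.0 severity
grading with inter-rater agreement, 16-week resource-utilisation
extraction, and a weighted unit-cost model, plus a synthetic data
generator that stands in for the non-shareable source EHR. Out of scope:
SQL/warehouse integration, NLP negation or uncertainty detection, image
analysis, and causal inference about confounders (a superadded-infection
flag is carried for reporting only).

## Cohort identification

Matching is case-insensitive, punctuation-tolerant substring matching
over whitespace-normalised text — the behaviour of a SQL `LIKE` screen.
There is deliberately no stemming and no word-boundary enforcement:
"pneumonia" matches inside "pneumonias", while "pneumonitis" does not
match "pneumonia"; a negated phrase ("no evidence of pneumonitis") still
matches. These known failure modes are exercised by the synthetic
distractors and motivate the manual-validation stand-in (a labelled
exclusion list whose before/after counts the funnel reports).

Stage-2 descriptor terms are evaluated on the report body only. Screening
phrases are typically introduced by the *requesting* clinician
("?pneumonitis") in the request section; restricting stage 2 to the body
keeps only reports where the radiologist describes compatible findings.
This is configurable (`TermConfig`), as the restriction is a design
choice rather than a hard rule of the underlying screen.

Episode deduplication is greedy earliest-first with a 183-day (6-month)
window measured from the last *kept* report, so a report beyond the
window opens a new episode for the same patient. Same-day ties break on
report identifier (stable, logged). The operation is idempotent and is
checked against an independent interval-suppression oracle.

Conventions: 6 months = 183 days; "prior to" = strict date inequality;
1 month = 30.44 days wherever months convert to days.

## Attribution

ICI criterion: any listed drug administration in
`[diagnosis − 91 d, diagnosis)`; RT criterion: any qualifying course with
first fraction in `[diagnosis − 365 d, diagnosis)`. Both half-open:
treatment on the diagnosis day does not qualify. The diagnosis date is
the symptom-onset date when supplied, else the index scan date, honouring
the clinical precedence of earliest documented symptoms. Whether the
original month windows were calendar or day arithmetic is unknowable from
the outside; fixed day counts (91/365) keep attribution a pure, testable
function of dates, and both windows are configurable. Candidates meeting
neither criterion are emitted to a separate exclusions stream rather than
silently dropped.

Lost treatment time is measured from the last administration on or before
diagnosis to the first administration after it; undefined when the drug
was never reintroduced.

## Grading and agreement

Grade is inferred from flags recoverable from structured data: death → 5,
life-threatening/intubation → 4, oxygen or hospitalisation indicated → 3,
symptomatic (medical intervention) → 2, else 1. The rule list is total
and ordered with death dominating. The grade-3 criterion collapses
CTCAE's "severe symptoms; oxygen indicated" into a single flag because
EHR documentation, not pulmonary-function thresholds, is the available
signal; note that *being admitted* is a resource event, not the grade-3
flag — patients are routinely admitted with grade-2 disease.

Krippendorff's alpha is computed from the coincidence matrix: each
ordered pair of distinct ratings within an item contributes
1/(mᵤ−1); α = 1 − D_o/D_e. Items with fewer than two ratings are
excluded; zero expected disagreement returns 1.0 by convention (logged).
The default difference metric is **interval** on the grade integers, so
adjacent-grade disagreement is penalised less than distant disagreement —
a deliberate choice for an ordered severity scale; nominal and ordinal
metrics are selectable since the metric behind any given published alpha
is rarely stated. The implementation is verified against an independent
brute-force pairwise-disagreement evaluation, exhaustively on small
annotation sets.

## Resource utilisation

Counts use the half-open window `[diagnosis, diagnosis + 112 d)` — the
diagnosis day is included, day 112 is not. Admission nights are
attributed wholly to the case when the admission starts inside the
window and are not clipped at the window edge (a 43-night stay starting
on day 110 belongs to the episode that caused it). Referral/BAL/PFT
flags accept any event on or after diagnosis because observed
times-to-review extend months beyond 16 weeks.

The strata comparison is Welch's unequal-variance t-test (difference,
95 % CI, two-sided p) on follow-up clinic counts, grade 1 versus grades
2–4. Welch is used because group variances cannot be assumed equal; it
coincides with the pooled test when n and variances match (tested as an
analytic identity). Fatal (grade 5) cases are excluded from the clinic
comparison — their follow-up is truncated by death — but included in
admission statistics.

## Costing

Per-patient cost is Σ weight × unit cost over the packaged ten-line NHS
2019/20 table. Weights are expected per-case usage: probabilities for
referred-only resources (0.417 initial + follow-up respiratory
appointments, 0.237 bronchoscopy, 0.043 rescue immunosuppression),
expected counts (1 CT, 1 MDT, 2 oncology follow-ups), and, for the two
admission lines, expected nights × admission probability: hospital
10.5 × 0.39, critical care 6.5 × 0.07. Some published renderings of this
table transpose the two probability factors between the rows; the
assignment used here is the one consistent with the observed admission
percentages (39 % hospital, 7 % CCU) and with the line totals (£1,940.91
and £424.75), and the packaged CSV stores the weights as explicit
products (`10.5*0.39`) so the convention is visible and auditable.

Display rounding is half-up at 2 dp; all arithmetic keeps unrounded
floats, and cohort extrapolation multiplies the *unrounded* per-patient
sum (139 × 3,932.3347 = £546,594.52 — rounding first would lose 65 p).
The rescue-immunosuppression unit cost is itself derivable (5 mg/kg
twice daily × 5 days × 70 kg = 3,500 mg at £377/100 mg = £13,195) and is
recomputed as a validation check. The sensitivity operation recomputes
per-patient cost under named per-line perturbations (scale/set/add on
weights or unit costs); cost is linear in every weight and unit cost, so
scenario effects are exactly additive per line.

Excluded from costing by design: empirical antibiotics, steroids,
co-trimoxazole, pathology/microbiology, and non-thorax imaging — the
estimate is conservative.

## Synthetic data generator

The generator emulates the study conditions, not real radiology prose.
Defaults: 5 % of simulated patients are true pneumonitis cases
(the underlying screened population has no published denominator; 5 % of
scanned oncology patients is a realistic prevalence for a mixed
ICI/thoracic-RT centre), split ICI : RT : both = 85 : 44 : 10 conditional
on being a case; severity pmf (109, 107, 15, 4, 13)/248 over grades 1–5;
resource-use probabilities from the observed management mix (steroids
0.964, antibiotics 0.568, referral 0.417, BAL 0.237, PFT 0.086, hospital
0.388, CCU 0.072).

Time-to-onset is a **truncated log-normal**: only a mean and a range are
available for each aetiology, and a right-skewed shape is the natural
choice given that roughly half of ICI cases present within 3 months. The
location parameter is solved by bisection so the *truncated* mean equals
the target (ICI 4.5 × 30.44 d on [4, 639.2] with σ = 1.1; RT
3.6 × 30.44 d on [8, 243.5] with σ = 0.8); sampling is inverse-CDF, so
draws respect the range by construction. σ = 1.1 puts ≈ 49 % of ICI
onsets below 3 months, reproducing the observed early-presentation share
as a self-check. Combined-aetiology cases reuse the ICI onset
distribution (their RT course is dated from an independent RT-onset
draw), since no separate onset summary exists for them. The same
truncated log-normal machinery drives stays (hospital mean 10.5 nights
on [1, 43]; CCU 6.5 on [1, 20]), work-up delays, time to death (mean 64 d
on [6, 378]) and ICI interruption length (mean 73 d on [11, 275],
re-challenge probability 28/81).

Follow-up clinic intensity is Poisson with mean 4.4 (grade 1), 6.61
(grades 2–4; difference 2.21) and 2.0 (grade 5, truncated by death).
Severity flags are emitted deterministically from the true grade, so the
grading stage recovers truth exactly and any disagreement in the
agreement analysis must be injected (`simulate_dual_annotation`).

Distractors (default 15 % of non-case patients) come in three types:
request-only mention (removed at stage 2), descriptor text without
qualifying treatment (removed at the treatment filter), and negated
mention with qualifying treatment — the only type the cascade cannot
remove, by design. With `distractor_rate=0` and negated mentions
disabled the cascade recovers the ground-truth case set exactly
(precision = recall = 1), which the tests assert; with negated mentions
enabled recall stays 1 while precision drops, mirroring the need for a
manual validation step.

What the generator does **not** emulate: realistic report prose and
layout variation, negation/uncertainty subtleties beyond one template
family, correlated demographics (marginals only, and demographics do not
drive any downstream stage), centre-level drift over calendar time,
repeat episodes per patient, and informative missingness. Passing tests
therefore demonstrate the pipeline's correctness against its stated
rules, not the real-world sensitivity of those rules to prose the
template bank does not produce.

## Problem sizes and determinism

Tests run the generator at 300–1,500 patients; the end-to-end parameter
recovery check uses 5,000 patients (≈ 250 cases), at which the binomial
3-SE bands on aetiology, severity and resource rates are a few
percentage points wide. One integer seed drives a single
`numpy.random.Generator`; identical config + seed yields byte-identical
output streams, asserted in the tests.
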