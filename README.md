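# pneumotox

Rule-based EHR informatics for treatment-related pneumonitis.

Pneumonitis is a potentially life-threatening adverse effect of immune
checkpoint inhibitors (ICI) and of thoracic radiotherapy (RT). Real-world
incidence, severity and cost data are scarce because cases are buried in
free-text radiology reports. `pneumotox` implements, as a tested and
reusable pipeline, the informatics approach a cancer centre can run over
its own data warehouse:

1. **Cohort identification** — a two-stage keyword cascade over CT thorax
   report text (screening phrases such as *pneumonitis*, *interstitial
   lung disease* in request or body; descriptor phrases such as *ground
   glass*, *diffuse* restricted to the report body), followed by
   structured treatment filters (six ICI drugs; RT to
   thorax/upper-abdomen/neck/vertebrae/breast/chest-wall) and 6-month
   episode deduplication so each episode is represented by its earliest CT.
2. **Attribution** — an episode is ICI-related if a listed drug was given
   in the preceding 3 months, RT-related if a qualifying course started in
   the preceding 12 months (half-open windows, day arithmetic).
3. **Severity grading** — CTCAE v5.0 grade from structured flags
   (death → 5, intubation → 4, oxygen/admission indicated → 3,
   symptomatic → 2, else 1) with dual-annotator concordance measured by
   Krippendorff's alpha, α = 1 − D_o/D_e over the coincidence matrix
   (nominal/ordinal/interval metrics).
4. **Resource utilisation** — consultant follow-up clinics, CT scans and
   MDT discussions counted over the 16 weeks (112 days, half-open) after
   diagnosis; admission nights; severity strata compared with Welch's
   unpaired t-test.
5. **Costing** — a weighted unit-cost model over NHS 2019/20 reference
   costs: per-patient cost = Σᵢ wᵢ·cᵢ over resource lines, where the
   admission-line weights are expected nights × admission probability;
   cohort and annual totals extrapolate the unrounded per-patient sum.
6. **Synthetic EHR generation** — because real EHR extracts cannot be
   shared, a generator emits report text, treatment histories, clinical
   events and ground-truth labels with realistic structure (truncated
   log-normal times-to-onset: ICI mean 4.5 months, range 4 d–21 mo; RT
   mean 3.6 months, range 8 d–8 mo; a grade 1–5 severity mix; configurable
   distractor reports including negated mentions), so every downstream
   stage is testable end to end.

## Worked example

```bash
pneumotox simulate --out demo/data --seed 1 --n-patients 2000
pneumotox pipeline --in demo/data --out demo/out
```

prints the identification funnel

```json
{"reports": 1364, "stage1_flagged": 439, "stage2_filtered": 336,
 "treatment_filtered": 244, "validated": 244, "episodes": 207,
 "attributed": 160, "symptomatic": 61}
```

— of 1,364 synthetic CT reports, 439 contain a screening phrase, 336 keep
a descriptor phrase in the report body, 244 belong to patients treated
with a qualifying ICI drug or RT course before the scan, 207 survive
6-month episode deduplication, 160 fall inside an attribution window and
61 of those are symptomatic (grade ≥ 2). `demo/out/summary.json` then
holds the incidence table (e.g. 40/1,005 ICI-treated patients with
symptomatic ICI pneumonitis → 3.98 %), the strata comparison on 16-week
clinic visits (difference in means 4.06, 95 % CI 3.10–5.02, p ≈ 2×10⁻¹³ —
inflated relative to the generator's configured 2.21 because unvalidated
negated-mention false positives land in the grade-1 stratum with zero
follow-up; rerun with distractors disabled to recover the configured
difference), and the cost block:

```json
{"per_patient_cost": 3932.33, "n_cases": 61,
 "cohort_total_cost": 239872.41, "annual_cost": 39978.74}
```

The per-patient figure is the ten-line NHS 2019/20 model: £3,932.33 per
symptomatic case; applied to a 139-case cohort over six years it gives
£546,594.52 in total and £91,099.09 per year:

```bash
python - <<'PY'
from pneumotox.costing import reference_cost_model, per_patient_cost, cohort_cost, round_half_up
m = reference_cost_model(n_cases=139, n_years=6)
print(round_half_up(per_patient_cost(m)), [round_half_up(x) for x in cohort_cost(m)])
PY
# 3932.33 [546594.52, 91099.09]
```

Each CLI stage (`simulate`, `identify`, `attribute`, `grade`,
`agreement`, `resources`, `cost`, `pipeline`) is a thin wrapper over the
library modules and exchanges plain JSON-Lines/CSV files; see
`pneumotox --help`.

## Documentation

`docs/methods.md` describes the model assumptions, the generator's design
and its limitations, and the numerical conventions (rounding, window
arithmetic, onset-distribution parameterisation).
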