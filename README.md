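# rwttd-qa

Fit-for-purpose data-quality assessment for the **real-world time to
treatment discontinuation (rwTTD)** end point in oncology.

Observational oncology studies increasingly estimate treatment duration from
EHR-derived real-world data products, but those products vary widely in how
completely and plausibly they capture the elements the end point depends on:
drug administrations and orders, lines of therapy (LOT), death dates, and
follow-up activity.  `rwttd-qa` is for outcomes researchers and data
engineers who need to decide whether a candidate data set is fit for
estimating rwTTD *before* committing to a study — and to document that
decision with reproducible, structured checks.

## What it computes

**The end point.** For a target systemic anticancer therapy (SACT), rwTTD is
the inclusive day count from initiation to discontinuation:

```
rwTTD = (date of last recorded dose − date of first recorded dose) + 1 day
```

Discontinuation is an event when the patient died during therapy (death
within 120 days of the last dose), initiated a new treatment (a higher line
number starting after the last dose), or shows a gap ≥ 120 days between the
last dose and the last recorded activity; otherwise the episode is censored
at the last medication use.  For oral drugs the last exposure is projected
from supply fields: `order_date + days_supply × (1 + refills) − 1`.

**Lines of therapy.** Line 1 starts at the first SACT on/after the index
date (first advanced diagnosis); a drug introduced within the next 28 days
joins the line's regimen; a drug outside the regimen at ≥ 28 days, or any
SACT after a ≥ 120-day gap, starts a new line.  Sparse vendor LOT tables
(number + start only) get end dates imputed as the day before the next line
and regimen names rebuilt from the events in the window.

**Twenty quality checks** over four element groups — SACT records (1–9), LOT
structure (10–14), mortality (15–17), follow-up (18–20) — each labelled with
a harmonized quality dimension (conformance / completeness / plausibility)
and an applicability flag (oral-only checks are omitted for an intravenous
target; mortality plausibility checks are omitted when death dates are
year-precision).

**A synthetic cohort generator** that emulates the structure of commercial
oncology EHR data sets with known ground truth, plus a defect injector
(coarsened dates, stripped drug identities, missing refills, conflicting or
missing death records, post-death activity, mis-numbered lines, data lag)
that logs every mutation — so every check is testable against the rate it is
supposed to measure.

## Worked example

Generate a 500-patient synthetic cohort and assess it:

```
$ rwttd-qa simulate --out demo --seed 7 --n 500
wrote 500 patients, 12316 drug events, 43950 activities to demo

$ rwttd-qa assess --config demo/config.yaml --in demo --out demo_report
assessed 500 patients, 319 target episodes; median rwTTD 127 days
```

`demo_report/qc_report.json` then contains, among the 20 tasks:

| task | meaning | value |
| --- | --- | --- |
| 1 | patients with any SACT record after index | 448/500 (89.6%) |
| 4 | administrations with a complete (day-precise) date | 11370/11370 (100%) |
| 5 | gaps between target administrations | median 21 d (IQR 21–21, n=4517) |
| 12 | patients whose first LOT number is not 1 | 0/448 (0%) |
| 15 | patients with a death record | 255/500 (51.0%) |
| 17 | patients with activity recorded after death | 0/255 (0%) |

Read: the cohort is defect-free (tasks 4, 12, 17 at their clean values), the
21-day gap median matches the target's every-3-weeks schedule, and roughly
half the patients have a death record — the pattern an adequate data set
should show.  Injecting defects moves exactly the matching task:
`drop_refill_fields: 0.2` in the params file drops task 7 completeness to
≈ 80%, `truncate_recent_months: 6` empties the last two quarters of the
task-10 initiation matrix (the signature of data lag).

`rwttd_results.csv` holds one row per target episode:

```
patient_id,line_number,line_group,therapy,first_dose_date,last_exposure_date,discontinuation_date,event,reason,rwttd_days
P00002,1,1L,combo,2015-02-17,2019-11-05,,false,censored,1723
P00004,2,2L+,combo,2019-02-08,2019-05-03,2019-05-03,true,death_on_therapy,85
```

Subcommands: `assess`, `simulate`, `derive-lots` (derivation only), `rwttd`
(end point only).  Every run writes a `manifest.json` tying outputs to input
digests and the config hash; reports are byte-identical across reruns of the
same inputs.

## Library use

```python
from rwttdqa import SyntheticParams, generate_cohort, run_assessment

params = SyntheticParams(n_patients=1000, seed=3)
bundle, truth = generate_cohort(params)
report = run_assessment(bundle, params.assessment_config())
print(report.task(5).stats["median"])   # 21.0
```

See `docs/methods.md` for the model, rule conventions, generator design and
known limitations.
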