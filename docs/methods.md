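# Methods

## Problem and scope

`rwttd-qa` implements a use-case-specific data-quality assessment for the
real-world time-to-treatment-discontinuation (rwTTD) end point of a systemic
anticancer therapy (SACT) estimated from EHR-derived oncology tables.  The
package covers the whole chain the end point depends on: a typed cohort data
model, line-of-therapy (LOT) derivation, the end-point computation with its
discontinuation and censoring rules, twenty quality checks grouped by the
data elements they verify, and a synthetic cohort generator with logged
defect injection so every check and the end-point pipeline can be validated
without access to real (proprietary) data.

## The end point

rwTTD is the inclusive day count from the first to the last recorded dose of
the target drug:

    rwTTD = (date of last recorded dose − date of first recorded dose) + 1 day

An episode ends in a discontinuation *event* when any of the following holds,
evaluated in priority order (the priority affects only the reason label, never
the date):

1. **death on therapy** — a day-precise death date no more than
   `gap_threshold_days` (default 120) after the last dose;
2. **new treatment** — a LOT with a higher line number starting after the
   last dose;
3. **activity gap** — at least `gap_threshold_days` between the last dose and
   the last recorded activity of any category.

Otherwise the episode is censored at the last medication use.  The
discontinuation date for every event reason is the last exposure date.

Design choices where the conceptual definition is open:

- "Died during therapy" is operationalized as death within the same 120-day
  gap threshold used for the activity rule, keeping one notion of "still on
  therapy"; it is configurable.
- A new treatment requires a *higher line number*; a drug switch inside the
  same line is a regimen change, not a discontinuation.
- A re-initiation of the target in a later line is a separate episode and is
  reported separately.
- For oral targets the last exposure is projected from supply fields:
  `order_date + days_supply × (1 + refills) − 1`; orders missing those fields
  contribute their order date and are counted as degraded.
- A death date coarser than day precision cannot support day arithmetic; the
  death branch is skipped and the skip logged, the same posture the quality
  checks take (tasks 16–17 are omitted when no day-precise death exists).

## LOT derivation

Line 1 starts at the first SACT event on or after the index date (the first
advanced-diagnosis date).  Two rules create line boundaries:

- **combination window** — a drug whose first appearance falls at day offsets
  0–27 from the line start joins the line's regimen; a drug outside the
  current regimen first appearing at offset ≥ 28 starts a new line.  The
  window is anchored at the line start, not at the previous event, and day 28
  is exclusive (a literal reading of "within the next 28 days").
- **therapy gap** — any SACT event after a gap of ≥ 120 days since the
  previous SACT event starts a new line, even when the drug is unchanged
  (consistent with the rwTTD gap rule).

Events are processed in (date, drug-name) order, making derivation invariant
to input ordering; coarse-dated events are skipped with a logged count.  The
regimen name is the sorted distinct ingredient set joined by `+`; the line
end date is the last assigned event date.

These two rules admit exactly one partition of a patient's event sequence.
The test suite verifies this with an independent brute-force checker that
enumerates all contiguous partitions and filters by the rules (10,000 random
small patients, uniqueness asserted each time).

Sparse vendor LOT tables (line number + start date only) get end dates
imputed as the day before the next line's start (data cutoff for the last
line) and regimen names rebuilt from the SACT events inside the imputed
window.  When both a vendor table and raw events exist, quality checks use
the vendor table — mirroring practice, where the provided LOT is the product
under assessment — and a provided-vs-derived agreement count is emitted as a
diagnostic.

## The twenty checks

Tasks 1–9 verify SACT administration/order records (presence after index,
drug identity, date completeness, dosing-gap distribution, supply/refill
completeness); tasks 10–14 verify LOT structure (quarterly initiation matrix,
field completeness, first-line numbering, line at target initiation,
early-receipt dates vs approval dates); tasks 15–17 verify mortality (death
record presence, conflicting records, post-death activity tiered at ≥1/3/7/30
days); tasks 18–20 verify follow-up (patients and patient-date pairs per
activity category, visit frequency during treatment, dose-to-last-visit gap
among patients surviving a 180-day window).  Dimension labels
(conformance/completeness/plausibility) follow the harmonized data-quality
terminology and are config-overridable, as the published task list does not
fix the assignment.

Conventions applied uniformly:

- "after the diagnosis date" means on-or-after the index date (same-day
  treatment starts are clinically real);
- records whose dates are too coarse for a comparison leave the task's
  denominator, and every exclusion is counted in the degradation log;
- task 5 pools within-patient consecutive-date gaps across patients and
  collapses same-day duplicates;
- task 12's denominator is patients with at least one LOT starting on/after
  the index date — patients without LOT records cannot exhibit the defect,
  and this base makes the reported proportion directly interpretable as a
  rate over the affected units;
- task 14 uses ceiling-rank order statistics (the ⌈p·n⌉-th earliest
  initiation date); percentile dates are reported only when `n ≥ 1/p`,
  otherwise marked not calculated;
- task 17 counts at patient level (a patient counts once per tier if any
  activity exceeds the tier); tier counts are therefore monotone
  nonincreasing;
- tasks 19–20 count "visits" as the configurable visit-category set, default
  `facility_visit`; task 20 excludes patients whose last visit precedes the
  last dose (logged).

Oral-only tasks (6, 9) are marked inapplicable with a reason when the target
route is intravenous; mortality plausibility tasks (16, 17) are marked
inapplicable when no day-precise death date exists.

## Synthetic cohorts and defect injection

The generator emulates the *structure* of commercial EHR-derived oncology
data sets, not clinical dynamics: no tumor model, no covariate-dependent
treatment choice.  Key defaults and their rationale:

| parameter | default | why |
| --- | --- | --- |
| index window | 2015-01-01 – 2019-08-31 | covers the study window used throughout |
| data cutoff | 2019-11-25 | end of observation for censoring and lag checks |
| dosing interval | 21 days, jitter 0 | the expected q3w schedule of an IV immunotherapy |
| cycles per line | geometric, mean 6 | right-skewed treatment durations |
| target line placement | none/1/2/3 at 25/30/30/15% | first- and later-line use both present |
| combination probability | 0.30 (60% of combos approved) | mono-dominant use with an approved partner set |
| discontinuation scenarios | death 30%, switch 25%, abandon 15%, censored 30% | all four endpoint branches well populated |
| mortality knobs | 0.65–0.85 post-discontinuation death probabilities | overall death-record prevalence ≈ 52–64%, in line with an advanced head-and-neck-cancer cohort |
| activity rates | 0.02–1.0 events / 30 days per category | multi-category follow-up with realistic density |

Lines are constructed to satisfy the derivation rules *by construction*:
every regimen drug starts on the line's first dosing day; a switch transition
uses a 30–100-day gap with a regimen disjoint from the previous line; a
restart transition uses a ≥ 130-day gap.  Each target episode is built to
realize a chosen discontinuation scenario, and the true reason is then
re-derived by the generator itself with plain date arithmetic — a second,
independent implementation of the endpoint definition — so the recovery test
compares two separately written rule evaluations.  When the calendar makes a
scenario infeasible (e.g. an index too close to cutoff for a 120-day gap),
the records are kept and the truth reflects what was actually built.

Clean cohorts are free of every defect the checks look for: all dates
day-precise, all drug records identified, vendor LOT tables equal to the
construction plan, no activity after death.  `inject_defects` then applies
each defect independently at its configured rate (identity stripping, date
coarsening, supply-field removal, death-record removal/duplication/
coarsening, post-death activity with tier-categorical gaps, first-line
renumbering, SACT record dropout, and recency truncation emulating data
lag), logging every mutation, so each task's observed proportion can be
compared with the exact binomial interval of the injected rate.

What passing these tests shows — and does not show: they demonstrate that
the checks measure what they claim on data whose truth is known, and that
the endpoint and derivation implement their definitions exactly.  They do
not certify behaviour on real EHR data, whose defects are correlated,
whose LOT tables come from unknown vendor algorithms, and whose
missingness is rarely independent of outcome.

## Numerical and degenerate-input choices

- Quantiles use linear interpolation (NumPy default); SD is the sample
  standard deviation (ddof = 1, 0 for a single value).
- Kaplan–Meier summaries use the product-limit estimator (via lifelines);
  the median is the smallest time with survival ≤ 0.5 and is reported as
  undefined when never reached.
- Ties in sparse-LOT starts break by line number (logged finding, not an
  error); a same-day successor line yields a one-day line.
- Zero-length episodes (first dose = last dose) are excluded from the
  visit-frequency denominator with a logged count.
- Exact-duplicate rows are dropped at load with a logged count; duplicates
  carry no information for any check.
- Reports are a pure function of (cohort, config): no timestamps inside
  `qc_report.json`, keys sorted, floats rounded to 4 decimals.

## Problem sizes used in the validation suite

The test suite and the reproduction script use 10,000 enumeration cases for
the derivation cross-check, 2,000-patient cohorts for recovery and
defect-rate properties, 1,000 patients for the dosing-grid/data-lag
signatures, and a 10,000-patient cohort for the end-to-end scale check —
sizes at which every binomial recovery interval is informative while the
whole suite stays fast.

## Known limitations

- The advanced-cohort restriction (stage IV + metastasis code) is atemporal:
  codes are not required to precede or follow the index date.
- Oral-target ground truth records the last *order* date, not the projected
  supply end, so endpoint recovery on oral targets is only exercised by unit
  tests, not by the cohort-level recovery property.
- The maintenance-therapy flag is carried through but plays no algorithmic
  role in derivation.
- No cross-data-set comparison logic: the package assesses one cohort per
  run; comparing two sources is interpretation done on two reports.
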