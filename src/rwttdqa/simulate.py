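"""Synthetic EHR-like oncology cohorts with known ground truth.

The generator emulates the structure of commercial EHR-derived oncology data
sets for an advanced head-and-neck-cancer population treated with an
intravenous target drug: a per-patient advanced-diagnosis index date, lines
of therapy built to satisfy the LOT derivation rules by construction (every
regimen drug starts on the line's first dosing day; switch transitions use a
30-100 day gap with a disjoint regimen; restart transitions use a >=130 day
gap), intravenous administrations on a fixed dosing grid (default every 21
days), supportive-care oral orders with days-supply/refill fields, death
dates, and multi-category follow-up activity.

Every target episode is constructed to realize a known discontinuation
scenario (death on therapy, switch to a new treatment, activity gap, or
censoring at cutoff), and the generator re-derives the true reason from its
own records with plain date arithmetic, independent of the assessment
pipeline, so recovery can be tested end to end.

Defect injection mutates a clean cohort at per-defect rates and logs every
mutation, so each quality check can be validated against the rate it is
supposed to measure.

A single seeded pseudo-random stream is consumed in documented order
(patients in id order: demographics -> treatment -> orders -> activities;
then defects), so any run is reproducible from its seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dates import PartialDate
from .model import (
    ACTIVITY_CATEGORIES,
    ActivityEvent,
    AssessmentConfig,
    CohortBundle,
    ConfigError,
    DrugEvent,
    LotRecord,
    PatientRecord,
    canonical_regimen,
)

SCENARIOS = ("death_on_therapy", "new_treatment", "activity_gap", "censored")

# RxNorm-style codes for the synthetic drug menu (synthetic identifiers)
DRUG_CODES: Dict[str, str] = {
    "TARGET": "999001",
    "carboplatin": "40048",
    "cisplatin": "2555",
    "docetaxel": "72962",
    "fluorouracil": "4492",
    "methotrexate": "6851",
    "ondansetron": "26225",
}


@dataclass
class SyntheticParams:
    """Generator knobs; defaults describe the emulated study conditions."""

    n_patients: int = 2000
    seed: int = 0
    index_start: dt.date = dt.date(2015, 1, 1)
    index_end: dt.date = dt.date(2019, 8, 31)
    cutoff: dt.date = dt.date(2019, 11, 25)
    target_name: str = "TARGET"
    target_route: str = "intravenous"
    other_drugs: Tuple[str, ...] = (
        "carboplatin",
        "cisplatin",
        "docetaxel",
        "fluorouracil",
        "methotrexate",
    )
    approved_partners: Tuple[str, ...] = ("carboplatin", "fluorouracil")
    dosing_interval_days: int = 21
    dosing_jitter_days: int = 0
    mean_cycles: float = 6.0
    p_treated: float = 0.9
    target_line_probs: Tuple[float, float, float, float] = (0.25, 0.30, 0.30, 0.15)
    p_target_combo: float = 0.30
    p_combo_approved: float = 0.60
    scenario_probs: Dict[str, float] = field(
        default_factory=lambda: {
            "death_on_therapy": 0.30,
            "new_treatment": 0.25,
            "activity_gap": 0.15,
            "censored": 0.30,
        }
    )
    p_death_new_treatment: float = 0.65
    p_death_after_gap: float = 0.85
    p_death_untargeted: float = 0.80
    p_oral_orders: float = 0.6
    oral_days_supply: int = 30
    oral_max_refills: int = 2
    activity_rates: Dict[str, float] = field(
        default_factory=lambda: {
            "facility_visit": 1.0,
            "laboratory": 0.8,
            "vital_sign": 1.0,
            "diagnosis": 0.4,
            "drug": 0.6,
            "procedure": 0.2,
            "ecog": 0.2,
            "biomarker_test": 0.05,
            "genomic_test": 0.02,
        }
    )

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if self.index_end < self.index_start:
            raise ConfigError("index window is empty")
        if self.cutoff <= self.index_start:
            raise ConfigError("cutoff precedes the index window")
        probs = [self.scenario_probs.get(s, 0.0) for s in SCENARIOS]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError("scenario_probs must be nonnegative and sum to 1")
        if any(p < 0 for p in self.target_line_probs) or abs(sum(self.target_line_probs) - 1.0) > 1e-9:
            raise ConfigError("target_line_probs must be nonnegative and sum to 1")
        for name, p in (
            ("p_treated", self.p_treated),
            ("p_target_combo", self.p_target_combo),
            ("p_combo_approved", self.p_combo_approved),
            ("p_oral_orders", self.p_oral_orders),
            ("p_death_untargeted", self.p_death_untargeted),
            ("p_death_new_treatment", self.p_death_new_treatment),
            ("p_death_after_gap", self.p_death_after_gap),
        ):
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be in [0,1], got {p}")
        for cat, rate in self.activity_rates.items():
            if cat not in ACTIVITY_CATEGORIES:
                raise ConfigError(f"unknown activity category {cat!r}")
            if rate < 0:
                raise ConfigError(f"activity rate for {cat} must be nonnegative")
        if self.dosing_interval_days <= 2 * self.dosing_jitter_days:
            raise ConfigError("dosing jitter too large for the dosing interval")

    def assessment_config(self) -> AssessmentConfig:
        approved = canonical_regimen((self.target_name,) + self.approved_partners)
        return AssessmentConfig(
            target_name=self.target_name,
            target_codes=(f"RxNorm:{DRUG_CODES.get(self.target_name, '999001')}",),
            target_route=self.target_route,
            study_start_date=self.index_start,
            data_cutoff_date=self.cutoff,
            approval_dates={
                "second_line_plus": dt.date(2016, 8, 5),
                "first_line_combo": dt.date(2019, 6, 10),
            },
            approved_combinations=(approved,),
        )


@dataclass
class DefectSpec:
    """Per-defect injection rates; every rate is an independent Bernoulli.

    Rates mirror the quality findings the checks are designed to surface:
    identity-less drug records, coarse administration/order dates, missing
    supply/refill fields, year-only or missing or conflicting death dates,
    post-death activity, mis-numbered first lines, dropped SACT records and
    recency truncation (data lag).
    """

    strip_drug_identity: float = 0.0  # task 2
    drop_admin_date_precision: float = 0.0  # task 4
    drop_refill_fields: float = 0.0  # task 7
    drop_order_date_precision: float = 0.0  # task 8
    renumber_first_lot: float = 0.0  # task 12
    drop_death_record: float = 0.0  # task 15
    duplicate_death_conflicting: float = 0.0  # task 16
    coarsen_death_to_year: float = 0.0  # tasks 16/17 applicability
    add_post_death_activity: float = 0.0  # task 17
    drop_sact_records: float = 0.0
    truncate_recent_months: int = 0  # data lag, task 10
    post_death_tier_probs: Tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    post_death_tiers: Tuple[int, ...] = (1, 3, 7, 30)

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if f.name in ("truncate_recent_months", "post_death_tier_probs", "post_death_tiers"):
                continue
            value = getattr(self, f.name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"defect rate {f.name} must be in [0,1], got {value}")
        if self.truncate_recent_months < 0:
            raise ConfigError("truncate_recent_months must be nonnegative")
        if len(self.post_death_tier_probs) != len(self.post_death_tiers):
            raise ConfigError("post_death_tier_probs must match post_death_tiers in length")
        if abs(sum(self.post_death_tier_probs) - 1.0) > 1e-9:
            raise ConfigError("post_death_tier_probs must sum to 1")


@dataclass
class EpisodeTruth:
    patient_id: str
    line_number: int
    first_dose: dt.date
    last_dose: dt.date
    reason: str
    discontinuation_date: Optional[dt.date]

    def to_dict(self) -> Dict:
        return {
            "patient_id": self.patient_id,
            "line_number": self.line_number,
            "first_dose": self.first_dose.isoformat(),
            "last_dose": self.last_dose.isoformat(),
            "reason": self.reason,
            "discontinuation_date": (
                None if self.discontinuation_date is None else self.discontinuation_date.isoformat()
            ),
        }


@dataclass
class GroundTruth:
    """What the generator actually built, for recovery testing."""

    lots: List[LotRecord]
    episodes: List[EpisodeTruth]
    defect_log: List[Dict] = field(default_factory=list)

    def lots_for(self, patient_id: str) -> List[LotRecord]:
        return [l for l in self.lots if l.patient_id == patient_id]

    def to_dict(self) -> Dict:
        return {
            "lots": [
                {
                    "patient_id": l.patient_id,
                    "line_number": l.line_number,
                    "regimen_name": l.regimen_name,
                    "start_date": l.start_date.isoformat(),
                    "end_date": None if l.end_date is None else l.end_date.isoformat(),
                }
                for l in self.lots
            ],
            "episodes": [e.to_dict() for e in self.episodes],
            "defect_log": list(self.defect_log),
        }


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_RACES = ("White", "Black or African American", "Asian", "Other race", "Missing")
_RACE_P = (0.67, 0.11, 0.02, 0.14, 0.06)


def _geometric_cycles(rng: np.random.Generator, mean_cycles: float) -> int:
    p = 1.0 / max(mean_cycles, 1.0)
    return int(rng.geometric(p))


def _dose_grid(
    rng: np.random.Generator,
    start: dt.date,
    n_cycles: int,
    interval: int,
    jitter: int,
    limit: dt.date,
) -> List[dt.date]:
    dates = [start]
    for i in range(1, n_cycles):
        offset = i * interval + (int(rng.integers(-jitter, jitter + 1)) if jitter else 0)
        d = start + dt.timedelta(days=offset)
        if d > limit:
            break
        if d <= dates[-1]:  # keep the grid strictly increasing under jitter
            d = dates[-1] + dt.timedelta(days=1)
        dates.append(d)
    return dates


@dataclass
class _LinePlan:
    number: int
    regimen: Tuple[str, ...]
    dates: List[dt.date]

    @property
    def start(self) -> dt.date:
        return self.dates[0]

    @property
    def end(self) -> dt.date:
        return self.dates[-1]


def _true_reason(
    last_dose: dt.date,
    death: Optional[dt.date],
    later_line_starts: Sequence[dt.date],
    last_activity: Optional[dt.date],
    gap_threshold: int = 120,
) -> str:
    """Independent re-derivation of the discontinuation reason.

    Mirrors the conceptual definition with plain date arithmetic: death
    within the gap threshold of the last dose, else a later line starting
    after the last dose, else an activity gap of at least the threshold,
    else censored.
    """
    if death is not None and (death - last_dose).days <= gap_threshold:
        return "death_on_therapy"
    if any(s > last_dose for s in later_line_starts):
        return "new_treatment"
    if last_activity is not None and (last_activity - last_dose).days >= gap_threshold:
        return "activity_gap"
    return "censored"


def generate_cohort(params: SyntheticParams) -> Tuple[CohortBundle, GroundTruth]:
    """Generate a clean cohort and its ground truth.

    The cohort is defect-free: all dates day-precise, all drug records
    identified, provided LOTs equal the construction plan, activities never
    postdate death.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    interval = params.dosing_interval_days
    jitter = params.dosing_jitter_days
    cutoff = params.cutoff
    target = params.target_name
    oral_target = params.target_route == "oral"

    patients: List[PatientRecord] = []
    drug_events: List[DrugEvent] = []
    activities: List[ActivityEvent] = []
    provided_lots: List[LotRecord] = []
    truth_lots: List[LotRecord] = []
    truth_episodes: List[EpisodeTruth] = []

    index_span = (params.index_end - params.index_start).days

    for i in range(params.n_patients):
        pid = f"P{i:05d}"
        index = params.index_start + dt.timedelta(days=int(rng.integers(0, index_span + 1)))
        sex = str(rng.choice(["male", "female", "unknown"], p=[0.70, 0.295, 0.005]))
        age = int(np.clip(round(rng.normal(62, 10)), 18, 90))
        race = str(rng.choice(_RACES, p=_RACE_P))
        codes = [("ICD-10", f"C7{int(rng.integers(6, 9))}.{int(rng.integers(0, 10))}")]
        if rng.random() < 0.3:
            codes.append(("ICD-9", f"19{int(rng.integers(6, 9))}.{int(rng.integers(0, 10))}"))

        treated = rng.random() < params.p_treated
        target_line = 0
        scenario = None
        if treated:
            target_line = int(rng.choice([0, 1, 2, 3], p=params.target_line_probs))
            if target_line:
                scenario = str(
                    rng.choice(SCENARIOS, p=[params.scenario_probs[s] for s in SCENARIOS])
                )

        # ---- treatment lines -------------------------------------------
        lines: List[_LinePlan] = []
        death: Optional[dt.date] = None
        tail_visit: Optional[dt.date] = None
        if treated:
            n_lines = target_line if target_line else int(rng.integers(1, 3))
            if scenario == "new_treatment":
                n_lines = target_line + 1
            prev: Optional[_LinePlan] = None
            for k in range(1, n_lines + 1):
                # transition into line k
                if prev is None:
                    start = index + dt.timedelta(days=int(rng.integers(0, 46)))
                    switch = False
                else:
                    switch = rng.random() < 0.6
                    gap = (
                        30 + int(rng.integers(0, 71))
                        if switch
                        else 130 + int(rng.integers(0, 121))
                    )
                    start = prev.end + dt.timedelta(days=gap)
                if start > cutoff:
                    break
                # regimen for line k
                banned = set(prev.regimen) if (prev is not None and switch) else set()
                if k == target_line:
                    if rng.random() < params.p_target_combo:
                        if rng.random() < params.p_combo_approved and not (
                            banned & set(params.approved_partners)
                        ):
                            partners = params.approved_partners
                        else:
                            pool = [d for d in params.other_drugs if d not in banned]
                            partners = tuple(
                                str(d) for d in rng.choice(pool, size=1, replace=False)
                            )
                        regimen = (target,) + partners
                    else:
                        regimen = (target,)
                else:
                    pool = [d for d in params.other_drugs if d not in banned]
                    size = int(rng.integers(1, 3))
                    regimen = tuple(
                        str(d) for d in rng.choice(pool, size=min(size, len(pool)), replace=False)
                    )
                # cycle count / grid limit per scenario
                limit = cutoff
                if k == target_line and scenario == "censored":
                    n_cycles = 10_000  # run to the cutoff
                else:
                    n_cycles = _geometric_cycles(rng, params.mean_cycles)
                    if k == target_line and scenario == "activity_gap":
                        limit = cutoff - dt.timedelta(days=130)
                        if start > limit:
                            limit = cutoff  # no room: scenario degrades naturally
                dates = _dose_grid(rng, start, n_cycles, interval, jitter, limit)
                plan = _LinePlan(number=k, regimen=regimen, dates=dates)
                lines.append(plan)
                prev = plan

            # renumber after potential truncation
            for n, plan in enumerate(lines, start=1):
                plan.number = n
            if target_line and not any(target in p.regimen for p in lines):
                target_line = 0  # target line did not fit before cutoff
                scenario = None

            # ---- death per scenario ------------------------------------
            tplan = next((p for p in lines if target in p.regimen), None)
            if scenario == "death_on_therapy" and tplan is not None:
                cand = tplan.end + dt.timedelta(days=1 + int(rng.integers(0, 100)))
                death = cand if cand <= cutoff else None
            elif scenario == "new_treatment" and lines:
                if rng.random() < params.p_death_new_treatment:
                    cand = lines[-1].end + dt.timedelta(days=121 + int(rng.integers(0, 200)))
                    death = cand if cand <= cutoff else None
            elif scenario == "activity_gap" and tplan is not None:
                cand = tplan.end + dt.timedelta(days=120 + int(rng.integers(0, 61)))
                tail_visit = cand if cand <= cutoff else None
                if tail_visit is not None and rng.random() < params.p_death_after_gap:
                    cand = tail_visit + dt.timedelta(days=1 + int(rng.integers(0, 60)))
                    death = cand if cand <= cutoff else None
            elif scenario is None:
                if rng.random() < params.p_death_untargeted:
                    cand = index + dt.timedelta(days=60 + int(rng.integers(0, 900)))
                    death = cand if cand <= cutoff else None
        else:
            if rng.random() < params.p_death_untargeted:
                cand = index + dt.timedelta(days=60 + int(rng.integers(0, 900)))
                death = cand if cand <= cutoff else None

        # ---- materialize drug events and LOT records --------------------
        for plan in lines:
            for d in plan.dates:
                for drug in sorted(plan.regimen):
                    is_target_drug = drug == target
                    route = "ordered" if (oral_target and is_target_drug) else "administered"
                    drug_events.append(
                        DrugEvent(
                            patient_id=pid,
                            event_date=PartialDate.from_date(d),
                            route_kind=route,
                            drug_name=drug,
                            code_system="RxNorm",
                            drug_code=DRUG_CODES.get(drug, "0"),
                            days_supply=interval if route == "ordered" else None,
                            refills=0 if route == "ordered" else None,
                            canceled=False,
                            is_sact=True,
                            is_target=is_target_drug,
                        )
                    )
            lot = LotRecord(
                patient_id=pid,
                line_number=plan.number,
                regimen_name=canonical_regimen(plan.regimen),
                start_date=PartialDate.from_date(plan.start),
                end_date=PartialDate.from_date(plan.end),
                provenance="provided",
            )
            provided_lots.append(lot)
            truth_lots.append(dataclasses.replace(lot, provenance="derived"))

        # ---- supportive oral orders (non-SACT) ---------------------------
        order_end = min(cutoff, death - dt.timedelta(days=1)) if death else cutoff
        if rng.random() < params.p_oral_orders and order_end >= index:
            n_orders = 1 + int(rng.poisson(2))
            span = (order_end - index).days
            for _ in range(n_orders):
                d = index + dt.timedelta(days=int(rng.integers(0, span + 1)))
                drug_events.append(
                    DrugEvent(
                        patient_id=pid,
                        event_date=PartialDate.from_date(d),
                        route_kind="ordered",
                        drug_name="ondansetron",
                        code_system="RxNorm",
                        drug_code=DRUG_CODES["ondansetron"],
                        days_supply=params.oral_days_supply,
                        refills=int(rng.integers(0, params.oral_max_refills + 1)),
                        canceled=bool(rng.random() < 0.05),
                        is_sact=False,
                        is_target=False,
                    )
                )

        # ---- follow-up activities ---------------------------------------
        patient_activities: List[ActivityEvent] = []
        act_end = min(cutoff, death - dt.timedelta(days=1)) if death else cutoff
        span = (act_end - index).days
        if span >= 0:
            for cat in ACTIVITY_CATEGORIES:
                rate = params.activity_rates.get(cat, 0.0)
                if rate <= 0:
                    continue
                n = int(rng.poisson(rate * (span + 1) / 30.0))
                if n == 0:
                    continue
                offsets = rng.integers(0, span + 1, size=n)
                for off in offsets:
                    patient_activities.append(
                        ActivityEvent(
                            patient_id=pid,
                            category=cat,
                            event_date=PartialDate.from_date(index + dt.timedelta(days=int(off))),
                        )
                    )
        if tail_visit is not None and (death is None or tail_visit < death):
            patient_activities.append(
                ActivityEvent(
                    patient_id=pid,
                    category="facility_visit",
                    event_date=PartialDate.from_date(tail_visit),
                )
            )
        activities.extend(patient_activities)

        patients.append(
            PatientRecord(
                patient_id=pid,
                index_date=PartialDate.from_date(index),
                sex=sex,
                age_at_index=age,
                race=race,
                ajcc_stage="IV",
                diagnosis_codes=codes,
                death_date=None if death is None else PartialDate.from_date(death),
            )
        )

        # ---- episode ground truth ---------------------------------------
        tplan = next((p for p in lines if target in p.regimen), None)
        if tplan is not None:
            last_activity = max(
                (a.event_date.as_date() for a in patient_activities),
                default=None,
            )
            later_starts = [p.start for p in lines if p.number > tplan.number]
            reason = _true_reason(tplan.end, death, later_starts, last_activity)
            truth_episodes.append(
                EpisodeTruth(
                    patient_id=pid,
                    line_number=tplan.number,
                    first_dose=tplan.start,
                    last_dose=tplan.end,
                    reason=reason,
                    discontinuation_date=tplan.end if reason != "censored" else None,
                )
            )

    bundle = CohortBundle(
        patients=patients,
        drug_events=drug_events,
        activities=activities,
        provided_lots=provided_lots,
        provenance={"sources": {"generator": f"synthetic seed={params.seed} n={params.n_patients}"}},
    )
    truth = GroundTruth(lots=truth_lots, episodes=truth_episodes)
    return bundle, truth


# ---------------------------------------------------------------------------
# defect injection
# ---------------------------------------------------------------------------


def _months_before(d: dt.date, months: int) -> dt.date:
    month = d.month - months
    year = d.year
    while month <= 0:
        month += 12
        year -= 1
    day = min(d.day, [31, 29 if year % 4 == 0 and (year % 100 != 0 or year % 400 == 0) else 28,
                      31, 30, 31, 30, 31, 31, 30, 31, 30, 31][month - 1])
    return dt.date(year, month, day)


def inject_defects(
    bundle: CohortBundle,
    truth: GroundTruth,
    spec: DefectSpec,
    seed: int,
    cutoff: Optional[dt.date] = None,
) -> Tuple[CohortBundle, GroundTruth]:
    """Apply each defect independently at its rate; log every mutation.

    Inputs are not modified; record-level copies are returned.  ``cutoff`` is
    required when ``truncate_recent_months`` is set.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    out = bundle.copy()
    log: List[Dict] = list(truth.defect_log)

    def _log(defect: str, **details) -> None:
        log.append({"defect": defect, **details})

    # drug-event-level defects, in a fixed pass order
    kept_events: List[DrugEvent] = []
    for idx, e in enumerate(out.drug_events):
        if spec.drop_sact_records and e.is_sact and rng.random() < spec.drop_sact_records:
            _log("drop_sact_records", patient_id=e.patient_id, record=idx)
            continue
        if spec.strip_drug_identity and rng.random() < spec.strip_drug_identity:
            e.drug_name = None
            e.code_system = None
            e.drug_code = None
            e.is_sact = False
            e.is_target = False
            _log("strip_drug_identity", patient_id=e.patient_id, record=idx)
        if (
            spec.drop_admin_date_precision
            and e.route_kind == "administered"
            and rng.random() < spec.drop_admin_date_precision
        ):
            e.event_date = PartialDate(e.event_date.year, e.event_date.month)
            _log("drop_admin_date_precision", patient_id=e.patient_id, record=idx)
        if e.route_kind == "ordered":
            if spec.drop_refill_fields and rng.random() < spec.drop_refill_fields:
                e.days_supply = None
                e.refills = None
                _log("drop_refill_fields", patient_id=e.patient_id, record=idx)
            if spec.drop_order_date_precision and rng.random() < spec.drop_order_date_precision:
                e.event_date = PartialDate(e.event_date.year, e.event_date.month)
                _log("drop_order_date_precision", patient_id=e.patient_id, record=idx)
        kept_events.append(e)
    out.drug_events = kept_events

    # patient-level death defects
    for p in out.patients:
        if p.death_date is None:
            continue
        if spec.drop_death_record and rng.random() < spec.drop_death_record:
            p.death_date = None
            p.extra_death_dates = []
            _log("drop_death_record", patient_id=p.patient_id)
            continue
        if (
            spec.duplicate_death_conflicting
            and p.death_date.is_day()
            and rng.random() < spec.duplicate_death_conflicting
        ):
            other = p.death_date.as_date() + dt.timedelta(days=1 + int(rng.integers(0, 30)))
            p.extra_death_dates.append(PartialDate.from_date(other))
            _log("duplicate_death_conflicting", patient_id=p.patient_id)
        if spec.coarsen_death_to_year and rng.random() < spec.coarsen_death_to_year:
            p.death_date = PartialDate(p.death_date.year)
            p.extra_death_dates = [PartialDate(d.year) for d in p.extra_death_dates]
            _log("coarsen_death_to_year", patient_id=p.patient_id)

    # post-death activity
    if spec.add_post_death_activity:
        tiers = np.asarray(spec.post_death_tiers)
        tier_p = np.asarray(spec.post_death_tier_probs)
        for p in out.patients:
            if p.death_date is None or not p.death_date.is_day():
                continue
            if rng.random() < spec.add_post_death_activity:
                gap = int(rng.choice(tiers, p=tier_p))
                date = p.death_date.as_date() + dt.timedelta(days=gap)
                out.activities.append(
                    ActivityEvent(
                        patient_id=p.patient_id,
                        category="facility_visit",
                        event_date=PartialDate.from_date(date),
                    )
                )
                _log("add_post_death_activity", patient_id=p.patient_id, gap_days=gap)

    # provided-LOT renumbering
    if spec.renumber_first_lot and out.provided_lots:
        by_pid: Dict[str, List[LotRecord]] = {}
        for lot in out.provided_lots:
            by_pid.setdefault(lot.patient_id, []).append(lot)
        for pid in sorted(by_pid):
            if rng.random() < spec.renumber_first_lot:
                for lot in by_pid[pid]:
                    lot.line_number += 1
                _log("renumber_first_lot", patient_id=pid)

    # recency truncation (data lag)
    if spec.truncate_recent_months:
        if cutoff is None:
            raise ConfigError("truncate_recent_months requires a cutoff date")
        horizon = _months_before(cutoff, spec.truncate_recent_months)
        n_drug = len(out.drug_events)
        out.drug_events = [
            e
            for e in out.drug_events
            if not (e.event_date.is_day() and e.event_date.as_date() > horizon)
        ]
        n_act = len(out.activities)
        out.activities = [
            a
            for a in out.activities
            if not (a.event_date.is_day() and a.event_date.as_date() > horizon)
        ]
        _log(
            "truncate_recent_months",
            months=spec.truncate_recent_months,
            horizon=horizon.isoformat(),
            drug_events_removed=n_drug - len(out.drug_events),
            activities_removed=n_act - len(out.activities),
        )

    new_truth = GroundTruth(
        lots=[dataclasses.replace(l) for l in truth.lots],
        episodes=[dataclasses.replace(e) for e in truth.episodes],
        defect_log=log,
    )
    return out, new_truth


def write_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
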