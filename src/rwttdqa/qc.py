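"""The 20 data-quality checks for the rwTTD use case, and the report.

The checks cover four groups of required data elements: systemic anticancer
therapy administrations and orders (tasks 1-9), line-of-therapy structure
(tasks 10-14), mortality (tasks 15-17) and follow-up activity (tasks 18-20).
Each task is labelled with a harmonized quality dimension (conformance,
completeness, plausibility) and reports a numerator/denominator, summary
statistics, or a stratified table, together with an applicability flag:
oral-only tasks are marked omitted for an intravenous target, and mortality
plausibility tasks are marked omitted when death dates are coarser than day
precision.

"After the diagnosis date" is implemented as on-or-after the index date
(same-day treatment starts are clinically real).  Records whose dates are too
coarse for a comparison are excluded from that task's denominator and the
exclusion is counted in the degradation log.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .endpoint import RwttdResult, discontinuation_status
from .lot import (
    classify_target_episodes,
    compare_lots,
    derive_lots,
    impute_sparse_lots,
)
from .model import (
    ACTIVITY_CATEGORIES,
    AssessmentConfig,
    CohortBundle,
    LotRecord,
    TargetEpisode,
    harmonize_drugs,
    restrict_to_advanced,
)

logger = logging.getLogger(__name__)

TITLES: Dict[int, str] = {
    1: "Patients with any SACT administration or order record after the index date",
    2: "SACT drug records with missing drug identity (name and code)",
    3: "Patients with target SACT administration after the index date, study start onward",
    4: "SACT drug administration records with complete administration date",
    5: "Gap (days) between target SACT administration dates",
    6: "Patients with target SACT order date after the index date",
    7: "SACT drug order records with complete days-supply and refill information",
    8: "SACT drug order records with complete order date",
    9: "Gaps (days) between target SACT order dates, normalized by supply/refill/cancellation",
    10: "Patients initiating the target SACT by year and quarter",
    11: "Completeness of LOT information",
    12: "Patients whose first LOT number after the index date was not 1",
    13: "Distribution of LOT number at target SACT initiation",
    14: "Use of target SACT in first line relative to approval dates",
    15: "Patients with a death record",
    16: "Patients with multiple death records on different dates",
    17: "Patients with clinical activity recorded after the death date",
    18: "Unique patients and patient-date pairs after the index date, by activity category",
    19: "Frequency of visits during target SACT treatment",
    20: "Gap (days) from last target SACT administration to last visit, patients still alive",
}

DIMENSIONS: Dict[int, str] = {
    1: "completeness",
    2: "completeness",
    3: "completeness",
    4: "completeness",
    5: "plausibility",
    6: "completeness",
    7: "completeness",
    8: "completeness",
    9: "plausibility",
    10: "plausibility",
    11: "completeness",
    12: "plausibility",
    13: "plausibility",
    14: "plausibility",
    15: "completeness",
    16: "plausibility",
    17: "plausibility",
    18: "completeness",
    19: "plausibility",
    20: "plausibility",
}

ORAL_ONLY_TASKS = (6, 9)


@dataclass
class TaskResult:
    """One structured quality-check result."""

    task_id: int
    title: str
    dimension: str
    applicable: bool = True
    omission_reason: Optional[str] = None
    numerator: Optional[int] = None
    denominator: Optional[int] = None
    stats: Optional[Dict[str, float]] = None
    strata: Optional[Dict] = None
    notes: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (
            self.numerator is not None
            and self.denominator is not None
            and self.numerator > self.denominator
        ):
            raise ValueError(
                f"task {self.task_id}: numerator {self.numerator} > denominator {self.denominator}"
            )

    @property
    def percent(self) -> Optional[float]:
        if self.numerator is None or not self.denominator:
            return None
        return 100.0 * self.numerator / self.denominator

    def to_dict(self) -> Dict:
        pct = self.percent
        return {
            "task_id": self.task_id,
            "title": self.title,
            "dimension": self.dimension,
            "applicable": self.applicable,
            "omission_reason": self.omission_reason,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "percent": None if pct is None else round(pct, 4),
            "stats": self.stats,
            "strata": self.strata,
            "notes": list(self.notes),
        }


def _stats(values: Sequence[float]) -> Optional[Dict[str, float]]:
    if len(values) == 0:
        return None
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(arr, [25, 75])
    return {
        "n": int(arr.size),
        "median": round(float(np.median(arr)), 4),
        "q1": round(float(q1), 4),
        "q3": round(float(q3), 4),
        "min": round(float(arr.min()), 4),
        "max": round(float(arr.max()), 4),
        "mean": round(float(arr.mean()), 4),
        "sd": round(float(arr.std(ddof=1)), 4) if arr.size > 1 else 0.0,
    }


def _dimension(task_id: int, config: AssessmentConfig) -> str:
    return config.task_dimensions.get(task_id, DIMENSIONS[task_id])


def _task(task_id: int, config: AssessmentConfig, **kwargs) -> TaskResult:
    return TaskResult(
        task_id=task_id,
        title=TITLES[task_id],
        dimension=_dimension(task_id, config),
        **kwargs,
    )


def _not_applicable(task_id: int, config: AssessmentConfig, reason: str) -> TaskResult:
    return _task(task_id, config, applicable=False, omission_reason=reason)


# ---------------------------------------------------------------------------
# tasks 1-9: SACT administration and order records
# ---------------------------------------------------------------------------


def check_sact(
    bundle: CohortBundle,
    lots: Sequence[LotRecord],
    config: AssessmentConfig,
    notes: Optional[List[str]] = None,
) -> List[TaskResult]:
    notes = notes if notes is not None else []
    index_by_pid = {
        p.patient_id: p.index_date.as_date() for p in bundle.patients if p.index_date.is_day()
    }
    coarse_index = len(bundle.patients) - len(index_by_pid)
    if coarse_index:
        notes.append(f"{coarse_index} patients with non-day index date excluded from date comparisons")
    n_patients = len(bundle.patients)
    oral = config.target_route == "oral"

    events = bundle.drug_events
    admins = [e for e in events if e.route_kind == "administered"]
    orders = [e for e in events if e.route_kind == "ordered"]
    sact_admins = [e for e in admins if e.is_sact]
    target_admins = [e for e in admins if e.is_target and not e.canceled]
    target_orders = [e for e in orders if e.is_target and not e.canceled]

    def _after_index(e) -> bool:
        idx = index_by_pid.get(e.patient_id)
        return idx is not None and e.event_date.is_day() and e.event_date.as_date() >= idx

    tasks: List[TaskResult] = []

    # T1 — any SACT record on/after the index date
    t1_pids = {e.patient_id for e in events if e.is_sact and _after_index(e)}
    tasks.append(_task(1, config, numerator=len(t1_pids), denominator=n_patients))

    # T2 — missing drug identity
    t2_num = sum(1 for e in events if e.missing_identity)
    tasks.append(_task(2, config, numerator=t2_num, denominator=len(events)))

    # T3 — target administration on/after index, patients indexed from study start
    study_pids = {
        pid for pid, idx in index_by_pid.items() if idx >= config.study_start_date
    }
    t3_pids = {e.patient_id for e in target_admins if _after_index(e) and e.patient_id in study_pids}
    tasks.append(_task(3, config, numerator=len(t3_pids), denominator=len(study_pids)))

    # T4 — complete (day-precision) administration date
    t4_num = sum(1 for e in sact_admins if e.event_date.is_day())
    tasks.append(_task(4, config, numerator=t4_num, denominator=len(sact_admins)))

    # T5 — gaps between target administration dates, pooled across patients
    per_patient: Dict[str, set] = {}
    coarse_target = 0
    for e in target_admins:
        if e.event_date.is_day():
            per_patient.setdefault(e.patient_id, set()).add(e.event_date.as_date())
        else:
            coarse_target += 1
    if coarse_target:
        notes.append(f"task 5: {coarse_target} target administrations with coarse dates excluded")
    gaps: List[int] = []
    for dates in per_patient.values():
        ordered = sorted(dates)
        gaps.extend((b - a).days for a, b in zip(ordered, ordered[1:]))
    tasks.append(
        _task(
            5,
            config,
            stats=_stats(gaps),
            notes=[f"{len(gaps)} gaps pooled over {len(per_patient)} patients; same-day duplicates collapsed"],
        )
    )

    # T6 — target orders after index (oral targets only)
    if oral:
        t6_pids = {e.patient_id for e in target_orders if _after_index(e) and e.patient_id in study_pids}
        tasks.append(_task(6, config, numerator=len(t6_pids), denominator=len(study_pids)))
    else:
        tasks.append(_not_applicable(6, config, "oral-only task; target route is intravenous"))

    # T7 — orders with complete days-supply and refill information
    t7_num = sum(1 for e in orders if e.days_supply is not None and e.refills is not None)
    tasks.append(_task(7, config, numerator=t7_num, denominator=len(orders)))

    # T8 — orders with complete order date
    t8_num = sum(1 for e in orders if e.event_date.is_day())
    tasks.append(_task(8, config, numerator=t8_num, denominator=len(orders)))

    # T9 — normalized gaps between target order dates (oral targets only)
    if oral:
        by_pid: Dict[str, List] = {}
        for e in target_orders:
            if e.event_date.is_day():
                by_pid.setdefault(e.patient_id, []).append(e)
        norm_gaps: List[int] = []
        for evs in by_pid.values():
            evs.sort(key=lambda e: e.event_date.as_date())
            for a, b in zip(evs, evs[1:]):
                start = a.event_date.as_date()
                if a.days_supply is not None:
                    covered_end = start + dt.timedelta(days=a.days_supply * (1 + (a.refills or 0)) - 1)
                else:
                    covered_end = start
                norm_gaps.append((b.event_date.as_date() - covered_end).days)
        tasks.append(
            _task(
                9,
                config,
                stats=_stats(norm_gaps),
                notes=[f"{len(norm_gaps)} order-to-order gaps after subtracting covered supply"],
            )
        )
    else:
        tasks.append(_not_applicable(9, config, "oral-only task; target route is intravenous"))
    return tasks


# ---------------------------------------------------------------------------
# tasks 10-14: LOT structure
# ---------------------------------------------------------------------------


def _quarter_label(d: dt.date) -> str:
    return f"{d.year}Q{(d.month - 1) // 3 + 1}"


def _quarter_range(start: dt.date, end: dt.date) -> List[str]:
    labels = []
    y, q = start.year, (start.month - 1) // 3 + 1
    while (y, q) <= (end.year, (end.month - 1) // 3 + 1):
        labels.append(f"{y}Q{q}")
        q += 1
        if q == 5:
            y, q = y + 1, 1
    return labels

EPISODE_GROUPS = ("1L mono", "1L combo", "2L+ mono", "2L+ combo", "unknown")


def check_lot(
    bundle: CohortBundle,
    lots: Sequence[LotRecord],
    episodes: Sequence[TargetEpisode],
    config: AssessmentConfig,
    notes: Optional[List[str]] = None,
) -> List[TaskResult]:
    notes = notes if notes is not None else []
    n_patients = len(bundle.patients)
    index_by_pid = {
        p.patient_id: p.index_date.as_date() for p in bundle.patients if p.index_date.is_day()
    }
    tasks: List[TaskResult] = []

    # T10 — quarterly initiation counts by line group and therapy type
    quarters = _quarter_range(config.study_start_date, config.data_cutoff_date)
    table: Dict[str, Dict[str, int]] = {q: {g: 0 for g in EPISODE_GROUPS} for q in quarters}
    in_window = 0
    for ep in episodes:
        d = ep.first_dose
        label = _quarter_label(d)
        if label in table:
            table[label][ep.group_label] += 1
            in_window += 1
    if in_window < len(episodes):
        notes.append(
            f"task 10: {len(episodes) - in_window} initiations outside the study window excluded"
        )
    tasks.append(
        _task(10, config, numerator=in_window, denominator=len(episodes), strata=table)
    )

    # T11 — completeness of LOT fields, patient level
    by_pid: Dict[str, List[LotRecord]] = {}
    for lot in lots:
        by_pid.setdefault(lot.patient_id, []).append(lot)
    complete = {"line_number": 0, "line_name": 0, "line_start": 0, "line_end": 0}
    for pid, plots in by_pid.items():
        if all(l.line_number is not None for l in plots):
            complete["line_number"] += 1
        if all(l.regimen_name for l in plots):
            complete["line_name"] += 1
        if all(l.start_date.is_day() for l in plots):
            complete["line_start"] += 1
        if all(l.end_date is not None and l.end_date.is_day() for l in plots):
            complete["line_end"] += 1
    strata = {
        key: {
            "patients": count,
            "percent": round(100.0 * count / n_patients, 4) if n_patients else None,
        }
        for key, count in complete.items()
    }
    tasks.append(
        _task(
            11,
            config,
            numerator=len(by_pid),
            denominator=n_patients,
            strata=strata,
            notes=["numerator counts patients with any LOT record; strata give per-field completeness"],
        )
    )

    # T12 — first LOT number after the index date is not 1
    first_not_one = 0
    with_lots_after_index = 0
    for pid, plots in by_pid.items():
        idx = index_by_pid.get(pid)
        if idx is None:
            continue
        usable = [l for l in plots if l.start_date.is_day() and l.start_date.as_date() >= idx]
        if not usable:
            continue
        with_lots_after_index += 1
        first = min(usable, key=lambda l: (l.start_date.as_date(), l.line_number))
        if first.line_number != 1:
            first_not_one += 1
    tasks.append(
        _task(
            12,
            config,
            numerator=first_not_one,
            denominator=with_lots_after_index,
            notes=["denominator counts patients with >=1 LOT starting on/after the index date"],
        )
    )

    # T13 — line number at target initiation (first episode per patient)
    first_by_pid: Dict[str, TargetEpisode] = {}
    for ep in episodes:
        cur = first_by_pid.get(ep.patient_id)
        if cur is None or ep.first_dose < cur.first_dose:
            first_by_pid[ep.patient_id] = ep
    dist: Dict[str, int] = {}
    known = 0
    for ep in first_by_pid.values():
        if ep.line_number is None:
            key = "unknown"
        elif ep.line_number <= 5:
            key = str(ep.line_number)
            known += 1
        elif ep.line_number <= 10:
            key = "6-10"
            known += 1
        else:
            key = ">10"
            known += 1
        dist[key] = dist.get(key, 0) + 1
    tasks.append(
        _task(
            13,
            config,
            numerator=known,
            denominator=len(first_by_pid),
            strata=dict(sorted(dist.items())),
        )
    )

    # T14 — first-line use relative to approval dates, with early-receipt cutoffs
    one_l_pids = {ep.patient_id for ep in episodes if ep.line_group == "1L"}
    groups = {
        "1L monotherapy": [
            ep for ep in episodes if ep.line_group == "1L" and ep.therapy == "mono"
        ],
        "approved 1L combination": [
            ep for ep in episodes if ep.line_group == "1L" and ep.approved_combo
        ],
    }
    approval_keys = {"1L monotherapy": "first_line_mono", "approved 1L combination": "first_line_combo"}
    strata = {}
    counted = 0
    for label, eps in groups.items():
        pids = {}
        for ep in eps:  # one initiation date per patient: earliest
            cur = pids.get(ep.patient_id)
            if cur is None or ep.first_dose < cur:
                pids[ep.patient_id] = ep.first_dose
        dates = sorted(pids.values())
        n = len(dates)
        counted += n
        entry: Dict[str, object] = {
            "n": n,
            "N": len(one_l_pids),
            "percent": round(100.0 * n / len(one_l_pids), 4) if one_l_pids else None,
            "first_initiation": dates[0].isoformat() if dates else None,
        }
        for p in config.receipt_percentiles:
            key = f"earliest_{round(p * 100):d}pct_date"
            if n and n >= 1.0 / p:
                k = math.ceil(p * n)
                entry[key] = dates[k - 1].isoformat()
            else:
                entry[key] = None
                if n:
                    notes.append(
                        f"task 14: {label}: earliest-{round(p*100)}% cutoff not calculated (only {n} patients)"
                    )
        approval = config.approval_dates.get(approval_keys[label])
        entry["approval_date"] = approval.isoformat() if approval else None
        entry["initiations_before_approval"] = (
            sum(1 for d in dates if d < approval) if approval else None
        )
        strata[label] = entry
    tasks.append(
        _task(
            14,
            config,
            numerator=min(counted, len(one_l_pids)),
            denominator=len(one_l_pids),
            strata=strata,
        )
    )
    return tasks


# ---------------------------------------------------------------------------
# tasks 15-17: mortality
# ---------------------------------------------------------------------------


def check_mortality(
    bundle: CohortBundle,
    config: AssessmentConfig,
    notes: Optional[List[str]] = None,
) -> List[TaskResult]:
    notes = notes if notes is not None else []
    tasks: List[TaskResult] = []
    n_patients = len(bundle.patients)
    with_death = [p for p in bundle.patients if p.death_date is not None]
    day_deaths = [p for p in with_death if p.death_date.is_day()]

    # T15 — any death record
    tasks.append(_task(15, config, numerator=len(with_death), denominator=n_patients))

    coarse_only = bool(with_death) and not day_deaths
    reason = "death dates are coarser than day precision"
    if coarse_only:
        notes.append("tasks 16-17 omitted: no day-precision death dates")
        tasks.append(_not_applicable(16, config, reason))
        tasks.append(_not_applicable(17, config, reason))
        return tasks

    # T16 — multiple death records on different dates
    t16_num = sum(1 for p in day_deaths if p.has_conflicting_death_dates())
    tasks.append(_task(16, config, numerator=t16_num, denominator=len(day_deaths)))

    # T17 — activity after the death date, tiered
    last_activity: Dict[str, dt.date] = {}
    for a in bundle.activities:
        if a.event_date.is_day():
            d = a.event_date.as_date()
            pid = a.patient_id
            if pid not in last_activity or d > last_activity[pid]:
                last_activity[pid] = d
    tiers = {f">={t}d": 0 for t in config.post_death_tiers}
    post_gaps: List[int] = []
    num = 0
    for p in day_deaths:
        death = p.death_date.as_date()
        last = last_activity.get(p.patient_id)
        if last is None or last <= death:
            continue
        gap = (last - death).days
        num += 1
        post_gaps.append(gap)
        for t in config.post_death_tiers:
            if gap >= t:
                tiers[f">={t}d"] += 1
    tasks.append(
        _task(
            17,
            config,
            numerator=num,
            denominator=len(day_deaths),
            strata=tiers,
            stats=_stats(post_gaps),
            notes=["stats summarize days from death to last recorded activity"],
        )
    )
    return tasks


# ---------------------------------------------------------------------------
# tasks 18-20: follow-up
# ---------------------------------------------------------------------------


def check_followup(
    bundle: CohortBundle,
    episodes: Sequence[TargetEpisode],
    config: AssessmentConfig,
    notes: Optional[List[str]] = None,
) -> List[TaskResult]:
    notes = notes if notes is not None else []
    tasks: List[TaskResult] = []
    n_patients = len(bundle.patients)
    index_by_pid = {
        p.patient_id: p.index_date.as_date() for p in bundle.patients if p.index_date.is_day()
    }

    # day-precision activities on/after index, per category
    per_cat: Dict[str, Dict[str, set]] = {c: {} for c in ACTIVITY_CATEGORIES}
    visit_dates: Dict[str, set] = {}
    for a in bundle.activities:
        if not a.event_date.is_day():
            continue
        idx = index_by_pid.get(a.patient_id)
        if idx is None:
            continue
        d = a.event_date.as_date()
        if a.category in config.visit_categories:
            visit_dates.setdefault(a.patient_id, set()).add(d)
        if d < idx:
            continue
        per_cat[a.category].setdefault(a.patient_id, set()).add(d)

    # T18 — unique patients and patient-date pairs per category
    strata = {}
    any_pids: set = set()
    for cat in ACTIVITY_CATEGORIES:
        pids = per_cat[cat]
        pairs = sum(len(v) for v in pids.values())
        any_pids.update(pids)
        strata[cat] = {
            "patients": len(pids),
            "percent": round(100.0 * len(pids) / n_patients, 4) if n_patients else None,
            "patient_date_pairs": pairs,
            "pairs_per_patient": round(pairs / len(pids), 2) if pids else None,
        }
    tasks.append(
        _task(18, config, numerator=len(any_pids), denominator=n_patients, strata=strata)
    )

    # T19 — visit frequency between first and last target administration
    group_freqs: Dict[str, List[float]] = {
        "1L combination": [],
        "1L monotherapy": [],
        "2L+ monotherapy": [],
        "all other": [],
    }
    excluded_single_day = 0
    for ep in episodes:
        first, last = ep.first_dose, ep.last_dose
        span = (last - first).days
        if span == 0:
            excluded_single_day += 1
            continue
        visits = sum(1 for d in visit_dates.get(ep.patient_id, ()) if first < d < last)
        freq = visits / span
        if ep.line_group == "1L" and ep.therapy == "combo":
            group_freqs["1L combination"].append(freq)
        elif ep.line_group == "1L" and ep.therapy == "mono":
            group_freqs["1L monotherapy"].append(freq)
        elif ep.line_group == "2L+" and ep.therapy == "mono":
            group_freqs["2L+ monotherapy"].append(freq)
        else:
            group_freqs["all other"].append(freq)
    if excluded_single_day:
        notes.append(
            f"task 19: {excluded_single_day} single-day episodes excluded (zero-length span)"
        )
    included = sum(len(v) for v in group_freqs.values())
    tasks.append(
        _task(
            19,
            config,
            numerator=included,
            denominator=len(episodes),
            strata={g: _stats(v) for g, v in group_freqs.items()},
        )
    )

    # T20 — gap from last target administration to last visit, patients alive
    death_by_pid = {p.patient_id: p.death_date for p in bundle.patients}
    last_target: Dict[str, dt.date] = {}
    for ep in episodes:
        cur = last_target.get(ep.patient_id)
        if cur is None or ep.last_dose > cur:
            last_target[ep.patient_id] = ep.last_dose
    window = config.alive_gap_window_days
    horizon = config.data_cutoff_date - dt.timedelta(days=window)
    gaps: List[int] = []
    coarse_death_excluded = 0
    no_visit_excluded = 0
    for pid, last in last_target.items():
        if last > horizon:
            continue  # last dose too close to cutoff to establish survival
        death = death_by_pid.get(pid)
        if death is not None:
            if not death.is_day():
                coarse_death_excluded += 1
                continue
            if (death.as_date() - last).days < window:
                continue  # did not remain alive through the window
        visits = visit_dates.get(pid)
        last_visit = max((d for d in (visits or ()) if d >= last), default=None)
        if last_visit is None:
            no_visit_excluded += 1
            continue
        gaps.append((last_visit - last).days)
    if coarse_death_excluded:
        notes.append(f"task 20: {coarse_death_excluded} patients with coarse death dates excluded")
    if no_visit_excluded:
        notes.append(f"task 20: {no_visit_excluded} patients without a visit after the last dose excluded")
    tasks.append(
        _task(
            20,
            config,
            numerator=len(gaps),
            denominator=len(last_target),
            stats=_stats(gaps),
            notes=[
                f"patients alive >={window}d after last dose with last dose >={window}d before cutoff"
            ],
        )
    )
    return tasks


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Deterministic, structured result of a full assessment run."""

    config: Dict
    config_hash: str
    provenance: Dict
    tasks: List[TaskResult]
    degradation_log: List[str]
    lot_comparison: Optional[Dict] = None

    def __post_init__(self) -> None:
        ids = sorted(t.task_id for t in self.tasks)
        if ids != list(range(1, 21)):
            raise ValueError(f"report must contain tasks 1-20 exactly once, got {ids}")

    def task(self, task_id: int) -> TaskResult:
        return next(t for t in self.tasks if t.task_id == task_id)

    def to_dict(self) -> Dict:
        return {
            "config": self.config,
            "config_hash": self.config_hash,
            "provenance": self.provenance,
            "tasks": [t.to_dict() for t in sorted(self.tasks, key=lambda t: t.task_id)],
            "degradation_log": list(self.degradation_log),
            "lot_comparison": self.lot_comparison,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"


def prepare_lots(
    bundle: CohortBundle, config: AssessmentConfig, notes: Optional[List[str]] = None
) -> List[LotRecord]:
    """The LOT table quality checks run against.

    Vendor-provided LOTs are preferred when present (sparse tables get end
    dates and regimen names imputed); otherwise lines are derived from SACT
    events patient by patient.
    """
    notes = notes if notes is not None else []
    if bundle.provided_lots is not None:
        provided = bundle.provided_lots
        if any(l.end_date is None for l in provided):
            sparse = [l for l in provided if l.end_date is None]
            full = [l for l in provided if l.end_date is not None]
            imputed = impute_sparse_lots(sparse, bundle.drug_events, config.data_cutoff_date)
            notes.append(f"{len(sparse)} sparse LOT records had end dates imputed")
            return sorted(full + imputed, key=lambda l: (l.patient_id, l.line_number))
        return list(provided)
    lots: List[LotRecord] = []
    skipped_pre_index = 0
    by_pid: Dict[str, List] = {}
    for e in bundle.drug_events:
        by_pid.setdefault(e.patient_id, []).append(e)
    for p in sorted(bundle.patients, key=lambda p: p.patient_id):
        if not p.index_date.is_day():
            continue
        idx = p.index_date.as_date()
        events = by_pid.get(p.patient_id, [])
        usable = [e for e in events if not e.event_date.is_day() or e.event_date.as_date() >= idx]
        skipped_pre_index += len(events) - len(usable)
        lots.extend(derive_lots(usable, idx, config))
    if skipped_pre_index:
        notes.append(f"{skipped_pre_index} SACT events before the index date excluded from derivation")
    return lots


def build_episodes(
    bundle: CohortBundle,
    lots: Sequence[LotRecord],
    config: AssessmentConfig,
) -> Tuple[List[TargetEpisode], List[RwttdResult]]:
    """Classify target episodes and evaluate the rwTTD end point for each."""
    lots_by_pid: Dict[str, List[LotRecord]] = {}
    for lot in lots:
        lots_by_pid.setdefault(lot.patient_id, []).append(lot)
    target_by_pid: Dict[str, List] = {}
    for e in bundle.drug_events:
        if e.is_target:
            target_by_pid.setdefault(e.patient_id, []).append(e)
    last_activity: Dict[str, dt.date] = {}
    for a in bundle.activities:
        if a.event_date.is_day():
            d = a.event_date.as_date()
            if a.patient_id not in last_activity or d > last_activity[a.patient_id]:
                last_activity[a.patient_id] = d

    episodes: List[TargetEpisode] = []
    results: List[RwttdResult] = []
    for p in sorted(bundle.patients, key=lambda p: p.patient_id):
        tevents = target_by_pid.get(p.patient_id)
        if not tevents:
            continue
        plots = lots_by_pid.get(p.patient_id, [])
        eps = classify_target_episodes(plots, tevents, config)
        for ep in eps:
            if config.target_route == "oral":
                lo, hi = ep.first_dose, ep.last_dose
                ep_events = [
                    e
                    for e in tevents
                    if e.event_date.is_day() and lo <= e.event_date.as_date() <= hi
                ]
            else:
                ep_events = None
            results.append(
                discontinuation_status(
                    ep,
                    plots,
                    p.death_date,
                    last_activity.get(p.patient_id),
                    config,
                    target_events=ep_events,
                )
            )
        episodes.extend(eps)
    return episodes, results


def run_assessment(
    bundle: CohortBundle,
    config: AssessmentConfig,
    ingredient_map=None,
    do_restrict: bool = False,
) -> QCReport:
    """Run the full 20-task assessment; deterministic for a given input.

    Pipeline: (optional) drug harmonization -> (optional) advanced-cohort
    restriction -> LOT preparation (provided/imputed/derived) -> target
    episode classification -> the four check groups.  The report always
    contains all 20 task ids with applicability flags.
    """
    if ingredient_map is not None:
        bundle = harmonize_drugs(bundle, ingredient_map, config)
    else:
        for e in bundle.drug_events:
            e.is_target = e.is_sact and config.is_target_event(e)
    if do_restrict:
        bundle = restrict_to_advanced(bundle)

    notes: List[str] = []
    lots = prepare_lots(bundle, config, notes)
    episodes, _results = build_episodes(bundle, lots, config)

    tasks: List[TaskResult] = []
    tasks += check_sact(bundle, lots, config, notes)
    tasks += check_lot(bundle, lots, episodes, config, notes)
    tasks += check_mortality(bundle, config, notes)
    tasks += check_followup(bundle, episodes, config, notes)
    tasks.sort(key=lambda t: t.task_id)

    lot_comparison = None
    if bundle.provided_lots is not None:
        derived = prepare_lots(
            CohortBundle(
                patients=bundle.patients,
                drug_events=bundle.drug_events,
                activities=[],
                provided_lots=None,
            ),
            config,
        )
        cmp = compare_lots(lots, derived)
        lot_comparison = {
            "patients_compared": cmp.patients_compared,
            "patients_agreeing": cmp.patients_agreeing,
            "agreement_fraction": (
                None if cmp.agreement_fraction is None else round(cmp.agreement_fraction, 4)
            ),
        }

    provenance = {
        k: v for k, v in bundle.provenance.items() if k not in ("loaded_at",)
    }
    return QCReport(
        config=config.to_dict(),
        config_hash=config.hash(),
        provenance=provenance,
        tasks=tasks,
        degradation_log=notes,
        lot_comparison=lot_comparison,
    )
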