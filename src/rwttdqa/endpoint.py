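"""Real-world time to treatment discontinuation (rwTTD) per target episode.

rwTTD is the inclusive day count from the first to the last recorded dose:
``(last - first) + 1``, so a single same-day exposure is 1 day.  The episode
ends in a discontinuation *event* when the patient died during therapy,
initiated a new treatment, or shows a gap of at least ``gap_threshold_days``
(default 120) between the last recorded dose and the last recorded activity;
otherwise the episode is censored at the last medication use.  The
discontinuation date for every event reason is the last exposure date; the
reason label follows the priority death > new treatment > activity gap when
several rules hold at once.

"Died during therapy" is operationalized as a day-precise death date no later
than ``gap_threshold_days`` after the last exposure.  A death date coarser
than day precision cannot support day arithmetic: the death branch is skipped
and the skip is logged, mirroring how mortality checks are omitted when only
the year of death is available.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .dates import PartialDate
from .model import AssessmentConfig, DrugEvent, LotRecord, TargetEpisode

logger = logging.getLogger(__name__)

REASONS = ("death_on_therapy", "new_treatment", "activity_gap", "censored")


@dataclass
class RwttdResult:
    """The rwTTD outcome for one target-drug episode."""

    patient_id: str
    line_number: Optional[int]
    line_group: str
    therapy: str
    first_dose_date: dt.date
    last_exposure_date: dt.date
    discontinuation_date: Optional[dt.date]
    event: bool
    reason: str
    rwttd_days: int
    degraded_oral_records: int = 0

    def to_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "line_number": "" if self.line_number is None else self.line_number,
            "line_group": self.line_group,
            "therapy": self.therapy,
            "first_dose_date": self.first_dose_date.isoformat(),
            "last_exposure_date": self.last_exposure_date.isoformat(),
            "discontinuation_date": (
                "" if self.discontinuation_date is None else self.discontinuation_date.isoformat()
            ),
            "event": str(self.event).lower(),
            "reason": self.reason,
            "rwttd_days": self.rwttd_days,
        }


def last_exposure_date(
    target_events: Iterable[DrugEvent],
    route: str,
    config: AssessmentConfig,
) -> Tuple[dt.date, int]:
    """Last covered exposure day for the target drug.

    Intravenous targets: the latest administration date.  Oral targets: the
    latest projected supply-end over orders, ``order_date + days_supply *
    (1 + refills) - 1`` when the supply fields are present; an order missing
    them contributes its order date and is counted as degraded (the count
    feeds the supply/refill completeness check).

    Returns ``(date, n_degraded)``.  Raises ``ValueError`` when no usable
    (non-canceled, day-precision) event exists.
    """
    usable = [
        e
        for e in target_events
        if not e.canceled and e.event_date.is_day()
    ]
    if not usable:
        raise ValueError("no exposure: all target events canceled or undated")
    degraded = 0
    if route == "intravenous":
        last = max(e.event_date.as_date() for e in usable)
    else:
        ends: List[dt.date] = []
        for e in usable:
            start = e.event_date.as_date()
            if e.days_supply is not None:
                covered = e.days_supply * (1 + (e.refills or 0))
                ends.append(start + dt.timedelta(days=covered - 1))
            else:
                degraded += 1
                ends.append(start)
        last = max(ends)
        if degraded:
            logger.info("last_exposure_date: %d oral orders lacked supply fields", degraded)
    return last, degraded


def compute_rwttd(first_dose: dt.date, last_exposure: dt.date) -> int:
    """Inclusive day count from initiation to last exposure: (last-first)+1."""
    if first_dose > last_exposure:
        raise ValueError("first dose after last exposure")
    return (last_exposure - first_dose).days + 1


def discontinuation_status(
    episode: TargetEpisode,
    lots: Sequence[LotRecord],
    death_date: Optional[PartialDate],
    last_activity_date: Optional[dt.date],
    config: AssessmentConfig,
    route: Optional[str] = None,
    target_events: Optional[Sequence[DrugEvent]] = None,
) -> RwttdResult:
    """Evaluate the discontinuation rules for one target episode.

    Branches, in priority order:

    1. death on therapy — a day-precise death date within
       ``gap_threshold_days`` after the last exposure;
    2. new treatment — a LOT with a higher line number starting after the
       last exposure;
    3. activity gap — ``last_activity - last_exposure >=
       gap_threshold_days`` (exclusive day difference);
    4. otherwise censored at the last exposure.
    """
    route = route or config.target_route
    gap = config.gap_threshold_days
    first = episode.first_dose
    if target_events is not None:
        last, degraded = last_exposure_date(target_events, route, config)
    else:
        last, degraded = episode.last_dose, 0

    reason = "censored"
    if death_date is not None:
        if not death_date.is_day():
            logger.info(
                "discontinuation_status: %s death date at %s precision; death branch skipped",
                episode.patient_id,
                death_date.precision,
            )
        elif (death_date.as_date() - last).days <= gap:
            reason = "death_on_therapy"
    if reason == "censored" and episode.line_number is not None:
        for lot in lots:
            if (
                lot.patient_id == episode.patient_id
                and lot.line_number > episode.line_number
                and lot.start_date.is_day()
                and lot.start_date.as_date() > last
            ):
                reason = "new_treatment"
                break
    if reason == "censored" and last_activity_date is not None:
        if (last_activity_date - last).days >= gap:
            reason = "activity_gap"

    event = reason != "censored"
    return RwttdResult(
        patient_id=episode.patient_id,
        line_number=episode.line_number,
        line_group=episode.line_group,
        therapy=episode.therapy,
        first_dose_date=first,
        last_exposure_date=last,
        discontinuation_date=last if event else None,
        event=event,
        reason=reason,
        rwttd_days=compute_rwttd(first, last),
        degraded_oral_records=degraded,
    )


def km_summary(results: Sequence[RwttdResult]) -> Tuple[pd.DataFrame, Optional[float]]:
    """Product-limit survival summary of rwTTD with right censoring.

    Returns ``(table, median)`` where the table has one row per distinct
    event/censor time (time, at_risk, events, censored, survival) and the
    median is the smallest time with survival <= 0.5, or ``None`` when never
    reached.
    """
    if not results:
        raise ValueError("km_summary requires at least one result")
    durations = [r.rwttd_days for r in results]
    observed = [r.event for r in results]
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    table = kmf.event_table.reset_index().rename(
        columns={"event_at": "time", "at_risk": "at_risk", "observed": "events"}
    )
    surv = kmf.survival_function_["KM_estimate"]
    table = table[table["time"] > 0].copy()
    table["survival"] = [float(surv.loc[t]) for t in table["time"]]
    table = table[["time", "at_risk", "events", "censored", "survival"]]
    median = kmf.median_survival_time_
    if not np.isfinite(median):
        logger.info("km_summary: median rwTTD not reached (survival stays above 0.5)")
        median = None
    else:
        median = float(median)
    return table, median
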