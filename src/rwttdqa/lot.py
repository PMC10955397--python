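"""Line-of-therapy (LOT) derivation from systemic anticancer therapy events.

The first line begins at the first SACT event on or after the index date.
Two rules govern line boundaries:

* combination window — any drug whose first appearance falls within the
  combination window (day offsets 0..window-1 from the line start) joins the
  current line's regimen; a drug outside the current regimen first appearing
  at offset >= window starts a new line;
* therapy gap — any SACT event occurring after a gap >= the gap threshold
  (default 120 days) since the previous SACT event starts a new line, even
  when the drug is unchanged.

Events are processed in (date, drug) order, so the derivation is invariant to
input ordering.  The regimen name is the sorted distinct ingredient set joined
by "+"; the line end date is the last event date assigned to the line.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .dates import PartialDate
from .model import (
    AssessmentConfig,
    DrugEvent,
    LotRecord,
    TargetEpisode,
    canonical_regimen,
)

logger = logging.getLogger(__name__)


def _day_events(events: Iterable[DrugEvent]) -> Tuple[List[Tuple[dt.date, str]], int]:
    """Usable (date, drug) pairs plus the count of skipped events.

    Skipped: canceled orders, non-SACT records, events without a resolvable
    drug identity, and events whose date is coarser than day precision.
    """
    pairs: List[Tuple[dt.date, str]] = []
    skipped = 0
    for e in events:
        if e.canceled or not e.is_sact:
            continue
        drug = e.identity()
        if drug is None:
            skipped += 1
            continue
        if not e.event_date.is_day():
            skipped += 1
            continue
        pairs.append((e.event_date.as_date(), drug))
    pairs.sort()
    return pairs, skipped


def derive_lots(
    events: Iterable[DrugEvent],
    index_date: dt.date,
    config: AssessmentConfig,
) -> List[LotRecord]:
    """Derive the LOT sequence for one patient from their SACT events.

    Events must fall on/after ``index_date``; earlier events are the caller's
    responsibility to filter and raise ``ValueError`` here.  Non-day-precision
    events are skipped with a logged count.
    """
    events = list(events)
    pairs, skipped = _day_events(events)
    if skipped:
        logger.info("derive_lots: %d events skipped (coarse date or missing identity)", skipped)
    if pairs and pairs[0][0] < index_date:
        raise ValueError(
            f"SACT event on {pairs[0][0].isoformat()} precedes index date {index_date.isoformat()}"
        )
    window = config.combination_window_days
    gap = config.gap_threshold_days

    lots: List[LotRecord] = []
    cur_start: Optional[dt.date] = None
    cur_last: Optional[dt.date] = None
    cur_drugs: Set[str] = set()
    patient_id = next((e.patient_id for e in events if e.patient_id), "")

    def _close() -> None:
        lots.append(
            LotRecord(
                patient_id=patient_id,
                line_number=len(lots) + 1,
                regimen_name=canonical_regimen(cur_drugs),
                start_date=PartialDate.from_date(cur_start),
                end_date=PartialDate.from_date(cur_last),
                provenance="derived",
            )
        )

    for date, drug in pairs:
        if cur_start is None:
            cur_start, cur_last, cur_drugs = date, date, {drug}
            continue
        if (date - cur_last).days >= gap:
            _close()
            cur_start, cur_last, cur_drugs = date, date, {drug}
            continue
        if drug in cur_drugs:
            cur_last = date
            continue
        if (date - cur_start).days < window:
            cur_drugs.add(drug)
            cur_last = date
            continue
        _close()
        cur_start, cur_last, cur_drugs = date, date, {drug}
    if cur_start is not None:
        _close()
    return lots


def impute_sparse_lots(
    provided_lots: Sequence[LotRecord],
    sact_events: Iterable[DrugEvent],
    cutoff: dt.date,
) -> List[LotRecord]:
    """Fill end dates and regimen names for a sparse (number+start) LOT table.

    The end date of line k is the day before line k+1 starts; the last line
    ends at the data cutoff.  The regimen name is the sorted distinct SACT
    ingredient set administered or ordered within [start, end].  Two lines
    sharing a start date are a plausibility finding, not an error: ties break
    by line number and are logged.
    """
    by_patient: Dict[str, List[LotRecord]] = {}
    for lot in provided_lots:
        by_patient.setdefault(lot.patient_id, []).append(lot)
    events_by_patient: Dict[str, List[Tuple[dt.date, str]]] = {}
    for e in sact_events:
        if e.canceled or not e.is_sact or not e.event_date.is_day():
            continue
        drug = e.identity()
        if drug is None:
            continue
        events_by_patient.setdefault(e.patient_id, []).append((e.event_date.as_date(), drug))

    out: List[LotRecord] = []
    for pid, lots in by_patient.items():
        usable = [l for l in lots if l.start_date.is_day()]
        usable.sort(key=lambda l: (l.start_date.as_date(), l.line_number))
        starts = [l.start_date.as_date() for l in usable]
        if len(set(starts)) != len(starts):
            logger.warning("impute_sparse_lots: patient %s has lines sharing a start date", pid)
        for i, lot in enumerate(usable):
            start = starts[i]
            end = starts[i + 1] - dt.timedelta(days=1) if i + 1 < len(usable) else cutoff
            if end < start:  # same-day successor line
                end = start
            drugs = {d for (date, d) in events_by_patient.get(pid, []) if start <= date <= end}
            out.append(
                LotRecord(
                    patient_id=pid,
                    line_number=lot.line_number,
                    regimen_name=canonical_regimen(drugs),
                    start_date=lot.start_date,
                    end_date=PartialDate.from_date(end),
                    maintenance_flag=lot.maintenance_flag,
                    provenance="imputed_end",
                )
            )
    out.sort(key=lambda l: (l.patient_id, l.line_number))
    return out


@dataclass
class LotComparison:
    """Agreement between provided and event-derived LOT tables (diagnostic)."""

    patients_compared: int = 0
    patients_agreeing: int = 0
    notes: List[str] = field(default_factory=list)

    @property
    def agreement_fraction(self) -> Optional[float]:
        if self.patients_compared == 0:
            return None
        return self.patients_agreeing / self.patients_compared


def compare_lots(provided: Sequence[LotRecord], derived: Sequence[LotRecord]) -> LotComparison:
    """Count patients whose provided and derived LOT tables match exactly.

    Match = same line count and, line by line, same number, regimen, start
    and end date.  Emitted as a bonus diagnostic when a vendor LOT table is
    available alongside raw drug events.
    """

    def _key(lots: Sequence[LotRecord]):
        table: Dict[str, List[Tuple]] = {}
        for l in sorted(lots, key=lambda x: (x.patient_id, x.line_number)):
            table.setdefault(l.patient_id, []).append(
                (
                    l.line_number,
                    l.regimen_name,
                    l.start_date.isoformat(),
                    l.end_date.isoformat() if l.end_date else None,
                )
            )
        return table

    ptab, dtab = _key(provided), _key(derived)
    cmp = LotComparison()
    for pid in sorted(set(ptab) | set(dtab)):
        cmp.patients_compared += 1
        if ptab.get(pid) == dtab.get(pid):
            cmp.patients_agreeing += 1
    return cmp


def classify_target_episodes(
    lots: Sequence[LotRecord],
    target_events: Sequence[DrugEvent],
    config: AssessmentConfig,
) -> List[TargetEpisode]:
    """Group target-drug events into per-LOT initiation episodes.

    Each LOT whose [start, end] window contains at least one target event
    yields one episode, classified mono (regimen is the target alone) or
    combo, with combos flagged approved when the regimen matches the
    configured approved-combination set.  Target events falling inside no LOT
    window are a plausibility finding and yield a single episode with line
    group "unknown".
    """
    dates = sorted(
        e.event_date.as_date()
        for e in target_events
        if not e.canceled and e.event_date.is_day()
    )
    if not dates:
        return []
    day_lots = [l for l in lots if l.start_date.is_day() and l.end_date is not None and l.end_date.is_day()]
    day_lots.sort(key=lambda l: (l.start_date.as_date(), l.line_number))

    assigned: Dict[int, List[dt.date]] = {}
    orphans: List[dt.date] = []
    for d in dates:
        home = next(
            (i for i, l in enumerate(day_lots) if l.start_date.as_date() <= d <= l.end_date.as_date()),
            None,
        )
        if home is None:
            orphans.append(d)
        else:
            assigned.setdefault(home, []).append(d)

    episodes: List[TargetEpisode] = []
    target = config.target_name
    approved = {canonical_regimen(c.split("+")) for c in config.approved_combinations}
    for i in sorted(assigned):
        lot = day_lots[i]
        regimen = lot.regimen()
        mono = regimen == {target} or lot.regimen_name == target
        episodes.append(
            TargetEpisode(
                patient_id=lot.patient_id,
                line_number=lot.line_number,
                line_group="1L" if lot.line_number == 1 else "2L+",
                therapy="mono" if mono else "combo",
                approved_combo=(not mono) and canonical_regimen(regimen) in approved,
                lot=lot,
                target_dates=assigned[i],
            )
        )
    if orphans:
        pid = target_events[0].patient_id
        logger.warning(
            "classify_target_episodes: %d target events outside any LOT window for %s",
            len(orphans),
            pid,
        )
        episodes.append(
            TargetEpisode(
                patient_id=pid,
                line_number=None,
                line_group="unknown",
                therapy="unknown",
                approved_combo=False,
                lot=None,
                target_dates=orphans,
                finding=f"{len(orphans)} target events outside every LOT window",
            )
        )
    episodes.sort(key=lambda e: e.first_dose)
    return episodes
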