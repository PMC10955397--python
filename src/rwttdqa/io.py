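"""CSV readers and writers for the four cohort tables.

Tables are RFC-4180 CSVs with a header row, dates ISO-8601 with truncation
allowed ("2017", "2017-03", "2017-03-05").  LOT tables come in two dialects:
``full`` (patient_id, line_number, line_name, start_date, end_date,
maintenance) and ``sparse`` (patient_id, line_number, start_date only), which
mirrors how commercial vendors deliver the data.  Column names can be remapped
per table via ``column_maps``.

Loading is forgiving about value-level problems (a malformed date is kept at
the coarsest parseable precision, and the coarsening is logged) but strict
about structure: a missing mandatory column raises :class:`SchemaError` naming
table and column, and an event row citing an unknown patient raises
:class:`IntegrityError`.
"""

from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd

from .dates import PartialDate
from .model import (
    ACTIVITY_CATEGORIES,
    ActivityEvent,
    CohortBundle,
    DrugEvent,
    LotRecord,
    PatientRecord,
    SchemaError,
    SEXES,
    STAGES,
)

logger = logging.getLogger(__name__)

PATIENT_REQUIRED = ("patient_id", "index_date")
PATIENT_OPTIONAL = (
    "sex",
    "age_at_index",
    "race",
    "ajcc_stage",
    "diagnosis_codes",
    "death_date",
    "extra_death_dates",
)
DRUG_REQUIRED = ("patient_id", "event_date", "route_kind")
DRUG_OPTIONAL = (
    "drug_name",
    "code_system",
    "drug_code",
    "days_supply",
    "refills",
    "canceled",
    "is_sact",
    "is_target",
)
ACTIVITY_REQUIRED = ("patient_id", "category", "event_date")
LOT_FULL = ("patient_id", "line_number", "line_name", "start_date", "end_date")
LOT_SPARSE = ("patient_id", "line_number", "start_date")


def _read_table(path: Path, table: str, log: List[str]) -> pd.DataFrame:
    if not Path(path).exists():
        raise SchemaError(f"{table}: file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    before = len(df)
    df = df.drop_duplicates()
    dropped = before - len(df)
    if dropped:
        log.append(f"{table}: {dropped} exact-duplicate rows dropped at load")
        logger.info("%s: dropped %d duplicate rows", table, dropped)
    return df


def _require(df: pd.DataFrame, table: str, columns, column_map: Mapping[str, str]) -> None:
    for canonical in columns:
        actual = column_map.get(canonical, canonical)
        if actual not in df.columns:
            raise SchemaError(f"table {table!r} is missing mandatory column {actual!r}")


def _get(row, column_map: Mapping[str, str], canonical: str) -> str:
    return str(row.get(column_map.get(canonical, canonical), "") or "").strip()


def _parse_date(
    raw: str, table: str, column: str, log: List[str]
) -> Optional[PartialDate]:
    if not raw:
        return None
    parsed, coarsened = PartialDate.parse_lenient(raw)
    if parsed is None:
        log.append(f"{table}.{column}: unparseable date {raw!r} treated as missing")
        return None
    if coarsened or parsed.precision != "day":
        log.append(
            f"{table}.{column}: date {raw!r} kept at {parsed.precision} precision"
        )
    return parsed


def _parse_int(raw: str) -> Optional[int]:
    if raw == "":
        return None
    return int(float(raw))


def _parse_bool(raw: str) -> bool:
    return raw.strip().lower() in ("1", "true", "t", "yes", "y")


def _parse_codes(raw: str) -> List[Tuple[str, str]]:
    out = []
    for chunk in raw.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if ":" not in chunk:
            raise SchemaError(f"diagnosis code {chunk!r} is not SYSTEM:CODE formatted")
        system, code = chunk.split(":", 1)
        out.append((system.strip(), code.strip()))
    return out


def load_cohort(
    table_paths: Mapping[str, str | Path],
    column_maps: Optional[Mapping[str, Mapping[str, str]]] = None,
    lot_dialect: Optional[str] = None,
) -> CohortBundle:
    """Load the cohort tables into a typed, integrity-checked bundle.

    ``table_paths`` maps ``patients``, ``drug_events``, ``activities`` and
    optionally ``lots`` to CSV paths.  ``lot_dialect`` is ``"full"``,
    ``"sparse"``, or ``None`` to auto-detect from the columns present.
    """
    column_maps = column_maps or {}
    log: List[str] = []

    # patients -------------------------------------------------------------
    cmap = column_maps.get("patients", {})
    pdf = _read_table(Path(table_paths["patients"]), "patients", log)
    _require(pdf, "patients", PATIENT_REQUIRED, cmap)
    patients: List[PatientRecord] = []
    for row in pdf.to_dict("records"):
        pid = _get(row, cmap, "patient_id")
        index_date = _parse_date(_get(row, cmap, "index_date"), "patients", "index_date", log)
        if index_date is None:
            raise SchemaError(f"patients: patient {pid!r} has no parseable index_date")
        sex = _get(row, cmap, "sex") or "unknown"
        stage = _get(row, cmap, "ajcc_stage") or "unknown"
        if sex not in SEXES:
            raise SchemaError(f"patients: patient {pid!r} has invalid sex {sex!r}")
        if stage not in STAGES:
            raise SchemaError(f"patients: patient {pid!r} has invalid ajcc_stage {stage!r}")
        extra = [
            d
            for d in (
                _parse_date(x, "patients", "extra_death_dates", log)
                for x in _get(row, cmap, "extra_death_dates").split(";")
                if x.strip()
            )
            if d is not None
        ]
        patients.append(
            PatientRecord(
                patient_id=pid,
                index_date=index_date,
                sex=sex,
                age_at_index=_parse_int(_get(row, cmap, "age_at_index")),
                race=_get(row, cmap, "race") or None,
                ajcc_stage=stage,
                diagnosis_codes=_parse_codes(_get(row, cmap, "diagnosis_codes")),
                death_date=_parse_date(_get(row, cmap, "death_date"), "patients", "death_date", log),
                extra_death_dates=extra,
            )
        )

    # drug events ------------------------------------------------------------
    cmap = column_maps.get("drug_events", {})
    ddf = _read_table(Path(table_paths["drug_events"]), "drug_events", log)
    _require(ddf, "drug_events", DRUG_REQUIRED, cmap)
    drug_events: List[DrugEvent] = []
    for row in ddf.to_dict("records"):
        date = _parse_date(_get(row, cmap, "event_date"), "drug_events", "event_date", log)
        if date is None:
            log.append("drug_events: row without parseable event_date skipped")
            continue
        route = _get(row, cmap, "route_kind")
        if route not in ("administered", "ordered"):
            raise SchemaError(f"drug_events: invalid route_kind {route!r}")
        days_supply = _parse_int(_get(row, cmap, "days_supply"))
        refills = _parse_int(_get(row, cmap, "refills"))
        if route == "administered" and (days_supply is not None or refills is not None):
            raise SchemaError("drug_events: administered events must not carry days_supply/refills")
        drug_events.append(
            DrugEvent(
                patient_id=_get(row, cmap, "patient_id"),
                event_date=date,
                route_kind=route,
                drug_name=_get(row, cmap, "drug_name") or None,
                code_system=_get(row, cmap, "code_system") or None,
                drug_code=_get(row, cmap, "drug_code") or None,
                days_supply=days_supply,
                refills=refills,
                canceled=_parse_bool(_get(row, cmap, "canceled")),
                is_sact=_parse_bool(_get(row, cmap, "is_sact")),
                is_target=_parse_bool(_get(row, cmap, "is_target")),
            )
        )

    # activities -----------------------------------------------------------
    cmap = column_maps.get("activities", {})
    adf = _read_table(Path(table_paths["activities"]), "activities", log)
    _require(adf, "activities", ACTIVITY_REQUIRED, cmap)
    activities: List[ActivityEvent] = []
    for row in adf.to_dict("records"):
        category = _get(row, cmap, "category")
        if category not in ACTIVITY_CATEGORIES:
            raise SchemaError(f"activities: unknown category {category!r}")
        date = _parse_date(_get(row, cmap, "event_date"), "activities", "event_date", log)
        if date is None:
            log.append("activities: row without parseable event_date skipped")
            continue
        activities.append(
            ActivityEvent(patient_id=_get(row, cmap, "patient_id"), category=category, event_date=date)
        )

    # provided LOTs ----------------------------------------------------------
    provided_lots: Optional[List[LotRecord]] = None
    if table_paths.get("lots"):
        cmap = column_maps.get("lots", {})
        ldf = _read_table(Path(table_paths["lots"]), "lots", log)
        dialect = lot_dialect
        if dialect is None:
            dialect = "full" if cmap.get("end_date", "end_date") in ldf.columns else "sparse"
        required = LOT_FULL if dialect == "full" else LOT_SPARSE
        _require(ldf, "lots", required, cmap)
        provided_lots = []
        for row in ldf.to_dict("records"):
            start = _parse_date(_get(row, cmap, "start_date"), "lots", "start_date", log)
            if start is None:
                log.append("lots: row without parseable start_date skipped")
                continue
            end = None
            name = ""
            maintenance = None
            if dialect == "full":
                end = _parse_date(_get(row, cmap, "end_date"), "lots", "end_date", log)
                name = _get(row, cmap, "line_name")
                raw_maint = _get(row, cmap, "maintenance")
                maintenance = _parse_bool(raw_maint) if raw_maint else None
            provided_lots.append(
                LotRecord(
                    patient_id=_get(row, cmap, "patient_id"),
                    line_number=int(_get(row, cmap, "line_number")),
                    regimen_name=name,
                    start_date=start,
                    end_date=end,
                    maintenance_flag=maintenance,
                    provenance="provided",
                )
            )

    bundle = CohortBundle(
        patients=patients,
        drug_events=drug_events,
        activities=activities,
        provided_lots=provided_lots,
        provenance={
            "sources": {k: str(v) for k, v in table_paths.items() if v},
            "load_log": log,
            "loaded_at": dt.datetime.now().isoformat(timespec="seconds"),
        },
    )
    bundle.check_integrity()
    return bundle


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> Dict[str, Path]:
    """Re-export the bundle in the same CSV schemas ``load_cohort`` reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    def _iso(d) -> str:
        return "" if d is None else d.isoformat()

    rows = [
        {
            "patient_id": p.patient_id,
            "index_date": _iso(p.index_date),
            "sex": p.sex,
            "age_at_index": "" if p.age_at_index is None else p.age_at_index,
            "race": p.race or "",
            "ajcc_stage": p.ajcc_stage,
            "diagnosis_codes": ";".join(f"{s}:{c}" for s, c in p.diagnosis_codes),
            "death_date": _iso(p.death_date),
            "extra_death_dates": ";".join(d.isoformat() for d in p.extra_death_dates),
        }
        for p in bundle.patients
    ]
    paths["patients"] = out / "patients.csv"
    pd.DataFrame(rows, columns=PATIENT_REQUIRED + PATIENT_OPTIONAL).to_csv(paths["patients"], index=False)

    rows = [
        {
            "patient_id": e.patient_id,
            "event_date": _iso(e.event_date),
            "route_kind": e.route_kind,
            "drug_name": e.drug_name or "",
            "code_system": e.code_system or "",
            "drug_code": e.drug_code or "",
            "days_supply": "" if e.days_supply is None else e.days_supply,
            "refills": "" if e.refills is None else e.refills,
            "canceled": str(e.canceled).lower(),
            "is_sact": str(e.is_sact).lower(),
            "is_target": str(e.is_target).lower(),
        }
        for e in bundle.drug_events
    ]
    paths["drug_events"] = out / "drug_events.csv"
    pd.DataFrame(rows, columns=DRUG_REQUIRED + DRUG_OPTIONAL).to_csv(paths["drug_events"], index=False)

    rows = [
        {"patient_id": a.patient_id, "category": a.category, "event_date": _iso(a.event_date)}
        for a in bundle.activities
    ]
    paths["activities"] = out / "activities.csv"
    pd.DataFrame(rows, columns=ACTIVITY_REQUIRED).to_csv(paths["activities"], index=False)

    if bundle.provided_lots is not None:
        rows = [
            {
                "patient_id": l.patient_id,
                "line_number": l.line_number,
                "line_name": l.regimen_name,
                "start_date": _iso(l.start_date),
                "end_date": _iso(l.end_date),
                "maintenance": "" if l.maintenance_flag is None else str(l.maintenance_flag).lower(),
            }
            for l in bundle.provided_lots
        ]
        paths["lots"] = out / "lots.csv"
        pd.DataFrame(rows, columns=LOT_FULL + ("maintenance",)).to_csv(paths["lots"], index=False)

    return paths
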