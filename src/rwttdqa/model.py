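"""Canonical in-memory data model for the rwTTD quality-assessment pipeline.

Four tables describe an EHR-derived oncology cohort: patients (with the
advanced-diagnosis index date and vital status), drug events (systemic
anticancer therapy administrations and orders), optionally vendor-provided
lines of therapy, and longitudinal activity events that proxy follow-up.
The assessment configuration carries the target drug, the study window and
every rule constant (combination window, discontinuation gap, post-death
tiers, early-receipt percentiles) so a run is a pure function of
(cohort, config).
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import yaml

from .dates import PartialDate

logger = logging.getLogger(__name__)

SEXES = ("female", "male", "unknown")
STAGES = ("0", "I", "II", "III", "IV", "unknown")
ROUTE_KINDS = ("administered", "ordered")
ACTIVITY_CATEGORIES = (
    "diagnosis",
    "drug",
    "laboratory",
    "facility_visit",
    "vital_sign",
    "procedure",
    "genomic_test",
    "biomarker_test",
    "ecog",
)
CODE_SYSTEMS = ("NDC", "HCPCS", "RxNorm", "ICD-9", "ICD-10")


class SchemaError(ValueError):
    """A table does not conform to the expected schema."""


class IntegrityError(ValueError):
    """Cross-table referential integrity is violated."""


class ConfigError(ValueError):
    """The assessment configuration is invalid."""


def normalize_code(code: str) -> str:
    """Uppercase and strip the dot: ``"C77.0" -> "C770"``.

    ICD dot placement varies across EHR exports, so prefix matching is done
    on the dotless form.
    """
    return code.strip().upper().replace(".", "")


@dataclass
class PatientRecord:
    patient_id: str
    index_date: PartialDate
    sex: str = "unknown"
    age_at_index: Optional[int] = None
    race: Optional[str] = None
    ajcc_stage: str = "unknown"
    diagnosis_codes: List[Tuple[str, str]] = field(default_factory=list)
    death_date: Optional[PartialDate] = None
    extra_death_dates: List[PartialDate] = field(default_factory=list)

    def has_conflicting_death_dates(self) -> bool:
        """True when a second death record disagrees at shared precision."""
        if self.death_date is None:
            return False
        return any(d.compare(self.death_date) != 0 for d in self.extra_death_dates)


@dataclass
class DrugEvent:
    patient_id: str
    event_date: PartialDate
    route_kind: str
    drug_name: Optional[str] = None
    code_system: Optional[str] = None
    drug_code: Optional[str] = None
    days_supply: Optional[int] = None
    refills: Optional[int] = None
    canceled: bool = False
    is_sact: bool = False
    is_target: bool = False

    @property
    def missing_identity(self) -> bool:
        """No drug name and no drug code: the record cannot be classified."""
        return not self.drug_name and not self.drug_code

    def identity(self) -> Optional[str]:
        if self.drug_name:
            return self.drug_name
        if self.drug_code:
            return f"{self.code_system or '?'}:{self.drug_code}"
        return None


@dataclass
class ActivityEvent:
    patient_id: str
    category: str
    event_date: PartialDate


@dataclass
class LotRecord:
    """One line of therapy (LOT) for one patient.

    ``regimen_name`` is canonical: sorted distinct ingredient names joined by
    ``"+"``.  ``provenance`` records whether the line came from the source
    data, was derived from drug events, or had its end date imputed.
    """

    patient_id: str
    line_number: int
    regimen_name: str
    start_date: PartialDate
    end_date: Optional[PartialDate] = None
    maintenance_flag: Optional[bool] = None
    provenance: str = "provided"

    def regimen(self) -> Set[str]:
        return {p for p in self.regimen_name.split("+") if p}


def canonical_regimen(ingredients: Iterable[str]) -> str:
    return "+".join(sorted(set(ingredients)))


@dataclass
class TargetEpisode:
    """One initiation of the target drug, anchored to a LOT."""

    patient_id: str
    line_number: Optional[int]
    line_group: str  # "1L" | "2L+" | "unknown"
    therapy: str  # "mono" | "combo" | "unknown"
    approved_combo: bool
    lot: Optional[LotRecord]
    target_dates: List[dt.date]  # day-precision target event dates, sorted
    finding: Optional[str] = None

    @property
    def first_dose(self) -> dt.date:
        return self.target_dates[0]

    @property
    def last_dose(self) -> dt.date:
        return self.target_dates[-1]

    @property
    def group_label(self) -> str:
        if self.line_group == "unknown":
            return "unknown"
        return f"{self.line_group} {self.therapy}"


@dataclass
class AssessmentConfig:
    """Target drug, study window and rule constants for one assessment."""

    target_name: str
    target_codes: Tuple[str, ...] = ()  # "SYSTEM:CODE" strings
    target_route: str = "intravenous"
    study_start_date: dt.date = dt.date(2015, 1, 1)
    data_cutoff_date: dt.date = dt.date(2019, 11, 25)
    gap_threshold_days: int = 120
    combination_window_days: int = 28
    approval_dates: Dict[str, dt.date] = field(default_factory=dict)
    approved_combinations: Tuple[str, ...] = ()
    post_death_tiers: Tuple[int, ...] = (1, 3, 7, 30)
    alive_gap_window_days: int = 180
    receipt_percentiles: Tuple[float, ...] = (0.05, 0.10, 0.25)
    visit_categories: Tuple[str, ...] = ("facility_visit",)
    task_dimensions: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.target_name:
            raise ConfigError("target_drug name is required")
        if self.target_route not in ("intravenous", "oral"):
            raise ConfigError(f"target_route must be intravenous|oral, got {self.target_route!r}")
        if self.gap_threshold_days < self.combination_window_days:
            raise ConfigError("gap_threshold_days must be >= combination_window_days")
        tiers = tuple(self.post_death_tiers)
        if any(b <= a for a, b in zip(tiers, tiers[1:])) or any(t <= 0 for t in tiers):
            raise ConfigError("post_death_tiers must be strictly increasing positive integers")
        pcts = tuple(self.receipt_percentiles)
        if any(not 0 < p < 1 for p in pcts) or any(b <= a for a, b in zip(pcts, pcts[1:])):
            raise ConfigError("receipt_percentiles must be strictly increasing in (0,1)")
        if self.data_cutoff_date <= self.study_start_date:
            raise ConfigError("data_cutoff_date must fall after study_start_date")
        for cat in self.visit_categories:
            if cat not in ACTIVITY_CATEGORIES:
                raise ConfigError(f"unknown visit category {cat!r}")
        for key in self.approval_dates:
            if key not in ("first_line_mono", "second_line_plus", "first_line_combo"):
                raise ConfigError(f"unknown approval_dates key {key!r}")

    # -- (de)serialization -------------------------------------------------

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AssessmentConfig":
        raw = dict(raw)
        target = raw.pop("target_drug", None)
        if not isinstance(target, Mapping) or "name" not in target:
            raise ConfigError("config must define target_drug with a 'name' key")
        kwargs: Dict = {
            "target_name": target["name"],
            "target_codes": tuple(target.get("codes", ())),
        }

        def _date(value):
            if isinstance(value, dt.date):
                return value
            return PartialDate.parse(str(value)).as_date()

        simple = {
            "target_route": str,
            "gap_threshold_days": int,
            "combination_window_days": int,
            "alive_gap_window_days": int,
        }
        for key, cast in simple.items():
            if key in raw:
                kwargs[key] = cast(raw.pop(key))
        for key in ("study_start_date", "data_cutoff_date"):
            if key in raw:
                kwargs[key] = _date(raw.pop(key))
        if "approval_dates" in raw:
            kwargs["approval_dates"] = {
                k: _date(v) for k, v in (raw.pop("approval_dates") or {}).items() if v is not None
            }
        for key in ("approved_combinations", "visit_categories"):
            if key in raw:
                kwargs[key] = tuple(raw.pop(key))
        if "post_death_tiers" in raw:
            kwargs["post_death_tiers"] = tuple(int(t) for t in raw.pop("post_death_tiers"))
        if "receipt_percentiles" in raw:
            kwargs["receipt_percentiles"] = tuple(float(p) for p in raw.pop("receipt_percentiles"))
        if "task_dimensions" in raw:
            kwargs["task_dimensions"] = {int(k): str(v) for k, v in raw.pop("task_dimensions").items()}
        if raw:
            raise ConfigError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "AssessmentConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(raw, Mapping):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> Dict:
        return {
            "target_drug": {"name": self.target_name, "codes": list(self.target_codes)},
            "target_route": self.target_route,
            "study_start_date": self.study_start_date.isoformat(),
            "data_cutoff_date": self.data_cutoff_date.isoformat(),
            "gap_threshold_days": self.gap_threshold_days,
            "combination_window_days": self.combination_window_days,
            "approval_dates": {k: v.isoformat() for k, v in sorted(self.approval_dates.items())},
            "approved_combinations": list(self.approved_combinations),
            "post_death_tiers": list(self.post_death_tiers),
            "alive_gap_window_days": self.alive_gap_window_days,
            "receipt_percentiles": list(self.receipt_percentiles),
            "visit_categories": list(self.visit_categories),
            "task_dimensions": {str(k): v for k, v in sorted(self.task_dimensions.items())},
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def is_target_event(self, event: DrugEvent) -> bool:
        if event.drug_name and event.drug_name.lower() == self.target_name.lower():
            return True
        if event.drug_code:
            key = f"{event.code_system}:{event.drug_code}"
            return key in self.target_codes
        return False


@dataclass
class CohortBundle:
    """A loaded cohort: all four tables plus provenance metadata."""

    patients: List[PatientRecord]
    drug_events: List[DrugEvent]
    activities: List[ActivityEvent]
    provided_lots: Optional[List[LotRecord]] = None
    provenance: Dict = field(default_factory=dict)

    def patient_ids(self) -> Set[str]:
        return {p.patient_id for p in self.patients}

    def patient_map(self) -> Dict[str, PatientRecord]:
        return {p.patient_id: p for p in self.patients}

    def check_integrity(self) -> None:
        ids = self.patient_ids()
        if len(ids) != len(self.patients):
            seen: Set[str] = set()
            dupes = sorted({p.patient_id for p in self.patients if p.patient_id in seen or seen.add(p.patient_id)})
            raise IntegrityError(f"duplicate patient_id values: {dupes[:20]}")
        orphans = []
        for label, rows in (
            ("drug_events", self.drug_events),
            ("activities", self.activities),
            ("lots", self.provided_lots or []),
        ):
            bad = sorted({r.patient_id for r in rows if r.patient_id not in ids})
            if bad:
                orphans.append(f"{label}: {bad[:20]}")
        if orphans:
            raise IntegrityError("unknown patient_id values in " + "; ".join(orphans))

    def subset(self, keep_ids: Set[str]) -> "CohortBundle":
        return CohortBundle(
            patients=[p for p in self.patients if p.patient_id in keep_ids],
            drug_events=[e for e in self.drug_events if e.patient_id in keep_ids],
            activities=[a for a in self.activities if a.patient_id in keep_ids],
            provided_lots=(
                None
                if self.provided_lots is None
                else [l for l in self.provided_lots if l.patient_id in keep_ids]
            ),
            provenance=dict(self.provenance),
        )

    def copy(self) -> "CohortBundle":
        """Record-level copy; record objects are duplicated, not shared."""
        return CohortBundle(
            patients=[
                replace(p, diagnosis_codes=list(p.diagnosis_codes), extra_death_dates=list(p.extra_death_dates))
                for p in self.patients
            ],
            drug_events=[replace(e) for e in self.drug_events],
            activities=[replace(a) for a in self.activities],
            provided_lots=None if self.provided_lots is None else [replace(l) for l in self.provided_lots],
            provenance=dict(self.provenance),
        )


# -- cohort-level operations ----------------------------------------------

DEFAULT_ICD9_PREFIXES = ("196", "197", "198")
DEFAULT_ICD10_PREFIXES = ("C76", "C77", "C78")


def restrict_to_advanced(
    bundle: CohortBundle,
    stage_rule: Sequence[str] = ("IV",),
    icd9_prefixes: Sequence[str] = DEFAULT_ICD9_PREFIXES,
    icd10_prefixes: Sequence[str] = DEFAULT_ICD10_PREFIXES,
) -> CohortBundle:
    """Keep patients with a qualifying AJCC stage AND a metastasis code.

    Both conditions are required (conjunction).  Event tables are filtered to
    the surviving patients.  An empty result is valid.
    """
    stages = set(stage_rule)
    p9 = tuple(normalize_code(p) for p in icd9_prefixes)
    p10 = tuple(normalize_code(p) for p in icd10_prefixes)
    keep: Set[str] = set()
    for patient in bundle.patients:
        if patient.ajcc_stage not in stages:
            continue
        for system, code in patient.diagnosis_codes:
            norm = normalize_code(code)
            if system == "ICD-9" and norm.startswith(p9):
                keep.add(patient.patient_id)
                break
            if system == "ICD-10" and norm.startswith(p10):
                keep.add(patient.patient_id)
                break
    if not keep:
        logger.warning("restrict_to_advanced: no patients qualify")
    logger.info("restrict_to_advanced: %d of %d patients retained", len(keep), len(bundle.patients))
    return bundle.subset(keep)


def build_ingredient_map(
    rows: Iterable[Tuple[str, str, str, bool]],
) -> Dict[str, Tuple[str, bool]]:
    """Build a code -> (ingredient, is_sact) map; collisions are an error.

    Rows are ``(code_system, code, ingredient_name, is_sact)``.  The same code
    may be listed twice only with identical payloads.
    """
    out: Dict[str, Tuple[str, bool]] = {}
    for system, code, name, is_sact in rows:
        key = f"{system}:{code}"
        entry = (name, bool(is_sact))
        if key in out and out[key] != entry:
            raise ConfigError(f"ingredient map collision for {key}: {out[key]} vs {entry}")
        out[key] = entry
    return out


def harmonize_drugs(
    bundle: CohortBundle,
    ingredient_map: Mapping[str, Tuple[str, bool]],
    config: AssessmentConfig,
) -> CohortBundle:
    """Fill drug names from the user-supplied code map and flag SACT/target.

    Unmapped records keep their raw fields; the count of records left without
    any identity is logged (it surfaces in the missing-identity check).
    """
    sact_names = {name.lower() for name, is_sact in ingredient_map.values() if is_sact}
    unmapped = 0
    for event in bundle.drug_events:
        if event.drug_code:
            entry = ingredient_map.get(f"{event.code_system}:{event.drug_code}")
            if entry is not None:
                name, is_sact = entry
                if not event.drug_name:
                    event.drug_name = name
                event.is_sact = is_sact
        if event.drug_name and event.drug_name.lower() in sact_names:
            event.is_sact = True
        if event.missing_identity:
            unmapped += 1
            event.is_sact = False
        event.is_target = event.is_sact and config.is_target_event(event)
    if unmapped:
        logger.info("harmonize_drugs: %d records with no resolvable drug identity", unmapped)
    bundle.provenance.setdefault("harmonization", {})["unmapped_records"] = unmapped
    return bundle
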