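"""Shared fixtures: a standard config and compact record builders."""

from __future__ import annotations

import datetime as dt

import pytest

from rwttdqa import (
    ActivityEvent,
    AssessmentConfig,
    CohortBundle,
    DrugEvent,
    PartialDate,
    PatientRecord,
)

DAY0 = dt.date(2018, 1, 1)


def day(offset: int) -> dt.date:
    return DAY0 + dt.timedelta(days=offset)


def pday(offset: int) -> PartialDate:
    return PartialDate.from_date(day(offset))


def admin(pid: str, drug: str, offset: int, *, is_target: bool = False) -> DrugEvent:
    return DrugEvent(
        patient_id=pid,
        event_date=pday(offset),
        route_kind="administered",
        drug_name=drug,
        is_sact=True,
        is_target=is_target or drug == "TARGET",
    )


def order(
    pid: str,
    drug: str,
    offset: int,
    *,
    days_supply=None,
    refills=None,
    canceled: bool = False,
    is_sact: bool = True,
    is_target: bool = False,
) -> DrugEvent:
    return DrugEvent(
        patient_id=pid,
        event_date=pday(offset),
        route_kind="ordered",
        drug_name=drug,
        days_supply=days_supply,
        refills=refills,
        canceled=canceled,
        is_sact=is_sact,
        is_target=is_target or drug == "TARGET",
    )


def activity(pid: str, offset: int, category: str = "facility_visit") -> ActivityEvent:
    return ActivityEvent(patient_id=pid, category=category, event_date=pday(offset))


def patient(pid: str, index_offset: int = 0, **kwargs) -> PatientRecord:
    kwargs.setdefault("ajcc_stage", "IV")
    kwargs.setdefault("diagnosis_codes", [("ICD-10", "C77.0")])
    return PatientRecord(patient_id=pid, index_date=pday(index_offset), **kwargs)


def bundle(patients, drug_events=(), activities=(), provided_lots=None) -> CohortBundle:
    return CohortBundle(
        patients=list(patients),
        drug_events=list(drug_events),
        activities=list(activities),
        provided_lots=None if provided_lots is None else list(provided_lots),
    )


@pytest.fixture
def config() -> AssessmentConfig:
    return AssessmentConfig(
        target_name="TARGET",
        target_codes=("RxNorm:999001",),
        target_route="intravenous",
        study_start_date=dt.date(2015, 1, 1),
        data_cutoff_date=dt.date(2019, 11, 25),
        approval_dates={
            "second_line_plus": dt.date(2016, 8, 5),
            "first_line_combo": dt.date(2019, 6, 10),
        },
        approved_combinations=("TARGET+carboplatin+fluorouracil",),
    )


@pytest.fixture
def oral_config(config) -> AssessmentConfig:
    import dataclasses

    return dataclasses.replace(config, target_route="oral")
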