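"""Cohort loading, round-tripping, restriction and drug harmonization."""

import dataclasses

import pytest

from rwttdqa import (
    ConfigError,
    IntegrityError,
    SchemaError,
    build_ingredient_map,
    harmonize_drugs,
    load_cohort,
    restrict_to_advanced,
    write_cohort,
)
from rwttdqa.simulate import SyntheticParams, generate_cohort

from conftest import activity, admin, bundle, patient


def _write_tables(tmp_path, patients_rows, drug_rows, activity_rows, lot_rows=None):
    (tmp_path / "patients.csv").write_text(
        "patient_id,index_date,sex,ajcc_stage,diagnosis_codes,death_date\n"
        + "".join(r + "\n" for r in patients_rows)
    )
    (tmp_path / "drug_events.csv").write_text(
        "patient_id,event_date,route_kind,drug_name,code_system,drug_code,"
        "days_supply,refills,canceled,is_sact\n" + "".join(r + "\n" for r in drug_rows)
    )
    (tmp_path / "activities.csv").write_text(
        "patient_id,category,event_date\n" + "".join(r + "\n" for r in activity_rows)
    )
    paths = {
        "patients": tmp_path / "patients.csv",
        "drug_events": tmp_path / "drug_events.csv",
        "activities": tmp_path / "activities.csv",
    }
    if lot_rows is not None:
        (tmp_path / "lots.csv").write_text(
            "patient_id,line_number,line_name,start_date,end_date,maintenance\n"
            + "".join(r + "\n" for r in lot_rows)
        )
        paths["lots"] = tmp_path / "lots.csv"
    return paths


def test_clean_four_table_fixture_loads_without_warnings(tmp_path):
    paths = _write_tables(
        tmp_path,
        ["P1,2018-01-01,male,IV,ICD-10:C77.0,2019-05-01"],
        ["P1,2018-01-10,administered,TARGET,RxNorm,999001,,,false,true"],
        ["P1,facility_visit,2018-01-10"],
        ["P1,1,TARGET,2018-01-10,2018-03-01,"],
    )
    b = load_cohort(paths)
    assert len(b.patients) == 1 and len(b.drug_events) == 1 and len(b.activities) == 1
    assert b.provided_lots is not None and b.provided_lots[0].regimen_name == "TARGET"
    assert b.provenance["load_log"] == []


def test_year_only_death_date_is_coarsened_and_logged(tmp_path):
    paths = _write_tables(
        tmp_path,
        ["P1,2018-01-01,male,IV,ICD-10:C77.0,2017"],
        [],
        [],
    )
    b = load_cohort(paths)
    death = b.patients[0].death_date
    assert death is not None and death.precision == "year" and death.year == 2017
    assert any("death_date" in entry for entry in b.provenance["load_log"])


def test_orphan_drug_event_raises_integrity_error(tmp_path):
    paths = _write_tables(
        tmp_path,
        ["P1,2018-01-01,male,IV,ICD-10:C77.0,"],
        ["GHOST,2018-01-10,administered,TARGET,,,,,false,true"],
        [],
    )
    with pytest.raises(IntegrityError, match="GHOST"):
        load_cohort(paths)


def test_missing_mandatory_column_names_table_and_column(tmp_path):
    (tmp_path / "patients.csv").write_text("patient_id\nP1\n")
    (tmp_path / "drug_events.csv").write_text("patient_id,event_date,route_kind\n")
    (tmp_path / "activities.csv").write_text("patient_id,category,event_date\n")
    with pytest.raises(SchemaError, match="patients.*index_date"):
        load_cohort(
            {
                "patients": tmp_path / "patients.csv",
                "drug_events": tmp_path / "drug_events.csv",
                "activities": tmp_path / "activities.csv",
            }
        )


def test_exact_duplicate_rows_are_dropped_and_counted(tmp_path):
    row = "P1,2018-01-10,administered,TARGET,RxNorm,999001,,,false,true"
    paths = _write_tables(
        tmp_path,
        ["P1,2018-01-01,male,IV,ICD-10:C77.0,"],
        [row, row, row],
        [],
    )
    b = load_cohort(paths)
    assert len(b.drug_events) == 1
    assert any("duplicate" in entry for entry in b.provenance["load_log"])


def test_write_then_load_round_trips_field_for_field(tmp_path):
    params = SyntheticParams(n_patients=25, seed=5)
    generated, _ = generate_cohort(params)
    # first pass collapses exact-duplicate rows; thereafter the round trip
    # must be the identity, field for field at the stated precisions
    original = load_cohort(write_cohort(generated, tmp_path / "a"))
    reloaded = load_cohort(write_cohort(original, tmp_path / "b"))
    assert {(a.patient_id, a.category, a.event_date) for a in generated.activities} == {
        (a.patient_id, a.category, a.event_date) for a in original.activities
    }
    assert len(reloaded.patients) == len(original.patients)
    for a, b in zip(original.patients, reloaded.patients):
        assert (a.patient_id, a.index_date, a.sex, a.age_at_index, a.race) == (
            b.patient_id,
            b.index_date,
            b.sex,
            b.age_at_index,
            b.race,
        )
        assert a.diagnosis_codes == b.diagnosis_codes and a.death_date == b.death_date
    assert [dataclasses.astuple(e) for e in original.drug_events] == [
        dataclasses.astuple(e) for e in reloaded.drug_events
    ]
    assert [dataclasses.astuple(x) for x in original.activities] == [
        dataclasses.astuple(x) for x in reloaded.activities
    ]
    assert [
        (l.patient_id, l.line_number, l.regimen_name, l.start_date, l.end_date)
        for l in original.provided_lots
    ] == [
        (l.patient_id, l.line_number, l.regimen_name, l.start_date, l.end_date)
        for l in reloaded.provided_lots
    ]


class TestRestrictToAdvanced:
    def _cohort(self):
        patients = [
            patient("P1", ajcc_stage="IV", diagnosis_codes=[("ICD-10", "C77.0")]),
            patient("P2", ajcc_stage="IV", diagnosis_codes=[("ICD-9", "196.1")]),
            patient("P3", ajcc_stage="IV", diagnosis_codes=[("ICD-10", "C44.0")]),  # no met code
            patient("P4", ajcc_stage="III", diagnosis_codes=[("ICD-10", "C78.2")]),  # stage fails
            patient("P5", ajcc_stage="unknown", diagnosis_codes=[]),
            patient("P6", ajcc_stage="II", diagnosis_codes=[("ICD-9", "196.0")]),
        ]
        events = [admin(p.patient_id, "TARGET", 5) for p in patients]
        acts = [activity(p.patient_id, 3) for p in patients]
        return bundle(patients, events, acts)

    def test_conjunction_of_stage_and_code(self):
        out = restrict_to_advanced(self._cohort())
        assert sorted(out.patient_ids()) == ["P1", "P2"]
        assert {e.patient_id for e in out.drug_events} == {"P1", "P2"}
        assert {a.patient_id for a in out.activities} == {"P1", "P2"}

    def test_dot_stripped_prefix_matching(self):
        b = bundle([patient("P1", diagnosis_codes=[("ICD-10", "c77.9")])])
        assert restrict_to_advanced(b).patient_ids() == {"P1"}

    def test_idempotent_and_monotone(self):
        once = restrict_to_advanced(self._cohort())
        twice = restrict_to_advanced(once)
        assert once.patient_ids() == twice.patient_ids()
        assert once.patient_ids() <= self._cohort().patient_ids()

    def test_empty_result_is_valid(self):
        b = bundle([patient("P1", ajcc_stage="I", diagnosis_codes=[])])
        assert restrict_to_advanced(b).patients == []


class TestHarmonizeDrugs:
    def test_name_filled_and_flags_set_from_map(self, config):
        imap = build_ingredient_map([("RxNorm", "999001", "TARGET", True)])
        e = admin("P1", None, 5)
        e.drug_name = None
        e.is_sact = False
        e.is_target = False
        e.code_system, e.drug_code = "RxNorm", "999001"
        b = bundle([patient("P1")], [e])
        harmonize_drugs(b, imap, config)
        assert e.drug_name == "TARGET" and e.is_sact and e.is_target

    def test_unmapped_identityless_record_is_counted(self, config):
        e = admin("P1", None, 5)
        e.drug_name = None
        b = bundle([patient("P1")], [e])
        harmonize_drugs(b, {}, config)
        assert e.missing_identity and not e.is_sact
        assert b.provenance["harmonization"]["unmapped_records"] == 1

    def test_map_collision_is_an_error_before_any_mutation(self):
        with pytest.raises(ConfigError, match="collision"):
            build_ingredient_map(
                [
                    ("RxNorm", "40048", "carboplatin", True),
                    ("RxNorm", "40048", "cisplatin", True),
                ]
            )
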