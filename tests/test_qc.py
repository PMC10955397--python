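"""The twenty quality checks: counts, stats, applicability, determinism."""

import dataclasses
import datetime as dt

import pytest

from rwttdqa import (
    LotRecord,
    PartialDate,
    TargetEpisode,
    check_followup,
    check_lot,
    check_mortality,
    check_sact,
    run_assessment,
)

from conftest import activity, admin, bundle, day, order, patient, pday


def _by_id(tasks):
    return {t.task_id: t for t in tasks}


def _lot(pid, number, name, start, end):
    return LotRecord(
        patient_id=pid,
        line_number=number,
        regimen_name=name,
        start_date=pday(start),
        end_date=pday(end),
        provenance="provided",
    )


def _episode(pid, line, dates, therapy="mono", approved=False):
    return TargetEpisode(
        patient_id=pid,
        line_number=line,
        line_group="1L" if line == 1 else "2L+",
        therapy=therapy,
        approved_combo=approved,
        lot=None,
        target_dates=[day(o) for o in dates],
    )


class TestSactChecks:
    def test_patients_with_sact_after_index_hand_count(self, config):
        # 4 patients, 3 with SACT on/after their index date
        patients = [patient(f"P{i}") for i in range(1, 5)]
        events = [
            admin("P1", "TARGET", 0),  # same day as index: counts
            admin("P2", "carboplatin", 30),
            admin("P3", "docetaxel", -10),  # before index: does not count
            admin("P4", "TARGET", 5),
        ]
        tasks = _by_id(check_sact(bundle(patients, events), [], config))
        assert (tasks[1].numerator, tasks[1].denominator) == (3, 4)
        assert tasks[1].percent == 75.0

    def test_missing_identity_and_complete_dates(self, config):
        nameless = admin("P1", None, 10)
        nameless.drug_name = None
        nameless.is_sact = False  # identity unknown, cannot be classified SACT
        coarse = admin("P1", "carboplatin", 0)
        coarse.event_date = PartialDate(2018, 3)
        events = [admin("P1", "TARGET", 0), nameless, coarse]
        tasks = _by_id(check_sact(bundle([patient("P1")], events), [], config))
        assert (tasks[2].numerator, tasks[2].denominator) == (1, 3)
        # nameless events are not SACT, so the date-completeness base is 2
        assert (tasks[4].numerator, tasks[4].denominator) == (1, 2)

    def test_constant_dosing_grid_gap_distribution(self, config):
        patients = [patient("P1"), patient("P2")]
        events = [admin(p.patient_id, "TARGET", o) for p in patients for o in (0, 21, 42)]
        tasks = _by_id(check_sact(bundle(patients, events), [], config))
        s = tasks[5].stats
        assert (s["median"], s["q1"], s["q3"], s["min"], s["max"]) == (21, 21, 21, 21, 21)
        assert s["n"] == 4

    def test_order_completeness_counts(self, config):
        events = [
            order("P1", "ondansetron", 0, days_supply=30, refills=1, is_sact=False),
            order("P1", "ondansetron", 40, is_sact=False),  # missing supply fields
        ]
        tasks = _by_id(check_sact(bundle([patient("P1")], events), [], config))
        assert (tasks[7].numerator, tasks[7].denominator) == (1, 2)
        assert (tasks[8].numerator, tasks[8].denominator) == (2, 2)

    def test_oral_only_tasks_omitted_for_intravenous_target(self, config):
        tasks = _by_id(check_sact(bundle([patient("P1")]), [], config))
        for task_id in (6, 9):
            assert not tasks[task_id].applicable
            assert "oral" in tasks[task_id].omission_reason

    def test_oral_target_order_checks_apply(self, oral_config):
        events = [
            order("P1", "TARGET", 0, days_supply=21, refills=0),
            order("P1", "TARGET", 30, days_supply=21, refills=0),
        ]
        tasks = _by_id(check_sact(bundle([patient("P1")], events), [], oral_config))
        assert tasks[6].applicable and tasks[6].numerator == 1
        # covered through d20; next order d30 -> normalized gap 10
        assert tasks[9].applicable and tasks[9].stats["median"] == 10


class TestLotChecks:
    def test_quarterly_initiation_bucketing(self, config):
        eps = [
            _episode("P1", 1, [31]),  # 2018-02-01 -> 2018Q1
            _episode("P2", 2, [120]),  # 2018-05-01 -> 2018Q2
        ]
        tasks = _by_id(check_lot(bundle([patient("P1"), patient("P2")]), [], eps, config))
        strata = tasks[10].strata
        assert strata["2018Q1"]["1L mono"] == 1
        assert strata["2018Q2"]["2L+ mono"] == 1
        assert sum(sum(row.values()) for row in strata.values()) == 2

    def test_first_lot_number_other_than_one_is_flagged(self, config):
        lots = [_lot("P1", 3, "A", 10, 50), _lot("P2", 1, "A", 10, 50)]
        tasks = _by_id(check_lot(bundle([patient("P1"), patient("P2")]), lots, [], config))
        assert (tasks[12].numerator, tasks[12].denominator) == (1, 2)

    def test_lot_field_completeness_strata(self, config):
        complete = _lot("P1", 1, "A", 10, 50)
        nameless = _lot("P2", 1, "", 10, 50)
        endless = dataclasses.replace(_lot("P3", 1, "A", 10, 50), end_date=None)
        b = bundle([patient("P1"), patient("P2"), patient("P3"), patient("P4")])
        tasks = _by_id(check_lot(b, [complete, nameless, endless], [], config))
        strata = tasks[11].strata
        assert strata["line_number"]["patients"] == 3
        assert strata["line_name"]["patients"] == 2
        assert strata["line_start"]["patients"] == 3
        assert strata["line_end"]["patients"] == 2
        assert tasks[11].denominator == 4

    def test_receipt_percentile_uses_ceiling_rank(self, config):
        # 20 first-line mono initiators on a weekly grid starting 2018-01-01
        eps = [_episode(f"P{i:02d}", 1, [7 * i]) for i in range(20)]
        b = bundle([patient(f"P{i:02d}") for i in range(20)])
        tasks = _by_id(check_lot(b, [], eps, config))
        entry = tasks[14].strata["1L monotherapy"]
        assert entry["n"] == 20
        # ceil(0.05*20)=1 -> 1st date; ceil(0.10*20)=2 -> 2nd; ceil(0.25*20)=5 -> 5th
        assert entry["earliest_5pct_date"] == day(0).isoformat()
        assert entry["earliest_10pct_date"] == day(7).isoformat()
        assert entry["earliest_25pct_date"] == day(28).isoformat()

    def test_small_stratum_percentiles_not_calculated(self, config):
        eps = [_episode(f"P{i}", 1, [7 * i], therapy="combo", approved=True) for i in range(4)]
        b = bundle([patient(f"P{i}") for i in range(4)])
        tasks = _by_id(check_lot(b, [], eps, config))
        entry = tasks[14].strata["approved 1L combination"]
        assert entry["n"] == 4
        assert entry["earliest_5pct_date"] is None
        assert entry["first_initiation"] == day(0).isoformat()


class TestMortalityChecks:
    def test_death_record_and_conflict_counts(self, config):
        p1 = patient("P1", death_date=pday(100))
        p2 = patient("P2", death_date=pday(50), extra_death_dates=[pday(60)])
        p3 = patient("P3")
        tasks = _by_id(check_mortality(bundle([p1, p2, p3]), config))
        assert (tasks[15].numerator, tasks[15].denominator) == (2, 3)
        assert (tasks[16].numerator, tasks[16].denominator) == (1, 2)

    def test_post_death_activity_tiers_use_last_activity(self, config):
        p = patient("P1", death_date=pday(100))
        acts = [activity("P1", 105), activity("P1", 131)]  # max gap 31 days
        tasks = _by_id(check_mortality(bundle([p], activities=acts), config))
        t17 = tasks[17]
        assert (t17.numerator, t17.denominator) == (1, 1)
        assert t17.strata == {">=1d": 1, ">=3d": 1, ">=7d": 1, ">=30d": 1}
        assert t17.stats["median"] == 31

    def test_tier_counts_are_monotone_nonincreasing(self, config):
        patients = [patient(f"P{i}", death_date=pday(100)) for i in range(5)]
        acts = [
            activity("P0", 101),  # gap 1
            activity("P1", 104),  # gap 4
            activity("P2", 108),  # gap 8
            activity("P3", 140),  # gap 40
        ]
        tasks = _by_id(check_mortality(bundle(patients, activities=acts), config))
        counts = [tasks[17].strata[f">={t}d"] for t in (1, 3, 7, 30)]
        assert counts == [4, 3, 2, 1]
        assert counts == sorted(counts, reverse=True)

    def test_year_precision_deaths_omit_plausibility_tasks(self, config):
        p = patient("P1")
        p.death_date = PartialDate(2018)
        tasks = _by_id(check_mortality(bundle([p]), config))
        for task_id in (16, 17):
            assert not tasks[task_id].applicable
            assert "precision" in tasks[task_id].omission_reason

    def test_no_deaths_at_all_is_zero_not_omitted(self, config):
        tasks = _by_id(check_mortality(bundle([patient("P1")]), config))
        assert tasks[15].numerator == 0 and tasks[15].percent == 0.0
        assert tasks[16].applicable and tasks[17].applicable


class TestFollowupChecks:
    def test_patient_date_pairs_per_category(self, config):
        acts = [
            activity("P1", 5, "laboratory"),
            activity("P1", 5, "laboratory"),  # same day: one pair
            activity("P1", 9, "laboratory"),
            activity("P1", 12, "laboratory"),
            activity("P1", -3, "laboratory"),  # before index: excluded
        ]
        tasks = _by_id(check_followup(bundle([patient("P1")], activities=acts), [], config))
        lab = tasks[18].strata["laboratory"]
        assert lab["patients"] == 1 and lab["patient_date_pairs"] == 3
        assert lab["pairs_per_patient"] == 3.0

    def test_visit_frequency_is_visits_over_span(self, config):
        eps = [_episode("P1", 1, [0, 21, 42])]
        acts = [activity("P1", o) for o in (5, 15, 25, 35)] + [
            activity("P1", 0),  # boundary dates are excluded (strictly between)
            activity("P1", 42),
        ]
        tasks = _by_id(check_followup(bundle([patient("P1")], activities=acts), eps, config))
        s = tasks[19].strata["1L monotherapy"]
        assert s["n"] == 1
        assert s["median"] == pytest.approx(4 / 42, abs=1e-4)

    def test_single_day_episode_excluded_from_frequency(self, config):
        eps = [_episode("P1", 1, [0])]
        log = []
        tasks = _by_id(check_followup(bundle([patient("P1")]), eps, config, notes=log))
        assert tasks[19].numerator == 0
        assert any("single-day" in n for n in log)

    def test_alive_gap_window_exclusions(self, config):
        # P1: last dose d42, visit d100, no death -> gap 58
        # P2: last dose 100 days before cutoff -> excluded (too recent)
        # P3: died 30 days after last dose -> excluded (not alive through window)
        recent = (config.data_cutoff_date - dt.timedelta(days=100) - day(0)).days
        eps = [
            _episode("P1", 1, [0, 42]),
            _episode("P2", 1, [recent - 21, recent]),
            _episode("P3", 1, [0, 42]),
        ]
        b = bundle(
            [patient("P1"), patient("P2"), patient("P3", death_date=pday(72))],
            activities=[activity("P1", 100), activity("P2", recent), activity("P3", 60)],
        )
        tasks = _by_id(check_followup(b, eps, config))
        t20 = tasks[20]
        assert (t20.numerator, t20.denominator) == (1, 3)
        assert t20.stats["median"] == 58


class TestRunAssessment:
    def _bundle(self):
        patients = [
            patient("P1", death_date=pday(150)),
            patient("P2"),
            patient("P3"),
        ]
        events = [admin("P1", "TARGET", o) for o in (0, 21, 42)] + [
            admin("P2", "carboplatin", 10),
            admin("P3", "TARGET", 5),
        ]
        acts = [activity(p.patient_id, o) for p in patients for o in (2, 40, 80)]
        lots = [
            _lot("P1", 1, "TARGET", 0, 42),
            _lot("P2", 1, "carboplatin", 10, 10),
            _lot("P3", 1, "TARGET", 5, 5),
        ]
        return bundle(patients, events, acts, provided_lots=lots)

    def test_report_contains_all_twenty_tasks_once(self, config):
        report = run_assessment(self._bundle(), config)
        assert sorted(t.task_id for t in report.tasks) == list(range(1, 21))

    def test_defect_free_cohort_shows_no_defects(self, config):
        report = run_assessment(self._bundle(), config)
        assert report.task(2).numerator == 0
        assert report.task(4).percent == 100.0
        assert report.task(12).numerator == 0
        assert report.task(16).numerator == 0
        assert report.task(17).numerator == 0

    def test_reruns_are_byte_identical(self, config):
        a = run_assessment(self._bundle(), config).to_json()
        b = run_assessment(self._bundle(), config).to_json()
        assert a == b

    def test_adding_records_never_decreases_presence_numerators(self, config):
        base = run_assessment(self._bundle(), config)
        grown = self._bundle()
        grown.patients.append(patient("P4", death_date=pday(200)))
        grown.drug_events.append(admin("P4", "TARGET", 3))
        grown.activities.append(activity("P4", 30))
        bigger = run_assessment(grown, config)
        for task_id in (1, 15, 18):
            assert bigger.task(task_id).numerator >= base.task(task_id).numerator

    def test_lot_comparison_diagnostic_present_with_provided_lots(self, config):
        report = run_assessment(self._bundle(), config)
        assert report.lot_comparison is not None
        assert report.lot_comparison["patients_compared"] >= 1
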