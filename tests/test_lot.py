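"""LOT derivation rules, sparse-table imputation, and episode classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rwttdqa import (
    classify_target_episodes,
    derive_lots,
    impute_sparse_lots,
    LotRecord,
    PartialDate,
)

from _oracles import brute_force_lots
from conftest import DAY0, admin, day, pday


def _derived(events, config, index_offset=0):
    lots = derive_lots(events, day(index_offset), config)
    return [
        (
            l.line_number,
            l.regimen_name,
            (l.start_date.as_date() - DAY0).days,
            (l.end_date.as_date() - DAY0).days,
        )
        for l in lots
    ]


class TestDeriveLots:
    def test_drug_within_window_joins_the_line(self, config):
        events = [admin("P1", "A", 0), admin("P1", "B", 20), admin("P1", "A", 41)]
        assert _derived(events, config) == [(1, "A+B", 0, 41)]

    def test_new_drug_beyond_window_starts_new_line(self, config):
        events = [admin("P1", "A", 0), admin("P1", "B", 30)]
        assert _derived(events, config) == [(1, "A", 0, 0), (2, "B", 30, 30)]

    def test_same_drug_after_long_gap_starts_new_line(self, config):
        # gap 145-21=124 >= 120 even though the drug is unchanged
        events = [admin("P1", "A", 0), admin("P1", "A", 21), admin("P1", "A", 145)]
        assert _derived(events, config) == [(1, "A", 0, 21), (2, "A", 145, 145)]

    def test_window_boundary_day_28_does_not_join(self, config):
        events = [admin("P1", "A", 0), admin("P1", "B", 27), admin("P1", "C", 28)]
        assert _derived(events, config) == [(1, "A+B", 0, 27), (2, "C", 28, 28)]

    def test_events_before_index_are_rejected(self, config):
        with pytest.raises(ValueError, match="precedes index"):
            derive_lots([admin("P1", "A", 0)], day(5), config)

    def test_coarse_dated_events_are_skipped(self, config):
        coarse = admin("P1", "B", 0)
        coarse.event_date = PartialDate(2018, 2)
        events = [admin("P1", "A", 0), coarse]
        assert _derived(events, config) == [(1, "A", 0, 0)]

    def test_canceled_and_non_sact_events_are_ignored(self, config):
        ignored = admin("P1", "B", 5)
        ignored.canceled = True
        supportive = admin("P1", "C", 6)
        supportive.is_sact = False
        events = [admin("P1", "A", 0), ignored, supportive]
        assert _derived(events, config) == [(1, "A", 0, 0)]


# -- properties ------------------------------------------------------------

from rwttdqa import AssessmentConfig

CONFIG = AssessmentConfig(target_name="TARGET")  # read-only, shared across examples

_drug = st.sampled_from(["A", "B", "C"])
_event_lists = st.lists(
    st.tuples(st.integers(min_value=0, max_value=400), _drug), min_size=1, max_size=6
)


@settings(derandomize=True, max_examples=500)
@given(pairs=_event_lists)
def test_derivation_matches_bruteforce_enumeration(pairs):
    """The two boundary rules admit exactly one partition; we produce it."""
    events = [admin("P1", drug, off) for off, drug in pairs]
    lots = derive_lots(events, day(0), CONFIG)
    got = [
        (
            (l.start_date.as_date() - DAY0).days,
            (l.end_date.as_date() - DAY0).days,
            frozenset(l.regimen()),
        )
        for l in lots
    ]
    valid = brute_force_lots(sorted(pairs))
    assert len(valid) == 1, f"rules should admit exactly one partition, got {len(valid)}"
    assert got == valid[0]


@settings(derandomize=True, max_examples=200)
@given(pairs=_event_lists, seed=st.integers(min_value=0, max_value=2**16))
def test_event_order_permutation_is_irrelevant(pairs, seed):
    events = [admin("P1", drug, off) for off, drug in pairs]
    rng = np.random.default_rng(seed)
    shuffled = [events[i] for i in rng.permutation(len(events))]
    assert _derived(events, CONFIG) == _derived(shuffled, CONFIG)


@settings(derandomize=True, max_examples=200)
@given(pairs=_event_lists, shift=st.integers(min_value=0, max_value=300))
def test_shifting_all_dates_shifts_all_lines(pairs, shift):
    base = _derived([admin("P1", d, o) for o, d in pairs], CONFIG)
    moved = _derived([admin("P1", d, o + shift) for o, d in pairs], CONFIG, index_offset=shift)
    assert moved == [(n, r, s + shift, e + shift) for n, r, s, e in base]


@settings(derandomize=True, max_examples=300)
@given(pairs=_event_lists)
def test_every_event_lies_inside_its_line_window(pairs):
    events = [admin("P1", drug, off) for off, drug in pairs]
    lots = derive_lots(events, day(0), CONFIG)
    for off, drug in pairs:
        d = day(off)
        homes = [
            l
            for l in lots
            if l.start_date.as_date() <= d <= l.end_date.as_date() and drug in l.regimen()
        ]
        assert homes, f"event ({off},{drug}) outside every line window"
    # line numbers contiguous from 1, starts strictly increasing
    assert [l.line_number for l in lots] == list(range(1, len(lots) + 1))
    starts = [l.start_date.as_date() for l in lots]
    assert starts == sorted(starts) and len(set(starts)) == len(starts)


# -- sparse-table imputation ------------------------------------------------


def _sparse(pid, number, start_offset):
    return LotRecord(
        patient_id=pid,
        line_number=number,
        regimen_name="",
        start_date=pday(start_offset),
        provenance="provided",
    )


class TestImputeSparseLots:
    def test_end_is_day_before_next_start_or_cutoff(self):
        lots = impute_sparse_lots(
            [_sparse("P1", 1, 0), _sparse("P1", 2, 100)], [], day(500)
        )
        assert [(l.line_number, l.end_date.as_date()) for l in lots] == [
            (1, day(99)),
            (2, day(500)),
        ]
        assert all(l.provenance == "imputed_end" for l in lots)

    def test_single_line_ends_at_cutoff(self):
        (lot,) = impute_sparse_lots([_sparse("P1", 1, 0)], [], day(500))
        assert lot.end_date.as_date() == day(500)

    def test_regimen_from_events_inside_imputed_window(self):
        events = [admin("P1", "A", 5), admin("P1", "B", 150)]
        lots = impute_sparse_lots(
            [_sparse("P1", 1, 0), _sparse("P1", 2, 100)], events, day(500)
        )
        assert [l.regimen_name for l in lots] == ["A", "B"]

    def test_identical_start_dates_break_ties_by_line_number(self):
        lots = impute_sparse_lots([_sparse("P1", 2, 0), _sparse("P1", 1, 0)], [], day(90))
        assert [l.line_number for l in lots] == [1, 2]  # no crash, sorted output


# -- episode classification -------------------------------------------------


def _lot(pid, number, name, start, end):
    return LotRecord(
        patient_id=pid,
        line_number=number,
        regimen_name=name,
        start_date=pday(start),
        end_date=pday(end),
        provenance="provided",
    )


class TestClassifyTargetEpisodes:
    def test_later_line_monotherapy_is_2l_mono(self, config):
        lots = [_lot("P1", 1, "A", 0, 60), _lot("P1", 2, "TARGET", 200, 260)]
        (ep,) = classify_target_episodes(lots, [admin("P1", "TARGET", 200)], config)
        assert (ep.line_group, ep.therapy, ep.approved_combo) == ("2L+", "mono", False)

    def test_first_line_approved_combination(self, config):
        lots = [_lot("P1", 1, "TARGET+carboplatin+fluorouracil", 0, 60)]
        (ep,) = classify_target_episodes(lots, [admin("P1", "TARGET", 0)], config)
        assert (ep.line_group, ep.therapy, ep.approved_combo) == ("1L", "combo", True)

    def test_unapproved_combination_is_flagged_combo_only(self, config):
        lots = [_lot("P1", 1, "TARGET+docetaxel", 0, 60)]
        (ep,) = classify_target_episodes(lots, [admin("P1", "TARGET", 0)], config)
        assert (ep.line_group, ep.therapy, ep.approved_combo) == ("1L", "combo", False)

    def test_target_outside_every_lot_window_yields_unknown_episode(self, config):
        lots = [_lot("P1", 1, "A", 0, 60)]
        (ep,) = classify_target_episodes(lots, [admin("P1", "TARGET", 100)], config)
        assert ep.line_group == "unknown" and ep.finding is not None

    def test_reinitiation_in_later_line_is_a_separate_episode(self, config):
        lots = [_lot("P1", 1, "TARGET", 0, 42), _lot("P1", 2, "TARGET+docetaxel", 200, 280)]
        eps = classify_target_episodes(
            lots,
            [admin("P1", "TARGET", 0), admin("P1", "TARGET", 42), admin("P1", "TARGET", 200)],
            config,
        )
        assert [(e.line_number, e.first_dose, e.last_dose) for e in eps] == [
            (1, day(0), day(42)),
            (2, day(200), day(200)),
        ]
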