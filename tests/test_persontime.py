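"""Follow-up construction and person-day tabulation against the
day-enumeration oracle."""

import numpy as np
import pandas as pd
import pytest

from hipsir import (
    ExposurePolicy,
    SimConfig,
    StudyConfig,
    assign_groups,
    brute_force_tabulate,
    compute_followups,
    merge_windows,
    simulate_registry,
    tabulate,
    to_day,
    validate_table,
    windows_from_dispensings,
)

from conftest import make_dispensings, make_fractures, make_persons

CFG = StudyConfig()


class TestComputeFollowups:
    def test_uncensored_person_runs_to_study_end(self):
        persons = make_persons([("P1", "female", 1930)])
        fu, diag = compute_followups(persons, make_fractures([]), CFG)
        assert fu.loc[0, "start_day"] == to_day("2005-01-01")
        assert fu.loc[0, "end_day"] == to_day("2010-12-31")
        assert fu.loc[0, "end_reason"] == "study_end"
        assert diag["censored_before_study_start"] == 0

    def test_fracture_before_death_ends_followup(self):
        persons = make_persons([("P1", "female", 1930, "2009-01-01")])
        fractures = make_fractures([("P1", "2006-05-04")])
        fu, _ = compute_followups(persons, fractures, CFG)
        assert fu.loc[0, "end_day"] == to_day("2006-05-04")
        assert fu.loc[0, "end_reason"] == "fracture"

    def test_death_on_study_start_gives_one_day(self):
        persons = make_persons([("P1", "male", 1920, "2005-01-01")])
        fu, _ = compute_followups(persons, make_fractures([]), CFG)
        assert fu.loc[0, "end_day"] - fu.loc[0, "start_day"] + 1 == 1
        assert fu.loc[0, "end_reason"] == "death"

    def test_death_before_study_start_excluded(self):
        persons = make_persons(
            [("P1", "male", 1920, "2004-06-01"), ("P2", "female", 1930)]
        )
        fu, diag = compute_followups(persons, make_fractures([]), CFG)
        assert list(fu["person_id"]) == ["P2"]
        assert diag["censored_before_study_start"] == 1

    def test_emigration_censors(self):
        persons = make_persons([("P1", "female", 1930, None, "2007-03-15")])
        fu, _ = compute_followups(persons, make_fractures([]), CFG)
        assert fu.loc[0, "end_day"] == to_day("2007-03-15")
        assert fu.loc[0, "end_reason"] == "emigration"


def _single_person_inputs(windows_days, event=None):
    persons = make_persons([("P1", "female", 1930, "2005-01-10")])  # 10-day follow-up
    fu, _ = compute_followups(persons, make_fractures([event] if event else []), CFG)
    d0 = to_day("2005-01-01")
    win = pd.DataFrame(
        [("P1", "g", d0 + s, d0 + e, "overall") for s, e in windows_days],
        columns=["person_id", "group", "start_day", "end_day", "origin"],
    )
    return fu, win


class TestTabulate:
    def test_person_days_conserved_and_split(self):
        fu, win = _single_person_inputs([(2, 4)])  # days 3-5 of 10
        table = tabulate(fu, win, make_fractures([]), CFG)
        assert table["person_days"].sum() == 10
        assert table.loc[table.exposure_state == "exposed", "person_days"].sum() == 3

    def test_event_lands_in_exposed_cell(self):
        fu, win = _single_person_inputs([(2, 4)], event=("P1", "2005-01-04"))
        table = tabulate(fu, win, make_fractures([("P1", "2005-01-04")]), CFG)
        exposed = table[table.exposure_state == "exposed"]
        assert exposed["events"].sum() == 1
        assert table["events"].sum() == 1

    def test_followup_splits_across_calendar_bins(self):
        persons = make_persons([("P1", "female", 1930, "2005-03-01")])
        fu, _ = compute_followups(persons, make_fractures([]), CFG)
        table = tabulate(fu, None, make_fractures([]), CFG)
        by_period = table.groupby("period")["person_days"].sum()
        assert by_period[0] == 59  # Jan-Feb 2005
        assert by_period[1] == 1  # Mar 1, 2005
        assert table["person_days"].sum() == 60

    def test_no_windows_means_all_unexposed(self):
        fu, _ = _single_person_inputs([])
        table = tabulate(fu, None, make_fractures([]), CFG)
        assert set(table["exposure_state"]) == {"unexposed"}

    def test_event_outside_followup_is_hard_error(self):
        persons = make_persons([("P1", "female", 1930, "2005-06-01")])
        fu, _ = compute_followups(persons, make_fractures([]), CFG)
        fractures = make_fractures([("P1", "2006-01-01")])
        with pytest.raises(ValueError, match="outside follow-up"):
            tabulate(fu, None, fractures, CFG)

    def test_windows_truncated_to_followup(self):
        fu, win = _single_person_inputs([(5, 400)])  # runs far past death
        table = tabulate(fu, win, make_fractures([]), CFG)
        assert table.loc[table.exposure_state == "exposed", "person_days"].sum() == 5
        assert table["person_days"].sum() == 10


def test_tabulate_matches_bruteforce_on_random_cohort(small_registry, small_followups, small_classified):
    sub = small_classified[small_classified["group"] == "anxiolytics_total"]
    windows = merge_windows(windows_from_dispensings(sub, ExposurePolicy.fixed(7)))
    fast = tabulate(small_followups, windows, small_registry.fractures, CFG)
    slow = brute_force_tabulate(small_followups, windows, small_registry.fractures, CFG)
    pd.testing.assert_frame_equal(fast, slow)


def test_exclusion_windows_remove_reference_days(small_registry, small_followups, small_classified):
    """Mutually-exclusive sensitivity: days exposed to other groups leave
    the table entirely, so person-days shrink but never go negative."""
    from hipsir import subtract_windows

    anx = small_classified[small_classified["group"] == "anxiolytics_total"]
    hyp = small_classified[small_classified["group"] == "hypnotics_total"]
    pol = ExposurePolicy.ddd(1.0)
    w_anx = merge_windows(windows_from_dispensings(anx, pol))
    w_hyp = merge_windows(windows_from_dispensings(hyp, pol))
    exclude = subtract_windows(w_hyp, w_anx)
    full = tabulate(small_followups, w_anx, small_registry.fractures, CFG)
    red = tabulate(small_followups, w_anx, small_registry.fractures, CFG, exclude_windows=exclude)
    validate_table(red)
    assert red["person_days"].sum() < full["person_days"].sum()
    exp_full = full[full.exposure_state == "exposed"]["person_days"].sum()
    exp_red = red[red.exposure_state == "exposed"]["person_days"].sum()
    assert exp_red == exp_full  # exposed time to the analysed group untouched
    oracle = brute_force_tabulate(
        small_followups, w_anx, small_registry.fractures, CFG, exclude_windows=exclude
    )
    pd.testing.assert_frame_equal(red, oracle)


def test_validate_table_catches_inconsistencies(small_table):
    validate_table(small_table)
    broken = small_table.copy()
    broken.loc[broken.index[0], "events"] += 1
    with pytest.raises(ValueError, match="decompose"):
        validate_table(broken)
    with pytest.raises(ValueError, match="conserved"):
        validate_table(small_table, total_followup_days=1)
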