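"""Exposure-window construction: durations, merging, washout logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipsir import (
    ExposurePolicy,
    StudyConfig,
    assign_groups,
    merge_windows,
    recent_use_windows,
    subtract_windows,
    to_day,
    windows_from_dispensings,
)
from hipsir.exposure import duration_days, total_exposed_days

from conftest import make_dispensings

DDD1 = ExposurePolicy.ddd(1.0)
DDD05 = ExposurePolicy.ddd(0.5)


class TestDurationRule:
    def test_ddd_mode_divides_by_assumed_daily_dose(self):
        assert duration_days(25, DDD1) == [25]
        assert duration_days(25, DDD05) == [50]
        assert duration_days([10, 100], DDD05).tolist() == [20, 200]

    def test_fixed_mode_ignores_quantity(self):
        pol = ExposurePolicy.fixed(7)
        assert duration_days([1, 25, 1000], pol).tolist() == [7, 7, 7]

    def test_duration_at_least_one_day(self):
        assert duration_days(0.3, DDD1) == [1]

    def test_invalid_policies_rejected(self):
        with pytest.raises(ValueError):
            ExposurePolicy(mode="fixed_days")
        with pytest.raises(ValueError):
            ExposurePolicy(mode="ddd_days", pdd_factor=0)
        with pytest.raises(ValueError):
            ExposurePolicy(mode="weekly")

    def test_unconventional_values_allowed_but_flagged(self):
        assert not ExposurePolicy.fixed(10).is_conventional
        assert ExposurePolicy.fixed(14).is_conventional


def test_window_starts_on_purchase_day():
    disp = make_dispensings([("P1", "N05CF01", "zopiclone", "2005-03-01", 25)], group="z_hypnotic")
    w = windows_from_dispensings(disp, DDD1)
    assert w.loc[0, "start_day"] == to_day("2005-03-01")
    assert w.loc[0, "end_day"] == to_day("2005-03-25")


D0 = to_day("2005-01-01")


def _win(rows, group="g"):
    return pd.DataFrame(
        [("P1", group, D0 + s, D0 + e, "overall") for s, e in rows],
        columns=["person_id", "group", "start_day", "end_day", "origin"],
    )


@pytest.mark.parametrize(
    "rows,expected",
    [
        ([(1, 10), (5, 12)], [(1, 12)]),  # overlap
        ([(1, 3), (4, 6)], [(1, 6)]),  # adjacent days coalesce
        ([(1, 2), (10, 11)], [(1, 2), (10, 11)]),  # disjoint unchanged
        ([(1, 20), (5, 7)], [(1, 20)]),  # nested
        ([(4, 6), (1, 3)], [(1, 6)]),  # order-independent
    ],
)
def test_merge_windows_cases(rows, expected):
    got = merge_windows(_win(rows))
    assert [(s - D0, e - D0) for s, e in zip(got["start_day"], got["end_day"])] == expected


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    st.lists(
        st.tuples(st.integers(0, 400), st.integers(1, 60)).map(lambda t: (t[0], t[0] + t[1] - 1)),
        min_size=1,
        max_size=12,
    )
)
def test_merge_windows_equals_day_set_union(rows):
    """Merged intervals cover exactly the union of the input day sets."""
    got = merge_windows(_win(rows))
    days = set()
    for s, e in rows:
        days.update(range(s, e + 1))
    got_days = set()
    for s, e in zip(got["start_day"] - D0, got["end_day"] - D0):
        seg = set(range(s, e + 1))
        assert not got_days & seg  # disjoint
        got_days |= seg
    assert got_days == days
    # non-adjacent: consecutive merged intervals leave a gap of >= 1 day
    starts = got["start_day"].to_numpy()
    ends = got["end_day"].to_numpy()
    assert (starts[1:] > ends[:-1] + 1).all()


@settings(deadline=None, derandomize=True, max_examples=100)
@given(
    st.lists(st.tuples(st.integers(0, 200), st.integers(1, 40)), min_size=1, max_size=8),
    st.lists(st.tuples(st.integers(0, 200), st.integers(1, 40)), min_size=0, max_size=8),
)
def test_subtract_windows_equals_day_set_difference(a_rows, b_rows):
    a = merge_windows(_win([(s, s + d - 1) for s, d in a_rows]))
    b = merge_windows(_win([(s, s + d - 1) for s, d in b_rows], group="h"))
    got = subtract_windows(a, b)
    a_days = {d for s, e in zip(a["start_day"], a["end_day"]) for d in range(s, e + 1)}
    b_days = {d for s, e in zip(b["start_day"], b["end_day"]) for d in range(s, e + 1)}
    got_days = {d for s, e in zip(got["start_day"], got["end_day"]) for d in range(s, e + 1)}
    assert got_days == a_days - b_days


def test_shorter_assumed_daily_dose_never_shrinks_exposure(small_registry):
    """Halving the assumed daily dose (1.0 -> 0.5 DDD/day) lengthens every
    dispensing's window, so total exposed days cannot decrease."""
    classified = assign_groups(small_registry.dispensings)
    for group, sub in classified.groupby("group"):
        t1 = total_exposed_days(merge_windows(windows_from_dispensings(sub, DDD1)))
        t05 = total_exposed_days(merge_windows(windows_from_dispensings(sub, DDD05)))
        assert t05 >= t1


def test_recent_windows_subset_of_overall(small_registry):
    """Every recently-started exposed day is also an overall exposed day."""
    classified = assign_groups(small_registry.dispensings)
    sub = classified[classified["group"] == "hypnotics_total"]
    overall = merge_windows(windows_from_dispensings(sub, DDD1))
    recent, _ = recent_use_windows(sub, DDD1)
    assert len(recent) > 0
    leftovers = subtract_windows(recent, overall)
    assert len(leftovers) == 0


class TestRecentUse:
    def test_first_ever_use_gets_capped_window(self):
        disp = make_dispensings(
            [("P1", "N05CF01", "zopiclone", "2006-04-01", 25)], group="z_hypnotic"
        )
        w, diag = recent_use_windows(disp, DDD1)
        assert len(w) == 1
        assert w.loc[0, "start_day"] == to_day("2006-04-01")
        assert w.loc[0, "end_day"] == to_day("2006-04-14")
        assert w.loc[0, "origin"] == "recent"

    def test_dispensing_within_washout_not_recent(self):
        disp = make_dispensings(
            [
                ("P1", "N05CF01", "zopiclone", "2005-03-01", 25),
                ("P1", "N05CF01", "zopiclone", "2005-06-01", 25),
            ],
            group="z_hypnotic",
        )
        w, diag = recent_use_windows(disp, DDD1)
        assert len(w) == 1 and w.loc[0, "start_day"] == to_day("2005-03-01")
        assert diag["blocked_by_prior_exposure"] == 1

    def test_short_run_caps_recent_window(self):
        disp = make_dispensings(
            [("P1", "N05CF01", "zopiclone", "2006-04-01", 5)], group="z_hypnotic"
        )
        w, diag = recent_use_windows(disp, DDD1)
        assert len(w) == 1
        assert w.loc[0, "end_day"] - w.loc[0, "start_day"] + 1 == 5
        assert diag["short_runs"] == 1

    def test_unobservable_washout_skipped(self):
        disp = make_dispensings(
            [("P1", "N05CF01", "zopiclone", "2004-02-01", 10)], group="z_hypnotic"
        )
        w, diag = recent_use_windows(disp, DDD1)
        assert len(w) == 0
        assert diag["unobservable_washout"] == 1

    def test_group_specific_vs_any_drug_washout(self):
        """Prior exposure to another group blocks 'recent' only under the
        stricter any-drug washout scope."""
        disp = make_dispensings(
            [
                ("P1", "N05BA04", "oxazepam", "2005-02-01", 25),
                ("P1", "N05CF01", "zopiclone", "2005-06-01", 25),
            ]
        )
        classified = assign_groups(disp)
        w_group, _ = recent_use_windows(classified, DDD1, washout_scope="group")
        assert (w_group.groupby("group").size()["z_hypnotic"]) == 1
        w_any, _ = recent_use_windows(classified, DDD1, washout_scope="any")
        assert "z_hypnotic" not in set(w_any["group"])
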