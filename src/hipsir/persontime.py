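"""Decomposition of follow-up into stratified person-days.

Each cohort member is followed from the study start until the first of:
first hip fracture, death, emigration, or the end of the study period
(all end days inclusive).  Follow-up days are classified by stratum —
sex x birth year x two-month calendar bin — and by exposure state with
respect to one drug group under one exposure policy.  The aggregate
``PersonTimeTable`` (a tidy frame keyed by stratum and exposure state,
carrying person-days and event counts split by diurnal class) is the
sufficient statistic for every standardized incidence ratio downstream.

:func:`tabulate` is the production interval-arithmetic implementation;
:func:`brute_force_tabulate` materialises one record per person-day and
serves as its exact oracle on small inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .registry_io import StudyConfig

__all__ = [
    "TABLE_COLUMNS",
    "compute_followups",
    "tabulate",
    "brute_force_tabulate",
    "validate_table",
]

TABLE_COLUMNS = [
    "sex",
    "birth_year",
    "period",
    "exposure_state",
    "person_days",
    "events",
    "day_events",
    "night_events",
    "time_missing_events",
]

_REASON_PRIORITY = ["fracture", "death", "emigration", "study_end"]

_FAR = 10**9  # sentinel day beyond any date in use


def compute_followups(
    persons: pd.DataFrame,
    fractures: pd.DataFrame,
    config: StudyConfig | None = None,
):
    """Follow-up interval and end reason per person.

    The end day is the minimum of first-fracture day, death day,
    emigration day and the study end; ties resolve in that priority
    order (the distinction is immaterial for person-time).  Persons
    whose death or emigration precedes the study start contribute no
    follow-up and are counted in the returned diagnostics.

    Returns ``(followups, diagnostics)`` with columns
    ``person_id, sex, birth_year, start_day, end_day, end_reason``.
    """
    config = config or StudyConfig()
    start_day = config.study_start_day

    def _days(series):
        out = np.full(len(series), _FAR, dtype=np.int64)
        mask = series.notna().to_numpy()
        if mask.any():
            out[mask] = series[mask].values.astype("datetime64[D]").astype(np.int64)
        return out

    death = _days(persons["death_date"])
    emig = _days(persons["emigration_date"])

    ev = fractures.drop_duplicates("person_id").set_index("person_id")["event_date"]
    ev_day_map = pd.Series(
        ev.values.astype("datetime64[D]").astype(np.int64), index=ev.index
    )
    frac = (
        persons["person_id"].map(ev_day_map).fillna(_FAR).to_numpy(np.int64)
    )

    candidates = np.stack(
        [frac, death, emig, np.full(len(persons), config.study_end_day)]
    )
    end = candidates.min(axis=0)
    reason_idx = candidates.argmin(axis=0)  # argmin takes the first = priority order

    alive = end >= start_day
    diagnostics = {"censored_before_study_start": int((~alive).sum())}

    followups = pd.DataFrame(
        {
            "person_id": persons.loc[alive, "person_id"].to_numpy(),
            "sex": persons.loc[alive, "sex"].to_numpy(),
            "birth_year": persons.loc[alive, "birth_year"].to_numpy(np.int64),
            "start_day": start_day,
            "end_day": end[alive],
            "end_reason": np.array(_REASON_PRIORITY, dtype=object)[reason_idx[alive]],
        }
    ).reset_index(drop=True)
    return followups, diagnostics


def _event_frame(fractures: pd.DataFrame) -> pd.DataFrame:
    """Fractures with integer event day and diurnal class label."""
    from .diurnal import classify_times  # local import to avoid a cycle

    ev = fractures.copy()
    ev["event_day"] = ev["event_date"].values.astype("datetime64[D]").astype(np.int64)
    if "diurnal_class" not in ev.columns:
        ev["diurnal_class"] = classify_times(ev["event_time"])
    return ev


def _truncate_windows(windows, row_of_person, fs, fe):
    """Clip windows to each person's follow-up; returns row idx, starts, ends."""
    if windows is None or len(windows) == 0:
        return (np.empty(0, np.int64),) * 3
    rows = windows["person_id"].map(row_of_person).to_numpy()
    keep = ~pd.isna(rows)
    rows = rows[keep].astype(np.int64)
    ws = windows["start_day"].to_numpy(np.int64)[keep]
    we = windows["end_day"].to_numpy(np.int64)[keep]
    ws = np.maximum(ws, fs[rows])
    we = np.minimum(we, fe[rows])
    keep2 = ws <= we
    return rows[keep2], ws[keep2], we[keep2]


def _bin_overlaps(starts, ends, bin_starts, bin_ends):
    """Covered days per calendar bin for each interval: (n, P) matrix."""
    lo = np.maximum(starts[:, None], bin_starts[None, :])
    hi = np.minimum(ends[:, None], bin_ends[None, :])
    return np.clip(hi - lo + 1, 0, None)


def tabulate(
    followups: pd.DataFrame,
    windows: pd.DataFrame,
    fractures: pd.DataFrame,
    config: StudyConfig | None = None,
    exclude_windows: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate follow-up into the stratified person-time table.

    ``windows`` are merged exposure windows of a single drug group and
    policy; they are truncated to each person's follow-up here, so
    window construction never needs outcome data.  Each follow-up day
    lands in exactly one (stratum, exposure state) cell; each person's
    fracture (if any) is counted in the cell of its event date, split
    by diurnal class.

    ``exclude_windows``, if given, removes its person-days from the
    unexposed state entirely (mutually-exclusive sensitivity analysis:
    time exposed to *other* drug groups neither exposed nor reference).
    The caller must pass day sets disjoint from ``windows``; events on
    excluded days are dropped from the table.

    An event date outside its person's follow-up is a hard error, since
    follow-up by construction ends at the first fracture.
    """
    config = config or StudyConfig()
    bin_starts = config.period_bin_starts()
    n_periods = len(bin_starts)
    bin_ends = np.r_[bin_starts[1:] - 1, config.study_end_day]

    n = len(followups)
    fs = followups["start_day"].to_numpy(np.int64)
    fe = followups["end_day"].to_numpy(np.int64)
    strata, stratum_levels = pd.MultiIndex.from_arrays(
        [followups["sex"], followups["birth_year"]]
    ).factorize(sort=True)
    n_strata = len(stratum_levels)
    row_of_person = pd.Series(np.arange(n), index=followups["person_id"])

    total_pb = _bin_overlaps(fs, fe, bin_starts, bin_ends)

    exposed_pb = np.zeros((n, n_periods), dtype=np.int64)
    wrows, ws, we = _truncate_windows(windows, row_of_person, fs, fe)
    if len(wrows):
        np.add.at(exposed_pb, wrows, _bin_overlaps(ws, we, bin_starts, bin_ends))

    excluded_pb = np.zeros((n, n_periods), dtype=np.int64)
    xrows, xs, xe = _truncate_windows(exclude_windows, row_of_person, fs, fe)
    if len(xrows):
        np.add.at(excluded_pb, xrows, _bin_overlaps(xs, xe, bin_starts, bin_ends))

    unexposed_pb = total_pb - exposed_pb - excluded_pb
    if (exposed_pb > total_pb).any() or (unexposed_pb < 0).any():
        raise ValueError("windows overlap each other or exclude_windows; merge first")

    days = np.zeros((n_strata, n_periods, 2), dtype=np.int64)
    np.add.at(days, strata, np.stack([exposed_pb, unexposed_pb], axis=-1))

    # events: one fracture at most per person, on a follow-up day
    counts = {
        key: np.zeros((n_strata, n_periods, 2), dtype=np.int64)
        for key in ("events", "day_events", "night_events", "time_missing_events")
    }
    ev = _event_frame(fractures)
    ev_rows_raw = ev["person_id"].map(row_of_person)
    present = ev_rows_raw.notna().to_numpy()
    ev = ev[present]
    ev_rows = ev_rows_raw[present].to_numpy(np.int64)
    ev_day = ev["event_day"].to_numpy(np.int64)
    if len(ev) and ((ev_day < fs[ev_rows]) | (ev_day > fe[ev_rows])).any():
        bad = ev.loc[
            (ev_day < fs[ev_rows]) | (ev_day > fe[ev_rows]), "person_id"
        ].tolist()
        raise ValueError(f"event date outside follow-up for persons {bad[:5]}")

    if len(ev):
        in_win = _membership(ev_rows, ev_day, wrows, ws, we, n)
        in_exc = _membership(ev_rows, ev_day, xrows, xs, xe, n)
        keep = ~in_exc
        ev_rows, ev_day = ev_rows[keep], ev_day[keep]
        in_win = in_win[keep]
        klass = ev["diurnal_class"].to_numpy()[keep]
        ev_period = config.period_of_day(ev_day)
        ev_state = np.where(in_win, 0, 1)
        idx = (strata[ev_rows], ev_period, ev_state)
        np.add.at(counts["events"], idx, 1)
        for key, label in [
            ("day_events", "day"),
            ("night_events", "night"),
            ("time_missing_events", "unknown"),
        ]:
            m = klass == label
            if m.any():
                np.add.at(counts[key], (idx[0][m], idx[1][m], idx[2][m]), 1)

    sex_lv = np.array([s for s, _ in stratum_levels], dtype=object)
    by_lv = np.array([b for _, b in stratum_levels], dtype=np.int64)
    S, P = n_strata, n_periods
    grid_s = np.repeat(np.arange(S), P * 2)
    grid_p = np.tile(np.repeat(np.arange(P), 2), S)
    grid_e = np.tile([0, 1], S * P)
    table = pd.DataFrame(
        {
            "sex": sex_lv[grid_s],
            "birth_year": by_lv[grid_s],
            "period": grid_p,
            "exposure_state": np.where(grid_e == 0, "exposed", "unexposed"),
            "person_days": days[grid_s, grid_p, grid_e],
            "events": counts["events"][grid_s, grid_p, grid_e],
            "day_events": counts["day_events"][grid_s, grid_p, grid_e],
            "night_events": counts["night_events"][grid_s, grid_p, grid_e],
            "time_missing_events": counts["time_missing_events"][grid_s, grid_p, grid_e],
        }
    )
    table = table[(table["person_days"] > 0) | (table["events"] > 0)]
    return _canonical(table)


def _membership(rows, day, wrows, ws, we, n) -> np.ndarray:
    """Whether each (row, day) point lies in any of the row's windows."""
    if len(wrows) == 0:
        return np.zeros(len(rows), dtype=bool)
    big = np.int64(10**7)
    order = np.lexsort((ws, wrows))
    cstart = wrows[order] * big + ws[order]
    cend = wrows[order] * big + we[order]
    cpt = rows * big + day
    j = np.searchsorted(cstart, cpt, side="right") - 1
    ok = j >= 0
    ok[ok] = cend[j[ok]] >= cpt[ok]
    return ok


def brute_force_tabulate(
    followups: pd.DataFrame,
    windows: pd.DataFrame,
    fractures: pd.DataFrame,
    config: StudyConfig | None = None,
    exclude_windows: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Reference implementation of :func:`tabulate` by materialising one
    record per person-day.  Identical contract and output; intended for
    small inputs (roughly a million person-days) and testing.
    """
    config = config or StudyConfig()
    ev = _event_frame(fractures).set_index("person_id")
    win_by_person: dict = {}
    if windows is not None:
        for pid, g in windows.groupby("person_id", sort=False):
            win_by_person[pid] = list(zip(g["start_day"], g["end_day"]))
    exc_by_person: dict = {}
    if exclude_windows is not None:
        for pid, g in exclude_windows.groupby("person_id", sort=False):
            exc_by_person[pid] = list(zip(g["start_day"], g["end_day"]))

    parts = []
    for fu in followups.itertuples(index=False):
        days = np.arange(fu.start_day, fu.end_day + 1)
        in_any = np.zeros(len(days), dtype=bool)
        for s, e in win_by_person.get(fu.person_id, ()):
            in_any |= (days >= s) & (days <= e)
        excluded = np.zeros(len(days), dtype=bool)
        for s, e in exc_by_person.get(fu.person_id, ()):
            excluded |= (days >= s) & (days <= e)
        is_ev = np.zeros(len(days), dtype=bool)
        klass = None
        if fu.person_id in ev.index:
            rec = ev.loc[fu.person_id]
            ev_day, klass = int(rec["event_day"]), rec["diurnal_class"]
            if not (fu.start_day <= ev_day <= fu.end_day):
                raise ValueError(f"event date outside follow-up for {fu.person_id}")
            is_ev = days == ev_day
        keep = ~excluded
        days, in_any, is_ev = days[keep], in_any[keep], is_ev[keep]
        parts.append(
            pd.DataFrame(
                {
                    "sex": fu.sex,
                    "birth_year": fu.birth_year,
                    "period": config.period_of_day(days),
                    "exposure_state": np.where(in_any, "exposed", "unexposed"),
                    "person_days": 1,
                    "events": is_ev.astype(np.int64),
                    "day_events": (is_ev & (klass == "day")).astype(np.int64),
                    "night_events": (is_ev & (klass == "night")).astype(np.int64),
                    "time_missing_events": (is_ev & (klass == "unknown")).astype(np.int64),
                }
            )
        )
    if not parts:
        return _canonical(pd.DataFrame(columns=TABLE_COLUMNS))
    df = pd.concat(parts, ignore_index=True)
    table = (
        df.groupby(["sex", "birth_year", "period", "exposure_state"], as_index=False)
        .sum()
    )
    return _canonical(table)


def _canonical(table: pd.DataFrame) -> pd.DataFrame:
    out = table.reindex(columns=TABLE_COLUMNS).copy()
    for c in TABLE_COLUMNS[1:3] + TABLE_COLUMNS[4:]:
        out[c] = out[c].astype(np.int64) if len(out) else out[c]
    return (
        out.sort_values(["sex", "birth_year", "period", "exposure_state"], kind="stable")
        .reset_index(drop=True)
    )


def validate_table(table: pd.DataFrame, total_followup_days: int | None = None):
    """Check internal consistency of a person-time table.

    Raises ``ValueError`` on a violated invariant: non-negative counts,
    diurnal decomposition ``events = day + night + missing`` per cell,
    and (optionally) conservation of total person-days.
    """
    if (table["person_days"] < 0).any() or (table["events"] < 0).any():
        raise ValueError("negative person_days or events")
    split = table["day_events"] + table["night_events"] + table["time_missing_events"]
    if not (split == table["events"]).all():
        raise ValueError("diurnal classes do not decompose the event count")
    if total_followup_days is not None:
        got = int(table["person_days"].sum())
        if got != total_followup_days:
            raise ValueError(
                f"person-days not conserved: table {got} vs follow-up {total_followup_days}"
            )
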