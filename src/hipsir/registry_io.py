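"""Readers, writers and validation for the three registry-style tables.

The analysis consumes three person-linked tables, supplied as plain CSV
with ISO-8601 dates and 24-hour ``HH:MM`` clock times:

``persons.csv``
    ``person_id, sex, birth_year, death_date, emigration_date``
    One row per cohort member.  ``sex`` is ``female`` or ``male``;
    ``birth_year`` must be before 1945 (the cohort is people aged 60+
    at the start of follow-up); the two date columns may be empty.

``dispensings.csv``
    ``person_id, atc_code, substance, dispense_date, n_ddd``
    One row per pharmacy purchase.  ``n_ddd`` is the dispensed quantity
    in defined daily doses (DDD) and must be positive.  Dispensings from
    the calendar year before follow-up starts are required so that
    washout periods are observable.

``fractures.csv``
    ``person_id, event_date, event_time``
    One row per registered hip fracture.  ``event_time`` may be empty
    (clock time unknown).  Only each person's earliest fracture enters
    the analysis; follow-up ends there.

Readers return a ``(DataFrame, ReadReport)`` pair: every input row is
either accepted or rejected with a row-level diagnostic, and
``accepted + rejected == input`` always holds.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StudyConfig",
    "ReadReport",
    "read_persons",
    "read_dispensings",
    "read_fractures",
    "write_persons",
    "write_dispensings",
    "write_fractures",
    "to_day",
    "day_to_date",
]

_EPOCH_ORDINAL = dt.date(1970, 1, 1).toordinal()

SEX_VALUES = ("female", "male")

PERSON_COLUMNS = ["person_id", "sex", "birth_year", "death_date", "emigration_date"]
DISPENSING_COLUMNS = ["person_id", "atc_code", "substance", "dispense_date", "n_ddd"]
FRACTURE_COLUMNS = ["person_id", "event_date", "event_time", "time_known"]


def to_day(d) -> int:
    """Convert a date (or parseable string) to integer days since 1970-01-01."""
    if isinstance(d, str):
        d = dt.date.fromisoformat(d)
    if isinstance(d, pd.Timestamp):
        d = d.date()
    return d.toordinal() - _EPOCH_ORDINAL


def day_to_date(day: int) -> dt.date:
    return dt.date.fromordinal(int(day) + _EPOCH_ORDINAL)


@dataclass(frozen=True)
class StudyConfig:
    """Fixed design parameters of the cohort analysis.

    Defaults encode a six-year follow-up (2005-01-01 to 2010-12-31) of a
    cohort born before 1945, with dispensing history available from
    2004-01-01 so that a 360-day washout preceding any in-study
    dispensing is fully observable.  Night is 20:00-07:59 and day
    08:00-19:59; calendar time is stratified in two-month bins.
    """

    study_start: dt.date = dt.date(2005, 1, 1)
    study_end: dt.date = dt.date(2010, 12, 31)
    history_start: dt.date = dt.date(2004, 1, 1)
    birth_year_max: int = 1944
    washout_days: int = 360
    recent_use_days: int = 14
    night_start: dt.time = dt.time(20, 0)
    night_end: dt.time = dt.time(8, 0)  # exclusive; 07:59 is the last night minute
    calendar_bin_months: int = 2

    def __post_init__(self):
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        if self.history_start > self.study_start:
            raise ValueError("dispensing history must start at or before study_start")
        if self.washout_days <= 0 or self.recent_use_days <= 0:
            raise ValueError("washout_days and recent_use_days must be positive")
        if 12 % self.calendar_bin_months != 0:
            raise ValueError("calendar_bin_months must divide 12")

    @property
    def study_start_day(self) -> int:
        return to_day(self.study_start)

    @property
    def study_end_day(self) -> int:
        return to_day(self.study_end)

    @property
    def history_start_day(self) -> int:
        return to_day(self.history_start)

    def period_bin_starts(self) -> np.ndarray:
        """Day numbers of the calendar-bin starts covering the study period."""
        starts = []
        y, m = self.study_start.year, self.study_start.month
        while (y, m) <= (self.study_end.year, self.study_end.month):
            starts.append(to_day(dt.date(y, m, 1)))
            m += self.calendar_bin_months
            y, m = y + (m - 1) // 12, (m - 1) % 12 + 1
        return np.asarray(starts, dtype=np.int64)

    @property
    def n_periods(self) -> int:
        return len(self.period_bin_starts())

    def period_of_day(self, day) -> np.ndarray:
        """Calendar-bin index (0-based) for integer day numbers."""
        starts = self.period_bin_starts()
        idx = np.searchsorted(starts, np.asarray(day), side="right") - 1
        return idx


@dataclass
class ReadReport:
    """Row-accounting diagnostics from a reader: accepted + rejected = input."""

    n_input: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    n_duplicates_discarded: int = 0  # later fracture records of the same person
    reasons: dict = field(default_factory=dict)
    messages: list = field(default_factory=list)

    def reject(self, reason: str, detail: str = "", n: int = 1):
        self.n_rejected += n
        self.reasons[reason] = self.reasons.get(reason, 0) + n
        if detail and len(self.messages) < 50:
            self.messages.append(f"{reason}: {detail}")


def _read_csv(path, required_cols) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _parse_dates(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series.replace("", pd.NA), format="%Y-%m-%d", errors="coerce")


def read_persons(path, config: StudyConfig | None = None):
    """Load the persons table.

    Rows with a birth year at or after the cohort cutoff, an unparseable
    field, or a death/emigration date before the study start are
    rejected and counted.  A duplicated ``person_id`` is a hard error.
    """
    config = config or StudyConfig()
    raw = _read_csv(path, ["person_id", "sex", "birth_year"])
    report = ReadReport(n_input=len(raw))

    dup = raw["person_id"][raw["person_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate person_id values: {sorted(set(dup))[:10]}")

    birth = pd.to_numeric(raw["birth_year"], errors="coerce")
    death = _parse_dates(raw.get("death_date", pd.Series("", index=raw.index)))
    emig = _parse_dates(raw.get("emigration_date", pd.Series("", index=raw.index)))
    start = pd.Timestamp(config.study_start)

    ok = pd.Series(True, index=raw.index)
    bad_sex = ~raw["sex"].isin(SEX_VALUES)
    bad_birth = birth.isna() | (birth > config.birth_year_max)
    bad_death_parse = (raw.get("death_date", "") != "") & death.isna()
    bad_emig_parse = (raw.get("emigration_date", "") != "") & emig.isna()
    early_censor = (death.notna() & (death < start)) | (emig.notna() & (emig < start))

    for mask, reason in [
        (bad_sex, "invalid_sex"),
        (bad_birth & ~bad_sex, "birth_year_out_of_range"),
        ((bad_death_parse | bad_emig_parse) & ok, "unparseable_date"),
        (early_censor, "censored_before_study_start"),
    ]:
        mask = mask & ok
        if mask.any():
            ids = raw.loc[mask, "person_id"].tolist()
            report.reject(reason, detail=", ".join(ids[:5]), n=int(mask.sum()))
            ok &= ~mask

    out = pd.DataFrame(
        {
            "person_id": raw.loc[ok, "person_id"],
            "sex": raw.loc[ok, "sex"],
            "birth_year": birth[ok].astype(int),
            "death_date": death[ok],
            "emigration_date": emig[ok],
        }
    ).reset_index(drop=True)
    report.n_accepted = len(out)
    return out, report


def read_dispensings(path, persons: pd.DataFrame, config: StudyConfig | None = None):
    """Load the dispensings table, linking against already-loaded persons.

    Rows referencing an unknown person, with non-positive ``n_ddd``, an
    unparseable or pre-history date, or an empty ATC code are rejected.
    """
    config = config or StudyConfig()
    raw = _read_csv(path, DISPENSING_COLUMNS[:-1] + ["n_ddd"])
    report = ReadReport(n_input=len(raw))

    known = set(persons["person_id"])
    date = _parse_dates(raw["dispense_date"])
    n_ddd = pd.to_numeric(raw["n_ddd"], errors="coerce")
    hist = pd.Timestamp(config.history_start)

    ok = pd.Series(True, index=raw.index)
    for mask, reason in [
        (~raw["person_id"].isin(known), "unknown_person_id"),
        (date.isna(), "unparseable_date"),
        (date.notna() & (date < hist), "before_history_start"),
        (n_ddd.isna() | (n_ddd <= 0), "nonpositive_n_ddd"),
        (raw["atc_code"].str.strip() == "", "empty_atc_code"),
    ]:
        mask = mask & ok
        if mask.any():
            ids = raw.loc[mask, "person_id"].tolist()
            report.reject(reason, detail=", ".join(ids[:5]), n=int(mask.sum()))
            ok &= ~mask

    out = pd.DataFrame(
        {
            "person_id": raw.loc[ok, "person_id"],
            "atc_code": raw.loc[ok, "atc_code"].str.strip(),
            "substance": raw.loc[ok, "substance"].str.strip().str.lower(),
            "dispense_date": date[ok],
            "n_ddd": n_ddd[ok].astype(float),
        }
    ).reset_index(drop=True)
    report.n_accepted = len(out)
    return out, report


def _parse_times(series: pd.Series) -> pd.Series:
    parsed = pd.to_datetime(series.replace("", pd.NA), format="%H:%M", errors="coerce")
    return parsed


def read_fractures(path, persons: pd.DataFrame, config: StudyConfig | None = None):
    """Load fracture events, keeping only each person's earliest.

    Events outside the study period or referencing unknown persons are
    rejected; later events of a person who already has one are counted
    in ``n_duplicates_discarded`` (follow-up ends at the first
    fracture).  ``time_known`` is true iff a clock time was present.
    """
    config = config or StudyConfig()
    raw = _read_csv(path, ["person_id", "event_date"])
    if "event_time" not in raw.columns:
        raw["event_time"] = ""
    report = ReadReport(n_input=len(raw))

    known = set(persons["person_id"])
    date = _parse_dates(raw["event_date"])
    time_raw = raw["event_time"].str.strip()
    time_parsed = _parse_times(time_raw)
    start, end = pd.Timestamp(config.study_start), pd.Timestamp(config.study_end)

    ok = pd.Series(True, index=raw.index)
    for mask, reason in [
        (~raw["person_id"].isin(known), "unknown_person_id"),
        (date.isna(), "unparseable_date"),
        (date.notna() & ((date < start) | (date > end)), "outside_study_period"),
        ((time_raw != "") & time_parsed.isna(), "unparseable_time"),
    ]:
        mask = mask & ok
        if mask.any():
            ids = raw.loc[mask, "person_id"].tolist()
            report.reject(reason, detail=", ".join(ids[:5]), n=int(mask.sum()))
            ok &= ~mask

    kept = pd.DataFrame(
        {
            "person_id": raw.loc[ok, "person_id"],
            "event_date": date[ok],
            "event_time": time_raw[ok].where(time_parsed[ok].notna(), ""),
            "time_known": time_parsed[ok].notna(),
        }
    )
    # first event per person; among same-day records prefer one with a known time
    kept = kept.sort_values(
        ["person_id", "event_date", "time_known"],
        ascending=[True, True, False],
        kind="stable",
    )
    first = ~kept["person_id"].duplicated()
    report.n_duplicates_discarded = int((~first).sum())
    out = kept[first].reset_index(drop=True)
    report.n_accepted = len(out)
    return out, report


def _fmt_dates(series: pd.Series) -> pd.Series:
    return series.dt.strftime("%Y-%m-%d").fillna("")


def write_persons(persons: pd.DataFrame, path):
    out = persons.copy()
    out["death_date"] = _fmt_dates(out["death_date"])
    out["emigration_date"] = _fmt_dates(out["emigration_date"])
    out[PERSON_COLUMNS].to_csv(path, index=False)


def write_dispensings(dispensings: pd.DataFrame, path):
    out = dispensings.copy()
    out["dispense_date"] = _fmt_dates(out["dispense_date"])
    out[DISPENSING_COLUMNS].to_csv(path, index=False)


def write_fractures(fractures: pd.DataFrame, path):
    out = fractures.copy()
    out["event_date"] = _fmt_dates(out["event_date"])
    out[["person_id", "event_date", "event_time"]].to_csv(path, index=False)
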