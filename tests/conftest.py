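import numpy as np
import pandas as pd
import pytest

from hipsir import (
    ExposurePolicy,
    SimConfig,
    StudyConfig,
    assign_groups,
    compute_followups,
    merge_windows,
    simulate_registry,
    tabulate,
    windows_from_dispensings,
)

DDD = ExposurePolicy.ddd(1.0)


def single_group_config(n, seed, rho=1.0, rho_day=None, rho_night=None, age_coef=0.0):
    """A hypnotics-only simulation: 30% ever-users, chosen true rate ratio."""
    kw = dict(
        n_persons=n,
        seed=seed,
        ever_user_fraction={"hypnotics_total": 0.30},
        rate_ratio={"hypnotics_total": rho},
        ever_user_age_coef=age_coef,
    )
    if rho_day is not None:
        kw["rate_ratio_day"] = {"hypnotics_total": rho_day}
    if rho_night is not None:
        kw["rate_ratio_night"] = {"hypnotics_total": rho_night}
    return SimConfig(**kw)


def hypnotic_table(reg, policy=DDD, config=None):
    """Person-time table for hypnotics_total from a simulated registry."""
    config = config or StudyConfig()
    followups, _ = compute_followups(reg.persons, reg.fractures, config)
    classified = assign_groups(reg.dispensings)
    sub = classified[classified["group"] == "hypnotics_total"]
    windows = merge_windows(windows_from_dispensings(sub, policy))
    return tabulate(followups, windows, reg.fractures, config)


def crude_table(table):
    """Collapse all strata: the unadjusted comparison."""
    out = table.copy()
    out["sex"] = "all"
    out["birth_year"] = 0
    out["period"] = 0
    return out


@pytest.fixture(scope="session")
def small_registry():
    """A 2,000-person default-condition registry shared across tests."""
    return simulate_registry(SimConfig(n_persons=2000, seed=1234))


@pytest.fixture(scope="session")
def small_followups(small_registry):
    followups, _ = compute_followups(small_registry.persons, small_registry.fractures)
    return followups


@pytest.fixture(scope="session")
def small_classified(small_registry):
    return assign_groups(small_registry.dispensings)


@pytest.fixture(scope="session")
def small_table(small_registry):
    return hypnotic_table(small_registry)


def make_persons(rows):
    """Persons frame from (person_id, sex, birth_year[, death, emigration]) tuples."""
    recs = []
    for r in rows:
        pid, sex, by = r[:3]
        death = r[3] if len(r) > 3 else None
        emig = r[4] if len(r) > 4 else None
        recs.append(
            {
                "person_id": pid,
                "sex": sex,
                "birth_year": by,
                "death_date": pd.Timestamp(death) if death else pd.NaT,
                "emigration_date": pd.Timestamp(emig) if emig else pd.NaT,
            }
        )
    return pd.DataFrame(recs)


def make_dispensings(rows, group=None):
    """Dispensings frame from (person_id, atc, substance, date, n_ddd) tuples.

    With ``group`` set, returns the classified (exploded) layout with a
    fixed group label instead of ATC/substance columns.
    """
    df = pd.DataFrame(
        rows, columns=["person_id", "atc_code", "substance", "dispense_date", "n_ddd"]
    )
    df["dispense_date"] = pd.to_datetime(df["dispense_date"])
    df["n_ddd"] = df["n_ddd"].astype(float)
    if group is not None:
        df["group"] = group
    return df


def make_fractures(rows):
    """Fractures frame from (person_id, date[, time]) tuples."""
    if not rows:
        return pd.DataFrame(
            {
                "person_id": pd.Series(dtype=object),
                "event_date": pd.Series(dtype="datetime64[ns]"),
                "event_time": pd.Series(dtype=object),
                "time_known": pd.Series(dtype=bool),
            }
        )
    recs = []
    for r in rows:
        pid, date = r[:2]
        time = r[2] if len(r) > 2 else ""
        recs.append(
            {
                "person_id": pid,
                "event_date": pd.Timestamp(date),
                "event_time": time,
                "time_known": bool(time),
            }
        )
    return pd.DataFrame(recs)
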