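"""Exposure-window construction from dispensing records.

A pharmacy dispensing is converted into a closed interval of exposed
days starting on the purchase day.  Because registries record neither
the prescribed daily dose nor actual intake, the exposed duration is an
assumption, selectable per analysis:

* ``fixed_days`` — a fixed window (3, 7 or 14 days) per dispensing,
  regardless of quantity;
* ``ddd_days`` — the dispensed number of defined daily doses (DDD)
  divided by an assumed daily consumption of 0.5 or 1.0 DDD/day.

Windows of one person and drug group are merged by set union on days —
overlapping or adjacent windows coalesce, with no carry-forward of
leftover supply.  "Recently started" use is the first 14 days of an
exposure run preceded by a 360-day washout with no exposed day to the
same group; runs shorter than 14 days yield correspondingly shorter
recent windows.

All functions work on integer day numbers (days since 1970-01-01, see
:func:`hipsir.registry_io.to_day`) in tidy frames with columns
``person_id, group, start_day, end_day, origin``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry_io import StudyConfig, to_day

__all__ = [
    "ExposurePolicy",
    "duration_days",
    "windows_from_dispensings",
    "merge_windows",
    "subtract_windows",
    "recent_use_windows",
    "total_exposed_days",
]

WINDOW_COLUMNS = ["person_id", "group", "start_day", "end_day", "origin"]

FIXED_DAY_CHOICES = (3, 7, 14)
PDD_FACTOR_CHOICES = (0.5, 1.0)


@dataclass(frozen=True)
class ExposurePolicy:
    """One assumed-exposure-duration rule.

    ``mode='fixed_days'`` uses ``fixed_days`` per dispensing;
    ``mode='ddd_days'`` uses ``ceil(n_ddd / pdd_factor)`` days, i.e. the
    dispensed DDDs at an assumed daily dose of ``pdd_factor`` DDD/day.
    Values outside the conventional sets (3/7/14 days; 0.5/1.0) are
    allowed but flagged via :attr:`is_conventional`.
    """

    mode: str
    fixed_days: int | None = None
    pdd_factor: float | None = None

    def __post_init__(self):
        if self.mode == "fixed_days":
            if not (isinstance(self.fixed_days, int) and self.fixed_days >= 1):
                raise ValueError("fixed_days mode requires a positive integer fixed_days")
            if self.pdd_factor is not None:
                raise ValueError("pdd_factor is not used in fixed_days mode")
        elif self.mode == "ddd_days":
            if not (self.pdd_factor and self.pdd_factor > 0):
                raise ValueError("ddd_days mode requires a positive pdd_factor")
            if self.fixed_days is not None:
                raise ValueError("fixed_days is not used in ddd_days mode")
        else:
            raise ValueError(f"unknown exposure mode {self.mode!r}")

    @property
    def is_conventional(self) -> bool:
        if self.mode == "fixed_days":
            return self.fixed_days in FIXED_DAY_CHOICES
        return self.pdd_factor in PDD_FACTOR_CHOICES

    @property
    def label(self) -> str:
        if self.mode == "fixed_days":
            return f"fixed{self.fixed_days}"
        return f"ddd{self.pdd_factor:g}"

    @classmethod
    def fixed(cls, days: int) -> "ExposurePolicy":
        return cls(mode="fixed_days", fixed_days=days)

    @classmethod
    def ddd(cls, pdd_factor: float = 1.0) -> "ExposurePolicy":
        return cls(mode="ddd_days", pdd_factor=pdd_factor)


def duration_days(n_ddd, policy: ExposurePolicy) -> np.ndarray:
    """Exposed days per dispensing (vectorised), always >= 1."""
    n_ddd = np.asarray(n_ddd, dtype=float)
    if policy.mode == "fixed_days":
        dur = np.full(n_ddd.shape, policy.fixed_days, dtype=np.int64)
    else:
        dur = np.ceil(n_ddd / policy.pdd_factor).astype(np.int64)
    return np.maximum(dur, 1)


def windows_from_dispensings(
    dispensings: pd.DataFrame, policy: ExposurePolicy, origin: str = "overall"
) -> pd.DataFrame:
    """Per-dispensing exposure windows, one row per (dispensing, group).

    ``dispensings`` must already carry a ``group`` column (see
    :func:`hipsir.drug_classification.assign_groups`).  The window is
    ``[dispense day, dispense day + duration - 1]``, closed on both
    ends: a fracture on the purchase day counts as exposed.
    """
    if "group" not in dispensings.columns:
        raise ValueError("dispensings must be classified first (missing 'group' column)")
    if "dispense_day" in dispensings.columns:
        start = dispensings["dispense_day"].to_numpy(np.int64)
    else:
        start = (
            dispensings["dispense_date"].values.astype("datetime64[D]").astype(np.int64)
        )
    dur = duration_days(dispensings["n_ddd"].to_numpy(), policy)
    return pd.DataFrame(
        {
            "person_id": dispensings["person_id"].to_numpy(),
            "group": dispensings["group"].to_numpy(),
            "start_day": start,
            "end_day": start + dur - 1,
            "origin": origin,
        }
    )


def _block_prefix_max(values: np.ndarray, block_id: np.ndarray) -> np.ndarray:
    """Running maximum of ``values`` restarting at each new block id.

    Blocks must be contiguous and ``block_id`` nondecreasing.
    """
    if len(values) == 0:
        return values.copy()
    span = values.max() - values.min() + 2
    shifted = values + block_id.astype(np.int64) * span
    return np.maximum.accumulate(shifted) - block_id.astype(np.int64) * span


def merge_windows(windows: pd.DataFrame) -> pd.DataFrame:
    """Coalesce windows of each (person, group, origin) into maximal
    disjoint closed intervals.

    Overlapping and adjacent (gap of zero days) windows merge; the
    output day set equals the union of the input day sets.
    """
    if len(windows) == 0:
        return windows.reindex(columns=WINDOW_COLUMNS).iloc[:0].copy()
    w = windows.sort_values(
        ["person_id", "group", "origin", "start_day", "end_day"], kind="stable"
    ).reset_index(drop=True)
    key = (
        w["person_id"].astype(str) + "\x00" + w["group"].astype(str) + "\x00" + w["origin"]
    )
    block = (key != key.shift()).cumsum().to_numpy(np.int64)
    start = w["start_day"].to_numpy(np.int64)
    end = w["end_day"].to_numpy(np.int64)
    run_end = _block_prefix_max(end, block)
    new_run = np.ones(len(w), dtype=bool)
    new_run[1:] = (block[1:] != block[:-1]) | (start[1:] > run_end[:-1] + 1)
    run_id = np.cumsum(new_run) - 1
    first = np.flatnonzero(new_run)
    merged_end = np.maximum.reduceat(run_end, first)
    out = w.iloc[first, :][["person_id", "group", "origin"]].reset_index(drop=True)
    out.insert(2, "start_day", start[first])
    out.insert(3, "end_day", merged_end)
    return out[WINDOW_COLUMNS]


def subtract_windows(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Day-set difference ``a \\ b`` per person (groups/origins of ``a`` kept).

    Both inputs should be merged windows; ``b`` is matched on
    ``person_id`` only, so it can represent exposure to *other* drug
    groups to be excised from ``a``'s day sets.
    """
    if len(a) == 0 or len(b) == 0:
        return a.copy()
    out_rows = []
    b_by_person = {
        pid: (g["start_day"].to_numpy(), g["end_day"].to_numpy())
        for pid, g in b.groupby("person_id", sort=False)
    }
    for row in a.itertuples(index=False):
        cuts = b_by_person.get(row.person_id)
        if cuts is None:
            out_rows.append(row)
            continue
        s, e = row.start_day, row.end_day
        cur = s
        for cs, ce in zip(*cuts):
            if ce < cur or cs > e:
                continue
            if cs > cur:
                out_rows.append(row._replace(start_day=cur, end_day=cs - 1))
            cur = max(cur, ce + 1)
            if cur > e:
                break
        if cur <= e:
            out_rows.append(row._replace(start_day=cur, end_day=e))
    return pd.DataFrame(out_rows, columns=a.columns).reset_index(drop=True)


def total_exposed_days(windows: pd.DataFrame) -> int:
    """Total covered days of a merged window set."""
    if len(windows) == 0:
        return 0
    return int((windows["end_day"] - windows["start_day"] + 1).sum())


def recent_use_windows(
    dispensings: pd.DataFrame,
    policy: ExposurePolicy,
    config: StudyConfig | None = None,
    washout_scope: str = "group",
):
    """Windows of recently started use: the first ``recent_use_days``
    (default 14) of an exposure run whose start is preceded by
    ``washout_days`` (default 360) with no exposed day.

    ``washout_scope='group'`` checks the washout against exposure to the
    same drug group ("the drug in question"); ``'any'`` checks against
    exposure to any studied group (stricter sensitivity variant).  A
    candidate whose washout interval extends before the start of the
    available dispensing history cannot be verified and is skipped;
    such candidates are counted in the returned diagnostics.  If an
    exposure run is shorter than ``recent_use_days`` the recent window
    is capped at the run length (counted in diagnostics as
    ``short_runs``).

    Returns ``(windows, diagnostics)`` where windows have
    ``origin='recent'``.
    """
    config = config or StudyConfig()
    if washout_scope not in ("group", "any"):
        raise ValueError("washout_scope must be 'group' or 'any'")
    diagnostics = {"unobservable_washout": 0, "blocked_by_prior_exposure": 0, "short_runs": 0}

    per_disp = windows_from_dispensings(dispensings, policy)
    merged = merge_windows(per_disp)
    if washout_scope == "any":
        ref = merged.assign(group="__any__")
        ref = merge_windows(ref)
    else:
        ref = merged

    runs_by_key = {
        key: (g["start_day"].to_numpy(), g["end_day"].to_numpy())
        for key, g in ref.groupby(["person_id", "group"], sort=False)
    }
    own_runs_by_key = {
        key: (g["start_day"].to_numpy(), g["end_day"].to_numpy())
        for key, g in merged.groupby(["person_id", "group"], sort=False)
    }

    rows = []
    for (pid, grp), g in per_disp.groupby(["person_id", "group"], sort=False):
        ref_key = (pid, "__any__") if washout_scope == "any" else (pid, grp)
        ref_starts, ref_ends = runs_by_key[ref_key]
        own_starts, own_ends = own_runs_by_key[(pid, grp)]
        for d in np.unique(g["start_day"].to_numpy()):
            if d - config.washout_days < config.history_start_day:
                diagnostics["unobservable_washout"] += 1
                continue
            # run (in washout-reference set) containing day d
            j = int(np.searchsorted(ref_starts, d, side="right")) - 1
            if j >= 0 and ref_starts[j] < d and ref_ends[j] >= d - 1:
                diagnostics["blocked_by_prior_exposure"] += 1  # d-1 already exposed
                continue
            if j > 0 and ref_ends[j - 1] >= d - config.washout_days:
                diagnostics["blocked_by_prior_exposure"] += 1
                continue
            # exposure run of the group itself, for the run-length cap
            k = int(np.searchsorted(own_starts, d, side="right")) - 1
            run_end = int(own_ends[k])
            end = min(d + config.recent_use_days - 1, run_end)
            if end - d + 1 < config.recent_use_days:
                diagnostics["short_runs"] += 1
            rows.append((pid, grp, int(d), end, "recent"))

    out = pd.DataFrame(rows, columns=WINDOW_COLUMNS)
    return merge_windows(out), diagnostics
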