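"""End-to-end orchestration: read -> classify -> window -> tabulate ->
estimate -> report.

An :class:`AnalysisPlan` lists (group, policy, subset) analyses.  The
person-time table for each (group, policy, origin) combination is
computed once; sex and birth-cohort subsets then only filter its
stratum cells, and diurnal analyses reuse its class-specific event
columns, so a full plan costs little more than its distinct exposure
definitions.  All analysis is deterministic; randomness exists only in
the synthetic-data generator.
"""

from __future__ import annotations

import hashlib
import sys
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .diurnal import diurnal_sir
from .drug_classification import GROUP_IDS, assign_groups
from .exposure import (
    ExposurePolicy,
    merge_windows,
    recent_use_windows,
    subtract_windows,
    windows_from_dispensings,
)
from .persontime import compute_followups, tabulate, validate_table
from .registry_io import StudyConfig
from .sir import SIRResult, sir_from_table

__all__ = ["Analysis", "AnalysisPlan", "default_plan", "run", "results_frame"]

# birth cohorts used for presentation; they partition all years < 1945
COHORT_BINS = {
    "1935-1944": (1935, 1944),
    "1925-1934": (1925, 1934),
    "1915-1924": (1915, 1924),
    "<1915": (None, 1914),
}


@dataclass(frozen=True)
class Analysis:
    """One planned SIR analysis.

    ``origin`` selects overall vs recently-started exposure windows;
    ``sex``/``cohort`` restrict the strata; ``diurnal`` ('day'/'night')
    switches to the class-specific event counts.
    """

    group: str
    policy: ExposurePolicy
    origin: str = "overall"
    sex: str | None = None
    cohort: str | None = None
    diurnal: str | None = None

    def __post_init__(self):
        if self.group not in GROUP_IDS:
            raise ValueError(f"unknown drug group {self.group!r}")
        if self.origin not in ("overall", "recent"):
            raise ValueError("origin must be 'overall' or 'recent'")
        if self.cohort is not None and self.cohort not in COHORT_BINS:
            raise ValueError(f"unknown birth cohort {self.cohort!r}")
        if self.diurnal not in (None, "day", "night"):
            raise ValueError("diurnal must be None, 'day' or 'night'")

    @property
    def subset_label(self) -> str:
        parts = []
        if self.origin == "recent":
            parts.append("recent")
        if self.sex:
            parts.append(self.sex)
        if self.cohort:
            parts.append(self.cohort)
        if self.diurnal:
            parts.append(self.diurnal)
        return "+".join(parts) or "overall"


@dataclass
class AnalysisPlan:
    analyses: list = field(default_factory=list)

    def add(self, *args, **kwargs) -> "AnalysisPlan":
        self.analyses.append(Analysis(*args, **kwargs))
        return self


TABLE2_GROUPS = [
    "anxiolytics_total",
    "short_acting_benzodiazepine",
    "long_acting_benzodiazepine",
    "hypnotics_total",
    "z_hypnotic",
    "any_benzo_or_like",
]


def default_plan(policy: ExposurePolicy | None = None) -> AnalysisPlan:
    """The standard report plan: the six main drug-group columns, each
    overall and by sex and birth cohort (one exposure policy)."""
    policy = policy or ExposurePolicy.ddd(1.0)
    plan = AnalysisPlan()
    for group in TABLE2_GROUPS:
        plan.add(group, policy)
        for sex in ("female", "male"):
            plan.add(group, policy, sex=sex)
        for cohort in COHORT_BINS:
            plan.add(group, policy, cohort=cohort)
    return plan


def _filter_cells(table: pd.DataFrame, sex=None, cohort=None) -> pd.DataFrame:
    out = table
    if sex is not None:
        out = out[out["sex"] == sex]
    if cohort is not None:
        lo, hi = COHORT_BINS[cohort]
        if lo is not None:
            out = out[out["birth_year"] >= lo]
        out = out[out["birth_year"] <= hi]
    return out


def run(
    persons: pd.DataFrame,
    dispensings: pd.DataFrame,
    fractures: pd.DataFrame,
    plan: AnalysisPlan,
    config: StudyConfig | None = None,
    method: str = "exact",
    washout_scope: str = "group",
    exclusive_exposure: bool = False,
    log=None,
):
    """Execute a plan; returns ``(results, manifest)``.

    ``results`` is a list of :class:`~hipsir.sir.SIRResult`;
    ``manifest`` records inputs, config, warnings and per-stage
    diagnostics.  With ``exclusive_exposure`` person-days exposed to
    studied groups *other* than the analysed one are excluded from the
    reference (unexposed) time, as a sensitivity analysis.
    """
    config = config or StudyConfig()
    log = log or (lambda msg: print(msg, file=sys.stderr))
    for a in plan.analyses:  # validate the full plan before any computation
        assert isinstance(a, Analysis)

    followups, fu_diag = compute_followups(persons, fractures, config)
    total_days = int((followups["end_day"] - followups["start_day"] + 1).sum())
    classified = assign_groups(dispensings)
    log(
        f"cohort: {len(followups)} persons, {total_days} person-days, "
        f"{len(fractures)} first fractures; {fu_diag['censored_before_study_start']} "
        "persons censored before study start"
    )
    known = int(fractures["time_known"].sum()) if "time_known" in fractures else 0
    if len(fractures):
        log(f"fracture clock time known for {known}/{len(fractures)} "
            f"({100 * known / len(fractures):.0f}%)")

    manifest = {
        "version": __version__,
        "config": {
            "study_start": str(config.study_start),
            "study_end": str(config.study_end),
            "washout_days": config.washout_days,
            "recent_use_days": config.recent_use_days,
            "calendar_bin_months": config.calendar_bin_months,
            "method": method,
            "washout_scope": washout_scope,
            "exclusive_exposure": exclusive_exposure,
        },
        "inputs": {
            "n_persons": len(persons),
            "n_dispensings": len(dispensings),
            "n_fractures": len(fractures),
            "checksums": {
                "persons": _frame_checksum(persons),
                "dispensings": _frame_checksum(dispensings),
                "fractures": _frame_checksum(fractures),
            },
        },
        "diagnostics": {"followup": fu_diag, "analyses": {}},
    }

    tables: dict = {}
    results: list[SIRResult] = []
    for a in plan.analyses:
        key = (a.group, a.policy, a.origin)
        if key not in tables:
            tables[key] = _build_table(
                classified, followups, fractures, a, config,
                washout_scope, exclusive_exposure, manifest, log,
            )
        table = _filter_cells(tables[key], sex=a.sex, cohort=a.cohort)
        ctx = dict(group=a.group, policy=a.policy.label, subset=a.subset_label)
        try:
            if a.diurnal:
                res = diurnal_sir(table, a.diurnal, method=method, **ctx)
            else:
                res = sir_from_table(table, method=method, **ctx)
        except ValueError as err:
            # sparse subset with no estimable expectation: report the
            # counts, leave the estimate undefined, and keep going
            col = f"{a.diurnal}_events" if a.diurnal else "events"
            res = SIRResult(
                observed=int(table.loc[table.exposure_state == "exposed", col].sum()),
                expected=float("nan"),
                sir=float("nan"),
                ci_low=float("nan"),
                ci_high=float("nan"),
                n_total=int(table[col].sum()),
                event_class=a.diurnal or "all",
                method=method,
                meta={"error": str(err)},
                **ctx,
            )
            manifest["diagnostics"].setdefault("unestimable", []).append(
                f"{a.group}/{a.policy.label}/{a.subset_label}: {err}"
            )
            log(f"{a.group}/{a.policy.label}/{a.subset_label}: not estimable ({err})")
        if res.n_degenerate_strata:
            log(
                f"{a.group}/{a.policy.label}/{a.subset_label}: "
                f"{res.n_degenerate_strata} strata with exposed but no unexposed time"
            )
        results.append(res)
    return results, manifest


def _build_table(
    classified, followups, fractures, a, config, washout_scope,
    exclusive_exposure, manifest, log,
):
    sub = classified[classified["group"] == a.group]
    if a.origin == "recent":
        windows, diag = recent_use_windows(sub, a.policy, config, washout_scope)
        manifest["diagnostics"]["analyses"][f"{a.group}/{a.policy.label}/recent"] = diag
    else:
        windows = merge_windows(windows_from_dispensings(sub, a.policy))
    exclude = None
    if exclusive_exposure:
        others = classified[classified["group"] != a.group].assign(group="__other__")
        other_windows = merge_windows(windows_from_dispensings(others, a.policy))
        exclude = subtract_windows(other_windows, windows)
    table = tabulate(followups, windows, fractures, config, exclude_windows=exclude)
    if exclude is None:
        total = int((followups["end_day"] - followups["start_day"] + 1).sum())
        validate_table(table, total_followup_days=total)
    else:
        validate_table(table)
    return table


def _frame_checksum(df: pd.DataFrame) -> str:
    payload = df.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def results_frame(results: list[SIRResult]) -> pd.DataFrame:
    """Tidy results table (one row per analysis), report-ready."""
    rows = []
    for r in results:
        rows.append(
            {
                "group": r.group,
                "policy": r.policy,
                "subset": r.subset,
                "event_class": r.event_class,
                "observed": r.observed,
                "expected": round(r.expected, 2),
                "sir": round(r.sir, 3),
                "ci_low": round(r.ci_low, 3),
                "ci_high": round(r.ci_high, 3),
                "attributable_risk_pct": (
                    round(100 * r.attributable_risk, 2)
                    if r.attributable_risk is not None
                    else None
                ),
                "n_total": r.n_total,
            }
        )
    return pd.DataFrame(rows)
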