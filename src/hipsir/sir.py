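"""Standardized incidence ratios and attributable risk.

The SIR compares the fracture incidence during exposed person-time with
the incidence expected if exposed time had carried the unexposed rates,
stratum by stratum (indirect standardization).  With strata s indexed
by sex x birth year x two-month calendar bin:

    rate_s = events_unexposed_s / person_days_unexposed_s
    E      = sum_s  rate_s * person_days_exposed_s
    SIR    = O / E,      O = events observed during exposure

The 95% interval treats O as Poisson with E fixed, using the exact
(chi-square / gamma quantile) bounds by default; Byar's approximation
is available for comparison.  The attributable risk is

    AR = (O - E) / N_total

with N_total the number of observed fractures in the analysis
population — the fraction of all fractures attributable to exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SIRResult",
    "expected_events",
    "poisson_ci_exact",
    "poisson_ci_byar",
    "sir_estimate",
    "attributable_risk",
    "sir_from_table",
]


@dataclass
class SIRResult:
    """One standardized-incidence-ratio analysis.

    ``attributable_risk`` is a fraction of all fractures (0.05 = 5%);
    ``subset`` documents any restriction (sex, birth cohort, recent
    use, diurnal class) applied before estimation.
    """

    observed: int
    expected: float
    sir: float
    ci_low: float
    ci_high: float
    attributable_risk: float | None = None
    n_total: int | None = None
    group: str | None = None
    policy: str | None = None
    subset: str = "overall"
    event_class: str = "all"
    method: str = "exact"
    n_degenerate_strata: int = 0
    meta: dict = field(default_factory=dict)

    def rounded(self) -> dict:
        """Report-style rounding: SIR and CI to 1 decimal, AR to 0.1%."""
        out = {
            "n": self.observed,
            "sir": round(self.sir, 1),
            "ci_low": round(self.ci_low, 1),
            "ci_high": round(self.ci_high, 1),
        }
        if self.attributable_risk is not None:
            out["attributable_risk_pct"] = round(100 * self.attributable_risk, 1)
        return out


def _stratum_margins(table: pd.DataFrame, event_col: str) -> pd.DataFrame:
    keys = ["sex", "birth_year", "period"]
    piv = table.pivot_table(
        index=keys,
        columns="exposure_state",
        values=["person_days", event_col],
        aggfunc="sum",
        fill_value=0,
    )
    out = pd.DataFrame(index=piv.index)
    for col, state, name in [
        ("person_days", "exposed", "days_exposed"),
        ("person_days", "unexposed", "days_unexposed"),
        (event_col, "exposed", "events_exposed"),
        (event_col, "unexposed", "events_unexposed"),
    ]:
        out[name] = piv[col][state] if (col, state) in piv.columns else 0
    return out.reset_index()


def expected_events(table: pd.DataFrame, event_col: str = "events"):
    """Expected exposed events under stratum-specific unexposed rates.

    Returns ``(E, breakdown)`` where the breakdown frame carries, per
    stratum, the margins, the unexposed rate and the contribution to E.
    Strata holding exposed person-time but no unexposed person-time
    cannot contribute an expectation; they are flagged ``degenerate``
    and contribute zero.  If every stratum with exposed time is
    degenerate, no expectation is estimable and a ``ValueError`` is
    raised.
    """
    m = _stratum_margins(table, event_col)
    with np.errstate(divide="ignore", invalid="ignore"):
        m["rate"] = np.where(
            m["days_unexposed"] > 0, m["events_unexposed"] / m["days_unexposed"], np.nan
        )
    m["degenerate"] = (m["days_exposed"] > 0) & (m["days_unexposed"] == 0)
    m["contribution"] = np.where(
        m["degenerate"] | (m["days_exposed"] == 0), 0.0, m["rate"] * m["days_exposed"]
    )
    has_exposed = m["days_exposed"] > 0
    if has_exposed.any() and bool(m.loc[has_exposed, "degenerate"].all()):
        raise ValueError("no estimable expectation: all exposed strata lack unexposed time")
    return float(m["contribution"].sum()), m


def poisson_ci_exact(observed: int, alpha: float = 0.05):
    """Exact two-sided Poisson interval for a count (chi-square form)."""
    o = int(observed)
    if o < 0:
        raise ValueError("observed count must be non-negative")
    low = 0.0 if o == 0 else stats.chi2.ppf(alpha / 2, 2 * o) / 2
    high = stats.chi2.ppf(1 - alpha / 2, 2 * o + 2) / 2
    return low, high


def poisson_ci_byar(observed: int, alpha: float = 0.05):
    """Byar's approximation to the Poisson interval (deviates mostly at
    small counts; kept for comparison with the exact bounds)."""
    o = int(observed)
    z = stats.norm.ppf(1 - alpha / 2)
    if o == 0:
        return 0.0, poisson_ci_exact(0, alpha)[1]
    low = o * (1 - 1 / (9 * o) - z / (3 * np.sqrt(o))) ** 3
    op = o + 1
    high = op * (1 - 1 / (9 * op) + z / (3 * np.sqrt(op))) ** 3
    return low, high


def sir_estimate(
    observed: int, expected: float, method: str = "exact", alpha: float = 0.05
):
    """Point estimate and CI of the SIR: ``(sir, ci_low, ci_high)``.

    ``observed = 0`` yields a zero estimate with a one-sided upper
    bound; ``expected = 0`` is undefined and raises.
    """
    if expected <= 0:
        raise ValueError("SIR undefined for non-positive expected count")
    ci = {"exact": poisson_ci_exact, "byar": poisson_ci_byar}[method](observed, alpha)
    return observed / expected, ci[0] / expected, ci[1] / expected


def attributable_risk(observed: int, expected: float, n_total: int) -> float:
    """Fraction of all fractures attributable to exposure: (O - E)/N.

    Negative when exposure is protective (E > O).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_total < observed:
        raise ValueError("n_total cannot be smaller than the observed exposed count")
    return (observed - expected) / n_total


def sir_from_table(
    table: pd.DataFrame,
    event_col: str = "events",
    n_total: int | None = None,
    method: str = "exact",
    alpha: float = 0.05,
    **meta,
) -> SIRResult:
    """Full SIR analysis of a person-time table.

    O is the ``event_col`` sum over exposed cells; E comes from
    :func:`expected_events`; ``n_total`` defaults to the ``event_col``
    total over the whole table (all fractures in the analysis
    population), the denominator of the attributable risk.
    """
    exposed = table[table["exposure_state"] == "exposed"]
    observed = int(exposed[event_col].sum())
    e, breakdown = expected_events(table, event_col=event_col)
    if n_total is None:
        n_total = int(table[event_col].sum())
    sir, lo, hi = sir_estimate(observed, e, method=method, alpha=alpha)
    ar = attributable_risk(observed, e, n_total) if n_total > 0 else None
    return SIRResult(
        observed=observed,
        expected=e,
        sir=sir,
        ci_low=lo,
        ci_high=hi,
        attributable_risk=ar,
        n_total=n_total,
        method=method,
        event_class="all" if event_col == "events" else event_col.replace("_events", ""),
        n_degenerate_strata=int(breakdown["degenerate"].sum()),
        **meta,
    )
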