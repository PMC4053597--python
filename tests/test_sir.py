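"""SIR estimation: expectation, exact Poisson intervals, attributable risk."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hipsir import (
    attributable_risk,
    expected_events,
    poisson_ci_byar,
    poisson_ci_exact,
    sir_estimate,
    sir_from_table,
)
from hipsir.persontime import TABLE_COLUMNS


def _table(cells):
    """Build a person-time table from
    (sex, birth_year, period, state, days, events[, day, night, missing])."""
    rows = []
    for c in cells:
        sex, by, per, state, days, events = c[:6]
        day, night, miss = (c[6], c[7], c[8]) if len(c) > 6 else (0, 0, events)
        rows.append((sex, by, per, state, days, events, day, night, miss))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


class TestExpectedEvents:
    def test_single_stratum(self):
        t = _table(
            [
                ("f", 1930, 0, "unexposed", 1000, 10),
                ("f", 1930, 0, "exposed", 100, 3),
            ]
        )
        e, bd = expected_events(t)
        assert e == pytest.approx(1.0)

    def test_two_strata_sum(self):
        t = _table(
            [
                ("f", 1930, 0, "unexposed", 1000, 10),  # rate 0.01
                ("f", 1930, 0, "exposed", 100, 0),
                ("m", 1920, 0, "unexposed", 500, 10),  # rate 0.02
                ("m", 1920, 0, "exposed", 50, 0),
            ]
        )
        e, _ = expected_events(t)
        assert e == pytest.approx(2.0)

    def test_zero_unexposed_events_contribute_zero(self):
        t = _table(
            [
                ("f", 1930, 0, "unexposed", 1000, 0),
                ("f", 1930, 0, "exposed", 100, 2),
            ]
        )
        e, _ = expected_events(t)
        assert e == 0.0

    def test_degenerate_stratum_flagged_and_skipped(self):
        t = _table(
            [
                ("f", 1930, 0, "unexposed", 1000, 10),
                ("f", 1930, 0, "exposed", 100, 1),
                ("m", 1920, 1, "exposed", 50, 1),  # no unexposed time here
            ]
        )
        e, bd = expected_events(t)
        assert e == pytest.approx(1.0)
        assert bd["degenerate"].sum() == 1

    def test_all_degenerate_raises(self):
        t = _table([("f", 1930, 0, "exposed", 100, 1)])
        with pytest.raises(ValueError, match="no estimable expectation"):
            expected_events(t)


class TestPoissonCI:
    @pytest.mark.parametrize("o", [0, 1, 5, 15, 50])
    def test_matches_independent_gamma_quantiles(self, o):
        """The chi-square bounds equal the gamma-quantile formulation of
        the exact Poisson interval (independent parameterisation)."""
        lo, hi = poisson_ci_exact(o)
        lo_ref = 0.0 if o == 0 else stats.gamma.ppf(0.025, a=o, scale=1)
        hi_ref = stats.gamma.ppf(0.975, a=o + 1, scale=1)
        assert lo == pytest.approx(lo_ref, rel=1e-9)
        assert hi == pytest.approx(hi_ref, rel=1e-9)

    def test_zero_count_upper_bound_is_minus_log_alpha_half(self):
        lo, hi = poisson_ci_exact(0)
        assert lo == 0.0
        assert hi == pytest.approx(-np.log(0.025), rel=1e-6)  # 3.6889

    def test_byar_close_to_exact_at_large_counts(self):
        lo_e, hi_e = poisson_ci_exact(100)
        lo_b, hi_b = poisson_ci_byar(100)
        assert lo_b == pytest.approx(lo_e, rel=0.005)
        assert hi_b == pytest.approx(hi_e, rel=0.005)


class TestSIREstimate:
    def test_identity_when_observed_equals_expected(self):
        sir, lo, hi = sir_estimate(10, 10.0)
        assert sir == 1.0
        assert lo < 1.0 < hi

    def test_example_bounds(self):
        sir, lo, hi = sir_estimate(15, 10.0)
        assert sir == pytest.approx(1.5)
        assert lo == pytest.approx(0.8395, abs=5e-4)
        assert hi == pytest.approx(2.4740, abs=5e-4)

    def test_zero_observed_one_sided(self):
        sir, lo, hi = sir_estimate(0, 5.0)
        assert sir == 0.0 and lo == 0.0
        assert hi == pytest.approx(3.6889 / 5, abs=1e-4)

    def test_zero_expected_undefined(self):
        with pytest.raises(ValueError):
            sir_estimate(3, 0.0)


class TestAttributableRisk:
    def test_direct_arithmetic(self):
        assert attributable_risk(150, 100.0, 1000) == pytest.approx(0.05)

    def test_null_and_protective(self):
        assert attributable_risk(10, 10.0, 100) == 0.0
        assert attributable_risk(100, 120.0, 1000) == pytest.approx(-0.02)

    def test_invalid_totals(self):
        with pytest.raises(ValueError):
            attributable_risk(10, 5.0, 0)
        with pytest.raises(ValueError):
            attributable_risk(10, 5.0, 5)


def self_standardized(table):
    """Duplicate each stratum's margins so exposed and unexposed carry
    identical person-time and events."""
    u = table.copy()
    u["exposure_state"] = "unexposed"
    u = u.groupby(["sex", "birth_year", "period", "exposure_state"], as_index=False).sum()
    e = u.copy()
    e["exposure_state"] = "exposed"
    return pd.concat([u, e], ignore_index=True)


def test_self_standardization_gives_unit_sir(small_table):
    """A table standardized against itself has SIR exactly 1."""
    res = sir_from_table(self_standardized(small_table))
    assert res.sir == pytest.approx(1.0, abs=1e-12)
    assert res.attributable_risk == pytest.approx(
        res.observed * 0.5 * (1 - 1) / res.n_total, abs=1e-12
    )


def test_identical_stratum_rates_give_unit_sir():
    """If exposed and unexposed rates agree in every stratum, the SIR is 1
    regardless of how person-time is distributed across strata."""
    t = _table(
        [
            ("f", 1930, 0, "unexposed", 2000, 20),
            ("f", 1930, 0, "exposed", 100, 1),
            ("m", 1915, 3, "unexposed", 500, 25),
            ("m", 1915, 3, "exposed", 40, 2),
        ]
    )
    res = sir_from_table(t)
    assert res.sir == pytest.approx(1.0)


def test_sir_from_table_counts_and_rounding(small_table):
    res = sir_from_table(small_table, group="hypnotics_total", policy="ddd1")
    assert res.observed == small_table.loc[
        small_table.exposure_state == "exposed", "events"
    ].sum()
    assert res.n_total == small_table["events"].sum()
    assert res.ci_low <= res.sir <= res.ci_high
    rounded = res.rounded()
    assert set(rounded) == {"n", "sir", "ci_low", "ci_high", "attributable_risk_pct"}
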