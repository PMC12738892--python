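"""The four disproportionality statistics, flags and consensus calling."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from pvsignal.signals import (
    ContingencyTable,
    bcpnn,
    build_tables,
    call_signals,
    mgps,
    prr_chi2,
    ror,
    score_all,
    score_table,
    scores_to_frame,
    unique_events,
    vectorized_consensus,
)

import oracles

cells = st.integers(min_value=1, max_value=100_000)


class TestRor:
    def test_simple_value(self):
        est, lo, hi = ror(ContingencyTable(10, 10, 20, 40))
        assert est == pytest.approx(2.0)
        assert lo < 2.0 < hi

    def test_independence(self):
        est, lo, hi = ror(ContingencyTable(25, 25, 25, 25))
        assert est == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_zero_cell_undefined(self):
        est, lo, hi = ror(ContingencyTable(0, 10, 20, 40))
        assert math.isnan(est) and math.isnan(lo) and math.isnan(hi)

    def test_ci_against_log_scale_bootstrap(self):
        """The Wald CI matches a parametric bootstrap on the log-OR: tables
        resampled from independent binomial margins, interval from the
        log-scale normal quantiles of the resampled log-ORs."""
        a, b, c, d = 396, 2000, 2600, 90000
        est, lo, hi = ror(ContingencyTable(a, b, c, d))
        rng = np.random.default_rng(42)
        n1, n0 = a + b, c + d
        ra = rng.binomial(n1, a / n1, size=100_000)
        rc = rng.binomial(n0, c / n0, size=100_000)
        ok = (ra > 0) & (ra < n1) & (rc > 0) & (rc < n0)
        log_or = np.log(
            (ra[ok] / (n1 - ra[ok])) / (rc[ok] / (n0 - rc[ok]))
        )
        boot_lo, boot_hi = np.exp(np.quantile(log_or, [0.025, 0.975]))
        assert lo == pytest.approx(boot_lo, rel=0.03)
        assert hi == pytest.approx(boot_hi, rel=0.03)


class TestPrrChi2:
    def test_exact_fraction(self):
        prr, _ = prr_chi2(ContingencyTable(10, 90, 10, 890))
        assert prr == pytest.approx(9.0)

    def test_independence_chi2_zero(self):
        prr, chi2 = prr_chi2(ContingencyTable(20, 40, 30, 60))  # ad == bc
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert prr == pytest.approx(1.0)

    def test_zero_denominator_undefined(self):
        prr, _ = prr_chi2(ContingencyTable(5, 5, 0, 10))
        assert math.isnan(prr)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_chi2_equals_expected_count_form(self, a, b, c, d):
        """The printed product formula equals the textbook sum over
        (O-E)^2/E, cross-checked through scipy's Pearson test."""
        _, chi2 = prr_chi2(ContingencyTable(a, b, c, d))
        ref = chi2_contingency([[a, b], [c, d]], correction=False).statistic
        assert chi2 == pytest.approx(ref, rel=1e-10)


class TestBcpnn:
    def test_independence_limit(self):
        e_ic, _, _ = bcpnn(ContingencyTable(100, 900, 1000, 9000))
        assert abs(e_ic) < 0.02

    def test_zero_a_regularized(self):
        e_ic, v_ic, ic025 = bcpnn(ContingencyTable(0, 50, 100, 1000))
        assert math.isfinite(e_ic) and math.isfinite(v_ic)
        assert ic025 < 0

    def test_high_precision_point(self):
        e_ic, v_ic, ic025 = bcpnn(ContingencyTable(20, 80, 100, 800))
        oe, ov, oi = oracles.bcpnn_oracle(20, 80, 100, 800)
        assert e_ic == pytest.approx(float(oe), rel=1e-12)
        assert v_ic == pytest.approx(float(ov), rel=1e-12)
        assert ic025 == pytest.approx(float(oi), rel=1e-12)


class TestMgps:
    def test_independence(self):
        ebgm, _ = mgps(ContingencyTable(10, 90, 90, 810))
        assert ebgm == pytest.approx(1.0)

    def test_monotone_in_a(self):
        lo = mgps(ContingencyTable(10, 90, 90, 810))[0]
        hi = mgps(ContingencyTable(20, 90, 90, 810))[0]
        assert hi > lo

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_lower_bound_below_point_estimate(self, a, b, c, d):
        ebgm, ebgm05 = mgps(ContingencyTable(a, b, c, d))
        assert ebgm05 < ebgm

    def test_zero_cell_undefined(self):
        ebgm, ebgm05 = mgps(ContingencyTable(5, 0, 3, 10))
        assert math.isnan(ebgm) and math.isnan(ebgm05)


@given(a=cells, b=cells, c=cells, d=cells)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_ror_ci_brackets_estimate(a, b, c, d):
    est, lo, hi = ror(ContingencyTable(a, b, c, d))
    assert lo <= est <= hi


def test_exact_independence_identities():
    """Proportional tables give ROR = PRR = EBGM = 1 and chi2 = 0."""
    for a, scale in [(10, 9), (50, 3), (7, 20)]:
        t = ContingencyTable(a, a * scale, a * 4, a * 4 * scale)
        assert ror(t)[0] == pytest.approx(1.0, abs=1e-12)
        prr, chi2 = prr_chi2(t)
        assert prr == pytest.approx(1.0, abs=1e-12)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert mgps(t)[0] == pytest.approx(1.0, abs=1e-12)


class TestBuildTables:
    def test_direct_construction(self):
        target = [("1", "x")] * 1  # counts below are shaped via distinct caseids
        target = [(f"t{i}", "x") for i in range(3)] + [(f"t{i}", "y") for i in range(7)]
        background = [(f"b{i}", "x") for i in range(10)] + [
            (f"b{i}", "y") for i in range(90)
        ]
        tables = build_tables(target, background)
        assert tables["x"] == ContingencyTable(3, 7, 10, 90)
        assert tables["y"] == ContingencyTable(7, 3, 90, 10)

    def test_term_absent_from_background(self):
        tables = build_tables([("t1", "rare")], [("b1", "x")])
        t = tables["rare"]
        assert t.c == 0
        s = score_table("rare", t)
        assert not s.consensus  # zero cells veto, never raise

    def test_empty_background_is_error(self):
        with pytest.raises(ValueError, match="background"):
            build_tables([("t1", "x")], [])

    def test_unique_events_collapses_repeats(self):
        assert unique_events([("1", "x"), ("1", "x"), ("2", "x")]) == [
            ("1", "x"),
            ("2", "x"),
        ]


class TestFlags:
    def test_count_floor_vetoes_huge_ror(self):
        s = score_table("x", ContingencyTable(2, 1, 1, 10_000))
        assert s.ror > 100
        assert not s.flag_ror and not s.flag_mhra
        assert not s.consensus

    def test_consensus_requires_all_four(self):
        # meets ROR, MHRA and BCPNN thresholds but EBGM05 < 2 -> no consensus
        s = score_table("x", ContingencyTable(100, 900, 500, 9500))
        assert s.flag_ror and s.flag_mhra and s.flag_bcpnn
        assert not s.flag_mgps
        assert not s.consensus

    def test_call_signals_filters_consensus(self):
        scores = score_all(
            {
                "sig": ContingencyTable(30, 70, 100, 2000),
                "null": ContingencyTable(10, 90, 100, 900),
            }
        )
        called = call_signals(scores)
        assert [s.term for s in called] == ["sig"]


@given(
    a=st.integers(0, 500), b=st.integers(0, 500),
    c=st.integers(0, 500), d=st.integers(0, 500),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_vectorized_consensus_matches_scalar(a, b, c, d):
    """The array fast path used in simulation studies reproduces the
    per-table flags bit for bit, including zero-cell handling."""
    s = score_table("x", ContingencyTable(a, b, c, d))
    v = vectorized_consensus(
        np.array([a]), np.array([b]), np.array([c]), np.array([d])
    )
    assert bool(v["ror"][0]) == s.flag_ror
    assert bool(v["mhra"][0]) == s.flag_mhra
    assert bool(v["bcpnn"][0]) == s.flag_bcpnn
    assert bool(v["mgps"][0]) == s.flag_mgps
    assert bool(v["consensus"][0]) == s.consensus


def test_scores_frame_sorted_and_complete():
    scores = score_all(
        {
            "b_sig": ContingencyTable(30, 70, 100, 2000),
            "a_null": ContingencyTable(10, 90, 100, 900),
            "c_big": ContingencyTable(50, 50, 100, 2000),
        }
    )
    df = scores_to_frame(scores)
    assert list(df.columns[:6]) == ["term", "level", "a", "b", "c", "d"]
    assert df.iloc[0]["consensus"]  # consensus rows first, larger a first
    assert set(df["term"]) == {"a_null", "b_sig", "c_big"}
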