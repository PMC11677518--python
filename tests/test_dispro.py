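"""Disproportionality statistics: formulas, brute-force equivalence,
signal-of-disproportionate-reporting behaviour."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize, stats

import vigisignal as vs
from vigisignal.dispro import (ContingencyTable, chi_square, ror_p_value,
                               signal_scan)
from vigisignal.errors import VigisignalError
from vigisignal.synth import SynthConfig

CALCITRIOL = ContingencyTable(304, 1051, 2138, 5366088)
ALFACALCIDOL = ContingencyTable(322, 844, 2120, 5366295)


class TestPointEstimates:
    """Reconstructed hypercalcemia tables reproduce the published values."""

    @pytest.mark.parametrize("table,ror,prr", [
        (CALCITRIOL, 726.0, 563.32),
        (ALFACALCIDOL, 965.7, 699.31),
    ])
    def test_published_ror_and_prr(self, table, ror, prr):
        assert round(vs.compute_ror(table), 1) == ror
        assert round(vs.compute_prr(table), 2) == prr

    def test_balanced_table_gives_unity(self):
        t = ContingencyTable(7, 7, 7, 7)
        assert vs.compute_ror(t) == 1.0
        assert vs.compute_prr(t) == 1.0

    def test_equal_reporting_proportions_give_prr_one(self):
        t = ContingencyTable(10, 90, 100, 900)
        assert vs.compute_prr(t) == pytest.approx(1.0)

    def test_no_comparator_events_is_infinite_with_warning(self):
        with pytest.warns(UserWarning, match="comparator"):
            assert math.isinf(vs.compute_prr(ContingencyTable(3, 7, 0, 90)))

    def test_zero_drug_margin_is_an_error(self):
        with pytest.raises(VigisignalError):
            vs.compute_prr(ContingencyTable(0, 0, 5, 95))

    def test_zero_cell_policy_applies_half_correction(self):
        t = ContingencyTable(3, 0, 5, 92)
        assert vs.compute_ror(t) == pytest.approx((3.5 * 92.5) / (0.5 * 5.5))


class TestConfidenceInterval:
    def test_matches_wald_formula(self):
        lo, hi = vs.ror_confidence_interval(CALCITRIOL)
        se = math.sqrt(1 / 304 + 1 / 1051 + 1 / 2138 + 1 / 5366088)
        ror = vs.compute_ror(CALCITRIOL)
        assert lo == pytest.approx(ror * math.exp(-1.959964 * se), rel=1e-5)
        assert hi == pytest.approx(ror * math.exp(1.959964 * se), rel=1e-5)
        assert lo < ror < hi

    def test_widens_monotonically_with_level(self):
        widths = []
        for level in (0.5, 0.8, 0.95, 0.99, 0.999):
            lo, hi = vs.ror_confidence_interval(CALCITRIOL, level)
            widths.append(hi - lo)
        assert widths == sorted(widths)

    def test_quantile_against_numerical_integration(self):
        # independent oracle: invert the normal CDF by root-finding on the
        # integrated density, then rebuild the interval endpoint
        def cdf(x):
            return integrate.quad(
                lambda u: math.exp(-u * u / 2) / math.sqrt(2 * math.pi),
                -12, x)[0]

        z = optimize.brentq(lambda x: cdf(x) - 0.975, 0, 6, xtol=1e-10)
        se = math.sqrt(1 / 304 + 1 / 1051 + 1 / 2138 + 1 / 5366088)
        lo, hi = vs.ror_confidence_interval(CALCITRIOL, 0.95)
        ror = vs.compute_ror(CALCITRIOL)
        assert hi == pytest.approx(ror * math.exp(z * se), rel=1e-8)
        assert lo == pytest.approx(ror * math.exp(-z * se), rel=1e-8)


class TestChiSquare:
    def test_perfect_independence_is_zero(self):
        stat, p = chi_square(ContingencyTable(10, 10, 10, 10))
        assert stat == 0.0 and p == 1.0

    def test_matches_direct_observed_expected_sum(self):
        t = ContingencyTable(30, 70, 10, 90)
        obs = np.array([[30, 70], [10, 90]], dtype=float)
        row, col = obs.sum(1), obs.sum(0)
        exp = np.outer(row, col) / obs.sum()
        stat, _ = chi_square(t, continuity_correction=False)
        assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum(), abs=1e-9)

    @pytest.mark.parametrize("correction", [False, True])
    def test_cross_checked_against_scipy(self, correction):
        t = ContingencyTable(30, 70, 10, 90)
        stat, p = chi_square(t, continuity_correction=correction)
        ref = stats.chi2_contingency(np.array([[30, 70], [10, 90]]),
                                     correction=correction)
        assert stat == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_published_pair_is_overwhelming(self):
        stat, p = chi_square(CALCITRIOL, continuity_correction=True)
        assert stat > 4 and p < 0.0001
        assert ror_p_value(CALCITRIOL) < 0.0001

    def test_zero_margin_warns_and_returns_null(self):
        with pytest.warns(UserWarning, match="margin"):
            assert chi_square(ContingencyTable(0, 0, 10, 90)) == (0.0, 1.0)


class TestSdrRule:
    @pytest.mark.parametrize("a,chi2,prr,expected", [
        (304, 1e5, 563.32, True),
        (2, 100, 50, False),     # case-count gate
        (3, 4.0, 2.0, True),     # thresholds are inclusive
        (3, 3.999, 2.0, False),
        (3, 4.0, 1.999, False),
    ])
    def test_threshold_evaluation(self, a, chi2, prr, expected):
        assert vs.evaluate_sdr(a, chi2, prr) is expected

    @settings(derandomize=True, max_examples=300)
    @given(st.integers(50, 3000), st.integers(1, 200), st.integers(1, 200),
           st.integers(0, 200))
    def test_monotone_in_joint_count(self, n, dm, em, a):
        assume(dm + em <= n)
        assume(max(0, dm + em - n) <= a <= min(dm, em) - 1)

        def sdr(a_):
            t = ContingencyTable.from_margins(a_, dm, em, n)
            chi2, _ = chi_square(t, continuity_correction=True)
            return vs.evaluate_sdr(t.a, chi2, vs.compute_prr(t))

        if sdr(a):
            assert sdr(a + 1)


def test_build_contingency_equals_exhaustive_recount(tiny_config):
    db = vs.generate_database(tiny_config)
    clean, _ = vs.deduplicate(db)
    for drug in ("drugA", "drugB"):
        for event in ("EventX", "EventY"):
            table = vs.build_contingency(clean, drug, event)
            a = b = c = d = 0
            for _, row in clean.iterrows():
                has_d = drug in row["suspect_drugs"]
                has_e = event in row["reactions"]
                a += has_d and has_e
                b += has_d and not has_e
                c += has_e and not has_d
                d += not has_d and not has_e
            assert (table.a, table.b, table.c, table.d) == (a, b, c, d)
            assert table.n == len(clean)


def test_absent_drug_gives_empty_drug_margin(demo_clean):
    t = vs.build_contingency(demo_clean, "no-such-drug", "Nausea")
    assert t.a == 0 and t.b == 0 and t.n == len(demo_clean)


def test_event_nobody_reports(demo_clean):
    t = vs.build_contingency(demo_clean, "calcitriol", "no-such-event")
    assert t.a == 0 and t.c == 0
    assert t.drug_margin == len(vs.subset(demo_clean, drug="calcitriol"))


class TestSignalScan:
    def test_null_database_has_no_flags(self):
        cfg = SynthConfig(
            n_reports=30_000,
            drugs=[("d1", 0.05), ("d2", 0.05)],
            events=[("e1", 0.05), ("e2", 0.05), ("e3", 0.05)],
            seed=21)
        db = vs.generate_database(cfg)
        results = signal_scan(db, ["d1", "d2"])
        assert results  # pairs are reported ...
        assert not any(r.is_sdr for r in results
                       if r.event in ("e1", "e2", "e3"))  # ... but none flagged

    def test_planted_pairs_are_flagged_exactly(self):
        cfg = SynthConfig(
            n_reports=10_000,
            drugs=[("d1", 0.08), ("d2", 0.08)],
            events=[("e1", 0.03), ("e2", 0.03)],
            planted_signals=[("d1", "e1", math.log(6))],
            seed=5)
        db = vs.generate_database(cfg)
        flagged = {(r.drug, r.event) for r in signal_scan(db, ["d1", "d2"])
                   if r.is_sdr and r.event in ("e1", "e2")}
        assert flagged == {("d1", "e1")}

    def test_small_count_pairs_reported_never_flagged(self, demo_clean, term_maps):
        results = signal_scan(demo_clean, ["calcitriol", "cholecalciferol"],
                              term_maps=term_maps)
        for r in results:
            if r.table.a < 3:
                assert not r.is_sdr

    def test_soc_level_counts_once_per_report(self, demo_clean, term_maps):
        results = signal_scan(demo_clean, ["calcitriol"], level="soc",
                              term_maps=term_maps)
        soc = "Gastrointestinal disorders"
        found = [r for r in results if r.event == soc]
        expected = vs.build_contingency(
            demo_clean, "calcitriol",
            lambda s: any(term_maps.soc(pt) == soc for pt in s))
        assert found and found[0].table == expected

    def test_serious_stratum_restricts_comparator_too(self, demo_clean, term_maps):
        results = signal_scan(demo_clean, ["calcitriol"],
                              stratum="serious_only", term_maps=term_maps)
        n_serious = len(vs.subset(demo_clean, serious_only=True))
        assert all(r.table.n == n_serious for r in results)

    def test_empty_drug_list_is_an_error(self, demo_clean):
        with pytest.raises(VigisignalError):
            signal_scan(demo_clean, [])

    def test_ror_prr_gap_bounded_by_cell_ratios(self, demo_clean, term_maps):
        # |ROR - PRR| / PRR is at most max(a/b, c/(c+d)) on any 2x2 table
        results = signal_scan(demo_clean, ["calcitriol", "cholecalciferol"],
                              term_maps=term_maps)
        for r in results:
            t = r.table
            if t.b == 0 or t.c == 0 or math.isinf(r.prr):
                continue
            bound = max(t.a / t.b, t.c / (t.c + t.d))
            assert abs(r.ror - r.prr) / r.prr <= bound + 1e-12


def test_type_one_error_rate_under_independence():
    """Uncorrected chi-square keeps roughly its nominal size over 1,000
    independent drug-event pairs with no planted association."""
    drugs = [(f"d{i}", 0.05) for i in range(40)]
    events = [(f"e{j}", 0.05) for j in range(25)]
    db = vs.generate_database(SynthConfig(
        n_reports=20_000, drugs=drugs, events=events, seed=13))
    results = signal_scan(db, [d for d, _ in drugs])
    stats_ = [r.chi2_uncorrected for r in results
              if r.event.startswith("e")]
    assert len(stats_) == 1000
    rate = np.mean([s >= 3.841 for s in stats_])
    assert rate <= 0.07


class TestDescriptiveTables:
    def test_single_report_single_pt(self, demo_clean):
        db = demo_clean.head(1).copy()
        db.at[db.index[0], "suspect_drugs"] = frozenset({"calcitriol"})
        db.at[db.index[0], "reactions"] = frozenset({"Nausea"})
        pt_table, summary = vs.descriptive_tables(db, ["calcitriol"])
        assert pt_table.iloc[0]["count"] == 1
        assert pt_table.iloc[0]["pct_of_mentions"] == 100.0
        assert summary.iloc[0]["mean_adrs_per_report"] == 1.0

    def test_mentions_count_each_pt_once_per_report(self, demo_clean):
        _, summary = vs.descriptive_tables(demo_clean, ["calcitriol"])
        sub = vs.subset(demo_clean, drug="calcitriol")
        assert summary.iloc[0]["n_mentions"] == sum(len(s) for s in sub["reactions"])
        assert summary.iloc[0]["n_reports"] == len(sub)
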