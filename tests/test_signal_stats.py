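"""The four disproportionality statistics against frozen values and oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracle import (
    bcpnn_oracle,
    chi2_uncorrected_oracle,
    chi2_yates_oracle,
    ebgm_oracle,
    prr_oracle,
    ror_oracle,
)
from pvsignal.contingency import ContingencyTable
from pvsignal.signal_stats import (
    BcpnnPriors,
    bcpnn_stats,
    compute_signal_stats,
    ebgm_stats,
    evaluate_signal,
    prr_stats,
    rank_results,
    ror_stats,
)


def T(a, b, c, d, label="X"):
    return ContingencyTable(label, "PT", a, b, c, d)


class TestRor:
    def test_balanced_table_is_null(self):
        ror, (lo, hi) = ror_stats(T(10, 10, 10, 10))
        assert ror == 1.0
        assert lo < 1 < hi

    def test_hand_derived_fixture(self):
        # (6,4,3,8): ROR = 48/12 = 4, SE = sqrt(7/8)
        ror, (lo, hi) = ror_stats(T(6, 4, 3, 8))
        assert ror == pytest.approx(4.0)
        assert lo == pytest.approx(4.0 * math.exp(-1.96 * math.sqrt(0.875)), rel=1e-12)
        assert (lo, hi) == (pytest.approx(0.639, abs=5e-4), pytest.approx(25.02, abs=5e-3))

    def test_zero_cell_non_computable(self):
        ror, (lo, hi) = ror_stats(T(0, 5, 5, 5))
        assert math.isnan(ror) and math.isnan(lo) and math.isnan(hi)


class TestPrr:
    def test_balanced_table_is_null(self):
        prr, _, _ = prr_stats(T(10, 10, 10, 10))
        assert prr == 1.0

    def test_hand_derived_fixture(self):
        prr, (lo, hi), _ = prr_stats(T(6, 4, 3, 8))
        assert prr == pytest.approx(2.2)
        assert lo == pytest.approx(2.2 * math.exp(-1.96 * math.sqrt(1 / 6 - 1 / 10 + 1 / 3 - 1 / 11)), rel=1e-12)
        assert (lo, hi) == (pytest.approx(0.740, abs=5e-4), pytest.approx(6.541, abs=5e-3))

    def test_chi2_yates_vs_uncorrected(self):
        _, _, yates = prr_stats(T(6, 4, 3, 8), "yates")
        _, _, raw = prr_stats(T(6, 4, 3, 8), "uncorrected")
        assert yates == pytest.approx(1.149, abs=5e-3)
        assert raw == pytest.approx(2.291, abs=5e-3)

    def test_chi2_yates_floors_at_zero(self):
        # |ad - bc| = 1 < N/2 = 2: corrected statistic must clamp to 0
        _, _, chi2 = prr_stats(T(1, 1, 1, 1))
        assert chi2 == 0.0

    def test_chi2_cross_check_against_scipy(self):
        scipy_stats = pytest.importorskip("scipy.stats")
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 200, size=4))
            obs = [[a, b], [c, d]]
            for variant, correction in (("yates", True), ("uncorrected", False)):
                _, _, chi2 = prr_stats(T(a, b, c, d), variant)
                expected = scipy_stats.chi2_contingency(obs, correction=correction).statistic
                assert chi2 == pytest.approx(expected, rel=1e-10)


class TestBcpnn:
    def test_hand_derived_fixture(self):
        ic, e_ic, v_ic, ic025 = bcpnn_stats(T(6, 4, 3, 8))
        assert BcpnnPriors().gamma(6, 4, 3, 8) == pytest.approx(529 / 110, rel=1e-12)
        assert e_ic == pytest.approx(0.383, abs=5e-4)
        assert v_ic == pytest.approx(0.416, abs=5e-4)
        assert ic025 == pytest.approx(-0.907, abs=5e-4)

    def test_symmetric_table_ic_zero_and_e_ic_to_zero(self):
        n = 250_000
        ic, e_ic, _, _ = bcpnn_stats(T(n, n, n, n))
        assert ic == 0.0
        assert abs(e_ic) < 1e-4

    def test_a_zero_still_gives_finite_shrunk_moments(self):
        ic, e_ic, v_ic, ic025 = bcpnn_stats(T(0, 10, 10, 100))
        assert math.isnan(ic)
        assert math.isfinite(e_ic) and math.isfinite(v_ic)
        assert ic025 < 0

    def test_priors_must_be_positive(self):
        with pytest.raises(ValueError):
            BcpnnPriors(alpha=0)

    def test_shrinkage_tightens_with_more_data(self):
        """For a fixed ROR, IC025 rises as counts scale up (grid check)."""
        prev = -math.inf
        for k in (1, 2, 5, 10, 50, 200):
            _, _, _, ic025 = bcpnn_stats(T(6 * k, 4 * k, 3 * k, 8 * k))
            assert ic025 > prev
            prev = ic025


class TestEbgm:
    def test_balanced_table_is_null(self):
        ebgm, _ = ebgm_stats(T(10, 10, 10, 10))
        assert ebgm == 1.0

    def test_hand_derived_fixture(self):
        ebgm, (lo, hi) = ebgm_stats(T(6, 4, 3, 8))
        assert ebgm == pytest.approx(1.4)
        assert lo == pytest.approx(0.224, abs=5e-4)

    def test_degenerate_margins_no_bounds(self):
        # only the target drug reports only this event: b = c = 0
        ebgm, (lo, hi) = ebgm_stats(T(10, 0, 0, 90))
        assert math.isfinite(ebgm)
        assert math.isnan(lo) and math.isnan(hi)


class TestFlagsAndRanking:
    def test_minimum_case_count_gates_ror_flag(self):
        s = compute_signal_stats(T(2, 1, 1, 1000))
        assert s.ror_lo > 5  # strong association, but only 2 reports
        assert not s.ror_flag and not s.prr_flag

    def test_balanced_table_all_flags_false(self):
        s = compute_signal_stats(T(10, 10, 10, 10))
        assert not any([s.ror_flag, s.prr_flag, s.bcpnn_flag, s.ebgm_flag, s.combined_flag])

    def test_strong_signal_all_flags_true(self):
        # oracle confirms every bound clears its threshold by construction
        a, b, c, d = 500, 500, 500, 498500
        _, ror_lo, _ = ror_oracle(a, b, c, d)
        _, _, _, ic025, _ = bcpnn_oracle(a, b, c, d)
        _, ebgm05, _ = ebgm_oracle(a, b, c, d)
        assert ror_lo > 1 and ic025 > 0 and ebgm05 > 2
        s = compute_signal_stats(T(a, b, c, d))
        assert s.ror_flag and s.prr_flag and s.bcpnn_flag and s.ebgm_flag and s.combined_flag

    def test_policy_any_vs_all(self):
        s = compute_signal_stats(T(103, 2905, 34, 8603), policy="all")
        assert s.ror_flag and not s.ebgm_flag and not s.combined_flag
        assert evaluate_signal(s, policy="any").combined_flag

    def test_rank_by_case_reports_with_tie_rules(self):
        rs = [compute_signal_stats(T(a, 10, 10, 100, label=lbl)) for a, lbl in [(5, "B"), (9, "C"), (7, "A"), (9, "A")]]
        ranked = rank_results(rs, by="case_reports")
        assert [(r.a, r.event_label) for r in ranked] == [(9, "A"), (9, "C"), (7, "A"), (5, "B")]

    def test_top_n_truncation_and_nonpositive(self):
        rs = [compute_signal_stats(T(a, 10, 10, 100)) for a in (5, 9, 7)]
        assert len(rank_results(rs, top_n=2)) == 2
        assert rank_results(rs, top_n=0) == []


class TestCrossMethodInvariants:
    tables = st.tuples(*[st.integers(1, 500)] * 4)

    @settings(max_examples=200, deadline=None)
    @given(cells=tables)
    def test_ror_and_prr_agree_in_direction_and_ror_is_more_extreme(self, cells):
        a, b, c, d = cells
        ror, _ = ror_stats(T(a, b, c, d))
        prr, _, _ = prr_stats(T(a, b, c, d))
        assert (ror - 1) * (prr - 1) >= 0
        if prr > 1:
            assert ror > prr

    @settings(max_examples=200, deadline=None)
    @given(cells=tables)
    def test_ic_is_log2_of_ebgm(self, cells):
        a, b, c, d = cells
        ic, _, _, _ = bcpnn_stats(T(a, b, c, d))
        ebgm, _ = ebgm_stats(T(a, b, c, d))
        assert ic == pytest.approx(math.log2(ebgm), rel=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(cells=tables)
    def test_label_swap_inverts_ror(self, cells):
        a, b, c, d = cells
        ror, _ = ror_stats(T(a, b, c, d))
        ror_swapped, _ = ror_stats(T(a, b, c, d).swapped())
        assert ror_swapped == pytest.approx(1.0 / ror, rel=1e-12)


class TestOracleAgreement:
    def test_all_statistics_match_naive_oracle_on_random_tables(self):
        """1e-10 relative agreement with a from-scratch transcription."""
        rng = np.random.default_rng(12345)
        rel = 1e-10
        for i in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(0 if i % 5 == 0 else 1, 5000, size=4))
            t = T(a, b, c, d)

            def check(got, want):
                if math.isnan(want):
                    assert math.isnan(got), (a, b, c, d)
                else:
                    assert got == pytest.approx(want, rel=rel), (a, b, c, d)

            ror, (rlo, rhi) = ror_stats(t)
            for got, want in zip((ror, rlo, rhi), ror_oracle(a, b, c, d)):
                check(got, want)
            prr, (plo, phi), chi2y = prr_stats(t, "yates")
            for got, want in zip((prr, plo, phi), prr_oracle(a, b, c, d)):
                check(got, want)
            check(chi2y, chi2_yates_oracle(a, b, c, d))
            _, _, chi2u = prr_stats(t, "uncorrected")
            check(chi2u, chi2_uncorrected_oracle(a, b, c, d))
            ic, e_ic, v_ic, ic025 = bcpnn_stats(t)
            o_ic, o_e, o_v, o_lo, _ = bcpnn_oracle(a, b, c, d)
            for got, want in zip((ic, e_ic, v_ic, ic025), (o_ic, o_e, o_v, o_lo)):
                check(got, want)
            ebgm, (elo, ehi) = ebgm_stats(t)
            for got, want in zip((ebgm, elo, ehi), ebgm_oracle(a, b, c, d)):
                check(got, want)
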