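import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from pvsignals import (
    ContingencyTable,
    ReportStore,
    SignalCriteria,
    build_table,
    compute_chi2_yates,
    compute_prr,
    compute_ror,
    detect_signals,
    evaluate_signal,
    implied_prr,
    reconstruct_table,
    significant_signals,
)
from pvsignals.errors import LexiconError, UnsolvableError

from conftest import make_report

cells = st.integers(1, 10**6)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


class TestContingencyTable:
    def test_margins_consistent(self):
        t = ContingencyTable(30, 70, 50, 950)
        assert t.D == 100 and t.d == 1000
        assert t.E == 80 and t.e == 1020
        assert t.N == 1100 == t.D + t.d == t.E + t.e

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestComputeRor:
    def test_proportional_rows_give_unity(self):
        assert compute_ror(ContingencyTable(10, 90, 100, 900)).ror == pytest.approx(1.0)

    def test_cross_product(self):
        res = compute_ror(ContingencyTable(30, 70, 50, 950))
        assert res.ror == pytest.approx((30 * 950) / (70 * 50))

    def test_zero_cell_non_evaluable(self):
        res = compute_ror(ContingencyTable(5, 0, 3, 10))
        assert not res.evaluable
        assert math.isnan(res.ror)
        assert "De" in res.reason

    def test_ci_against_independent_formula(self):
        t = ContingencyTable(30, 70, 50, 950)
        res = compute_ror(t)
        se = math.sqrt(1 / 30 + 1 / 70 + 1 / 50 + 1 / 950)
        assert res.ci_low == pytest.approx(res.ror * math.exp(-1.96 * se))
        assert res.ci_high == pytest.approx(res.ror * math.exp(1.96 * se))
        assert res.ci_low <= res.ror <= res.ci_high


class TestComputePrr:
    def test_equal_proportions_give_unity(self):
        assert compute_prr(ContingencyTable(10, 90, 100, 900)).prr == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        assert compute_prr(ContingencyTable(30, 70, 50, 950)).prr == pytest.approx(6.0)

    def test_zero_dE_non_evaluable(self):
        res = compute_prr(ContingencyTable(5, 5, 0, 10))
        assert not res.evaluable


class TestComputeChi2Yates:
    def test_clamped_to_zero_at_independence(self):
        assert compute_chi2_yates(ContingencyTable(10, 90, 100, 900)).chi2 == 0.0

    def test_derived_value(self):
        # frozen from an independent Yates implementation (scipy)
        assert compute_chi2_yates(ContingencyTable(30, 70, 50, 950)).chi2 == (
            pytest.approx(80.58612132352941)
        )

    def test_zero_margin_non_evaluable(self):
        assert not compute_chi2_yates(ContingencyTable(0, 0, 5, 5)).evaluable


class TestOracleEquivalence:
    def test_against_independent_implementations(self):
        rng = np.random.default_rng(7)
        draws = rng.integers(1, 10**6, size=(1000, 4))
        for DE, De, dE, de in draws:
            t = ContingencyTable(int(DE), int(De), int(dE), int(de))
            ours = compute_chi2_yates(t).chi2
            theirs = chi2_contingency(
                [[DE, dE], [De, de]], correction=True
            ).statistic
            assert ours == pytest.approx(theirs, rel=1e-10)
            # exact rational arithmetic for the ratio statistics
            ror_exact = Fraction(int(DE) * int(de), int(De) * int(dE))
            assert compute_ror(t).ror == pytest.approx(float(ror_exact), rel=1e-10)
            prr_exact = Fraction(int(DE), int(DE) + int(De)) / Fraction(
                int(dE), int(dE) + int(de)
            )
            assert compute_prr(t).prr == pytest.approx(float(prr_exact), rel=1e-10)


class TestSymmetries:
    @given(tables)
    @settings(max_examples=200)
    def test_chi2_transpose_invariant(self, t):
        assert compute_chi2_yates(t).chi2 == pytest.approx(
            compute_chi2_yates(t.transpose()).chi2, rel=1e-12
        )

    @given(tables)
    @settings(max_examples=200)
    def test_ror_column_swap_reciprocal(self, t):
        assert compute_ror(t.swap_columns()).ror == pytest.approx(
            1 / compute_ror(t).ror, rel=1e-12
        )

    @given(cells, cells, st.integers(1, 1000))
    @settings(max_examples=100)
    def test_exact_independence(self, a, b, k):
        # rows (a, b) and (k*a, k*b) are exactly proportional
        t = ContingencyTable(a, b, k * a, k * b)
        assert compute_ror(t).ror == pytest.approx(1.0)
        assert compute_prr(t).prr == pytest.approx(1.0)
        assert compute_chi2_yates(t).chi2 == 0.0


class TestEvaluateSignal:
    def test_low_de_never_significant(self):
        t = ContingencyTable(2, 1, 1, 10**6)
        assert not evaluate_signal(t).significant

    def test_derived_example_significant(self):
        # DE=30>=3, ROR=8.14>=2, CI low>1, PRR=6>=2, chi2=80.6>=4
        assert evaluate_signal(ContingencyTable(30, 70, 50, 950)).significant

    def test_boundary_inclusive_vs_strict(self):
        # engineered so ROR is exactly 2: (20*1000)/(100*100); PRR is then
        # necessarily just under 2, so relax it to isolate the ROR boundary
        t = ContingencyTable(20, 100, 100, 1000)
        assert compute_ror(t).ror == pytest.approx(2.0)
        lenient = SignalCriteria(min_prr=0.5)
        assert evaluate_signal(t, lenient).significant
        strict = SignalCriteria(min_prr=0.5, strict=True)
        assert not evaluate_signal(t, strict).significant

    def test_non_evaluable_statistic_fails_criterion(self):
        t = ContingencyTable(5, 5, 0, 100)  # dE = 0
        assert not evaluate_signal(t).significant


class TestDetectSignals:
    def test_planted_signals_only(self):
        reports = []
        isr = 1
        # 100 drug reports: 30 with "bad event", background 1000: 10 with it
        for _ in range(30):
            reports.append(make_report(isr, events=["bad event"])); isr += 1
        for _ in range(70):
            reports.append(make_report(isr, events=["common"])); isr += 1
        for _ in range(10):
            reports.append(make_report(isr, drug="other", events=["bad event"])); isr += 1
        for _ in range(990):
            reports.append(make_report(isr, drug="other", events=["common"])); isr += 1
        store = ReportStore.from_reports(reports, deduplicated=True)
        result = detect_signals(store, "denosumab")
        sig = significant_signals(result)
        assert [s.event for s in sig] == ["bad event"]
        by_event = {s.event: s for s in result}
        assert by_event["common"].DE == 70
        assert not by_event["common"].significant

    def test_no_overlap_gives_empty(self, small_store):
        result = detect_signals(small_store, "background")
        assert result == []

    def test_equal_de_ties_lexicographic(self):
        reports = [
            make_report(1, events=["zeta", "alpha"]),
            make_report(2, events=["zeta", "alpha"]),
            make_report(3, events=["zeta", "alpha"]),
            make_report(4, events=[]),
        ]
        for i in range(5, 105):
            reports.append(make_report(i, drug="other", events=[]))
        store = ReportStore.from_reports(reports, deduplicated=True)
        result = detect_signals(store, "denosumab")
        assert [s.event for s in result] == ["alpha", "zeta"]

    def test_unknown_drug_with_lexicon_raises(self, small_store, two_drug_lexicon):
        with pytest.raises(LexiconError):
            detect_signals(small_store, "aspirin", lexicon=two_drug_lexicon)


class TestBuildTable:
    def test_degenerate_store(self):
        store = ReportStore.from_reports(
            [make_report(i, events=["e"]) for i in range(1, 5)], deduplicated=True
        )
        t = build_table(store, "denosumab", "e")
        assert (t.DE, t.De, t.dE, t.de) == (4, 0, 0, 0)

    def test_cells_sum_to_store_size(self, small_store):
        t = build_table(small_store, "denosumab", "onj")
        assert t.N == len(small_store)
        assert (t.DE, t.De, t.dE, t.de) == (2, 1, 1, 2)

    def test_margin_complement_on_swap(self, small_store):
        t1 = build_table(small_store, "denosumab", "onj")
        t2 = build_table(small_store, "background", "onj")
        assert t2.D == 1
        assert t1.D + t2.D + 2 == len(small_store)  # ZA holds the other 2

    def test_ledger_recount(self, basic_config):
        from pvsignals import deduplicate, generate_reports

        store, _ = generate_reports(basic_config)
        dd = deduplicate(store)
        t = build_table(dd, "denosumab", "osteonecrosis of jaw")
        # independent recount via a direct pass over the records
        DE = De = dE = de = 0
        for r in dd.reports():
            exposed = any(
                e.canonical_name == "denosumab" and e.role == "primary_suspect"
                for e in r.drugs
            )
            has = "osteonecrosis of jaw" in r.events
            DE += exposed and has
            De += exposed and not has
            dE += (not exposed) and has
            de += (not exposed) and not has
        assert (t.DE, t.De, t.dE, t.de) == (DE, De, dE, de)


class TestImpliedPrr:
    def test_consistent_with_full_table(self):
        t = ContingencyTable(10, 90, 75, 1500)
        ror = compute_ror(t).ror
        assert implied_prr(10, 100, ror) == pytest.approx(
            compute_prr(t).prr, rel=1e-12
        )

    def test_printed_row_onj(self):
        assert implied_prr(6043, 117857, 53.025) == pytest.approx(50.358, abs=1e-2)

    def test_printed_row_tooth_extraction(self):
        assert implied_prr(2321, 36878, 142.143) == pytest.approx(133.26, abs=1e-2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            implied_prr(0, 100, 2.0)
        with pytest.raises(ValueError):
            implied_prr(10, 100, -1.0)


class TestReconstructTable:
    @given(
        st.integers(5, 5000),
        st.integers(5, 5000),
        st.integers(5, 50000),
        st.integers(5, 500000),
    )
    @settings(max_examples=60, deadline=None)
    def test_round_trip_fixed_point(self, DE, De, dE, de):
        t = ContingencyTable(DE, De, dE, de)
        chi2 = compute_chi2_yates(t).chi2
        ror = compute_ror(t).ror
        if chi2 <= 0:
            return
        rec = reconstruct_table(DE, DE + De, ror, chi2)
        for cell in ("DE", "De", "dE", "de"):
            assert getattr(rec, cell) == pytest.approx(
                getattr(t, cell), rel=1e-6, abs=1e-6
            )
        assert compute_ror(rec).ror == pytest.approx(ror, rel=1e-9)
        assert compute_chi2_yates(rec).chi2 == pytest.approx(chi2, rel=1e-9)

    def test_printed_row_onj_ci(self):
        rec = reconstruct_table(6043, 117857, 53.025, 193469.11)
        assert compute_ror(rec).ci_low == pytest.approx(51.377, rel=2e-3)

    def test_printed_row_tooth_extraction_ci(self):
        rec = reconstruct_table(2321, 36878, 142.143, 214317.12)
        assert compute_ror(rec).ci_low == pytest.approx(135.258, rel=2e-3)

    def test_unattainable_chi2_names_asymptote(self):
        with pytest.raises(UnsolvableError) as exc:
            reconstruct_table(6043, 117857, 53.025, 1e9)
        assert exc.value.asymptote is not None
        assert exc.value.asymptote < 1e9
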