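"""Disproportionality arithmetic, CI oracles, signal criteria and symmetries."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings, strategies as st

from neurovigil import (
    ContingencyTable,
    SignalScreen,
    build_2x2,
    evaluate_signal,
    ic,
    prr,
    ror,
)

cells = st.integers(min_value=1, max_value=200)


class TestRor:
    def test_symmetric_table_gives_unity(self):
        assert ror(ContingencyTable(10, 90, 10, 90)).estimate == pytest.approx(1.0)

    def test_point_estimate_cross_product(self):
        assert ror(ContingencyTable(20, 80, 10, 90)).estimate == pytest.approx(2.25)

    def test_confidence_interval_hand_oracle(self):
        # exp(ln 2.25 +- 1.96 * sqrt(1/20 + 1/80 + 1/10 + 1/90)), computed by hand
        r = ror(ContingencyTable(20, 80, 10, 90))
        assert r.low == pytest.approx(0.9942948922815062, rel=1e-12)
        assert r.high == pytest.approx(5.091547828817265, rel=1e-12)

    def test_zero_cell_policies(self):
        t = ContingencyTable(0, 80, 10, 90)
        assert not ror(t, policy="strict").defined
        h = ror(t, policy="haldane")
        assert h.defined and h.corrected
        assert h.estimate == pytest.approx((0.5 * 90.5) / (80.5 * 10.5))


class TestPrr:
    def test_symmetric_table_gives_unity(self):
        assert prr(ContingencyTable(10, 90, 10, 90)).estimate == pytest.approx(1.0)

    def test_point_estimate_proportion_ratio(self):
        assert prr(ContingencyTable(20, 80, 10, 90)).estimate == pytest.approx(2.0)

    def test_degenerate_zero_cell_strict(self):
        assert not prr(ContingencyTable(20, 80, 0, 90)).defined

    def test_se_variants_differ(self):
        t = ContingencyTable(20, 80, 10, 90)
        conv = prr(t, se_style="conventional")
        rstyle = prr(t, se_style="ror")
        assert conv.estimate == rstyle.estimate
        assert conv.high < rstyle.high  # conventional SE is smaller here


class TestIc:
    def test_independence_gives_zero(self):
        assert ic(ContingencyTable(25, 25, 25, 25)).estimate == pytest.approx(0.0)

    def test_observed_over_expected_oracle(self):
        # expected = (100*30)/200 = 15; IC = log2(20/15)
        assert ic(ContingencyTable(20, 80, 10, 90)).estimate == pytest.approx(
            math.log2(4 / 3), rel=1e-12
        )

    def test_zero_a_haldane_is_finite_negative(self):
        v = ic(ContingencyTable(0, 80, 10, 90), policy="haldane")
        assert v.defined and math.isfinite(v.estimate) and v.estimate < 0

    def test_log2_se_scale_widens_interval(self):
        t = ContingencyTable(20, 80, 10, 90)
        printed, log2 = ic(t, se_scale="printed"), ic(t, se_scale="log2")
        assert printed.estimate == log2.estimate
        # the published additive form uses the natural-log SE, narrower by ln 2
        assert (log2.high - log2.low) == pytest.approx(
            (printed.high - printed.low) / math.log(2)
        )


@settings(max_examples=200, deadline=None, derandomize=True)
@given(a=cells, b=cells, c=cells, d=cells)
def test_exchange_symmetry(a, b, c, d):
    """Swapping drug and comparator rows inverts ROR/PRR and negates IC."""
    t, s = ContingencyTable(a, b, c, d), ContingencyTable(c, d, a, b)
    assert ror(s).estimate == pytest.approx(1 / ror(t).estimate, rel=1e-12)
    assert prr(s).estimate == pytest.approx(1 / prr(t).estimate, rel=1e-12)
    # IC under exchange follows the defining observed/expected identity
    n = a + b + c + d
    assert ic(s).estimate == pytest.approx(math.log2(c * n / ((c + d) * (a + c))), rel=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(a=st.integers(2, 150), b=cells, c=cells, d=cells)
def test_ror_prr_monotone_in_a(a, b, c, d):
    lo, hi = ContingencyTable(a - 1, b, c, d), ContingencyTable(a, b, c, d)
    assert ror(hi).estimate > ror(lo).estimate
    assert prr(hi).estimate > prr(lo).estimate


@settings(max_examples=100, deadline=None, derandomize=True)
@given(a=st.integers(2, 100), extra_b=st.integers(0, 100),
       extra_c=st.integers(0, 100), d=st.integers(1, 500))
def test_ic_monotone_in_a_for_rare_events(a, extra_b, extra_c, d):
    """IC strictly increases with the joint count when the drug-event pair is
    rarer than either margin (a <= min(b, c)); with a dominant cell the
    observed/expected ratio saturates, so the global claim would be false
    (e.g. (1,1,1,5) -> (2,1,1,5) leaves IC unchanged)."""
    b, c = a + extra_b, a + extra_c
    lo, hi = ContingencyTable(a - 1, b, c, d), ContingencyTable(a, b, c, d)
    assert ic(hi).estimate > ic(lo).estimate


class TestEvaluateSignal:
    def _ci(self, low, high=10.0, defined=True):
        from neurovigil.signals import EstimateCI

        mid = (low + high) / 2 if defined else float("nan")
        return EstimateCI(mid, low, high, defined=defined)

    def test_count_rule_blocks_pt_signal(self):
        verdict, failed = evaluate_signal(2, self._ci(1.4), self._ci(0.5), level="pt")
        assert not verdict and "n<3" in failed

    def test_compound_rule_fires(self):
        verdict, failed = evaluate_signal(10, self._ci(1.05), self._ci(0.1), level="pt")
        assert verdict and failed == ()

    def test_overall_boundary(self):
        verdict, _ = evaluate_signal(10, self._ci(0.99), self._ci(0.5), level="overall")
        assert not verdict

    def test_undefined_components_fail_with_reason(self):
        undef = self._ci(0, defined=False)
        verdict, failed = evaluate_signal(10, undef, undef, level="pt")
        assert not verdict and "undefined" in failed


class TestBuild2x2:
    def test_enumerated_cells(self, hierarchy):
        import pandas as pd

        cohort = pd.DataFrame(
            {
                "exposed": [True, True, False, False],
                "ps_ingredients": [frozenset({"nivolumab"})] * 2 + [frozenset()] * 2,
                "nae_case": [True, False, True, False],
                "reactions": [("Dizziness",), ("Nausea",), ("Dizziness",), ("Nausea",)],
            }
        )
        t = build_2x2(cohort, "any", "nae")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
        tp = build_2x2(cohort, "nivolumab", "Dizziness")
        assert (tp.a, tp.b, tp.c, tp.d) == (1, 1, 1, 1)

    def test_no_exposed_rows(self):
        import pandas as pd

        cohort = pd.DataFrame(
            {
                "exposed": [False, False],
                "ps_ingredients": [frozenset(), frozenset()],
                "nae_case": [True, False],
                "reactions": [("Dizziness",), ("Nausea",)],
            }
        )
        t = build_2x2(cohort, "any", "nae")
        assert t.a == 0 and t.b == 0

    def test_empty_cohort_fails(self):
        import pandas as pd

        with pytest.raises(ValueError, match="empty"):
            build_2x2(pd.DataFrame(columns=["exposed"]), "any", "nae")

    def test_planted_multiplier_consistency(self, big_sim):
        """a*d/(b*c) near the planted multiplier 3 for rare events at 200k."""
        t = build_2x2(big_sim["cohort"], "pembrolizumab", "Seizure")
        assert 2.5 <= ror(t).estimate <= 3.5


def test_signal_screen_collects_all_pairs(small_sim):
    screen = SignalScreen(drugs=["any", "nivolumab"]).fit(small_sim["cohort"])
    assert screen.signals_["drug"].nunique() == 2
    assert "nae" in set(screen.signals_["event"])
    row = screen.signals_.iloc[0]
    assert row["a"] + row["b"] + row["c"] + row["d"] == len(small_sim["cohort"])
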