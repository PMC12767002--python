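"""Onset arithmetic, group comparisons, severity tests and trend fits."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neurovigil import (
    CaseReport,
    DrugRecord,
    compare_groups,
    quarterly_trend,
    serious_outcome_test,
    summarize_onset,
    time_to_onset,
    TrendRegressor,
)


def _report(event_dt, starts, roles=None):
    roles = roles or ["PS"] * len(starts)
    drugs = [
        DrugRecord(i + 1, role, "X", "x", therapy_start=s)
        for i, (s, role) in enumerate(zip(starts, roles))
    ]
    return CaseReport(
        primaryid="1", caseid="1", fda_dt=date(2021, 1, 1),
        event_dt=event_dt, drugs=drugs, reactions=("Dizziness",),
    )


class TestTimeToOnset:
    def test_calendar_arithmetic(self):
        days, reason = time_to_onset(_report(date(2020, 2, 4), [date(2020, 1, 1)]))
        assert days == 34 and reason is None

    def test_earliest_primary_suspect_start(self):
        days, _ = time_to_onset(
            _report(date(2020, 3, 15), [date(2020, 1, 1), date(2020, 3, 1)])
        )
        assert days == 74

    def test_non_ps_starts_ignored(self):
        days, reason = time_to_onset(
            _report(date(2020, 3, 15), [date(2020, 1, 1), date(2020, 3, 1)],
                    roles=["C", "PS"])
        )
        assert days == 14

    def test_event_before_start_is_flagged_not_clipped(self):
        days, reason = time_to_onset(_report(date(2020, 1, 1), [date(2020, 2, 1)]))
        assert days is None and reason == "negative"

    def test_missing_pieces_have_reason_codes(self):
        assert time_to_onset(_report(None, [date(2020, 1, 1)]))[1] == "no_event_date"
        assert time_to_onset(_report(date(2020, 1, 1), []))[1] == "no_therapy_start"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2000), st.integers(-5000, 5000))
    def test_translation_invariance(self, onset, shift):
        base = date(2015, 6, 1)
        d1, _ = time_to_onset(_report(base + timedelta(days=onset), [base]))
        d2, _ = time_to_onset(
            _report(base + timedelta(days=onset + shift), [base + timedelta(days=shift)])
        )
        assert d1 == d2 == onset


class TestSummarizeOnset:
    def test_median_and_within_two_months(self):
        (s,) = summarize_onset([10, 34, 100])
        assert s.median == 34 and s.q1 == 22 and s.q3 == 67
        assert s.within_60d == pytest.approx(2 / 3)

    def test_all_within_two_months(self):
        (s,) = summarize_onset([1, 59, 60])
        assert s.within_60d == 1.0

    def test_lognormal_median_oracle(self):
        """Generator onset draws recover the configured lognormal median."""
        from neurovigil.simulate import DrugSpec, SimConfig, PTSpec, generate_reports

        cfg = SimConfig(
            quarters=["2020Q1"], n_reports_per_quarter=[10_000],
            drug_catalog=[DrugSpec(ingredient="nivolumab", share=1.0, is_target=True,
                                   onset_median_days=float(np.exp(3.5)), onset_sigma=1.0)],
            pt_catalog=[PTSpec(name="Dizziness", baseline_rate=0.01),
                        PTSpec(name="Fatigue", baseline_rate=0.9)],
            missingness={"therapy_start": 0.0, "event_dt": 0.0},
            seed=9,
        )
        reports, _ = generate_reports(cfg)
        onsets = [time_to_onset(r)[0] for r in reports]
        onsets = [o for o in onsets if o is not None]
        assert np.median(onsets) == pytest.approx(np.exp(3.5), rel=0.05)


class TestCompareGroups:
    def test_identical_samples_mann_whitney(self):
        x = list(range(20))
        res = compare_groups(x + x, ["a"] * 20 + ["b"] * 20, family="onset")
        names = {r.test for r in res}
        assert names == {"log-rank", "Mann-Whitney U"}
        mwu = next(r for r in res if r.test == "Mann-Whitney U")
        assert mwu.statistic == pytest.approx(20 * 20 / 2)
        logrank = next(r for r in res if r.test == "log-rank")
        assert logrank.statistic == pytest.approx(0.0, abs=1e-10)

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 500)
        b = rng.normal(2, 1, 500)  # 2 SD shift
        res = compare_groups(
            np.concatenate([a, b]) + 10, ["a"] * 500 + ["b"] * 500, family="continuous"
        )
        assert res[0].p_value < 1e-3

    def test_three_groups_kruskal(self):
        rng = np.random.default_rng(3)
        vals = rng.exponential(30, 90)
        groups = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
        res = compare_groups(vals, groups, family="onset")
        assert {r.test for r in res} == {"log-rank", "Kruskal-Wallis"}

    def test_empty_group_error_names_group(self):
        # three declared groups, one with no observations
        labels = pd.Categorical(["a", "a", "c", "c"], categories=["a", "b", "c"])
        with pytest.raises(ValueError, match="'b'"):
            compare_groups([1.0, 2.0, 3.0, 4.0], labels, family="onset")
        with pytest.raises(ValueError, match="two groups"):
            compare_groups([1.0, 2.0], ["a", "a"], family="onset")

    def test_normality_gate_selects_t_test(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 200), rng.normal(0.1, 1, 200)
        res = compare_groups(np.concatenate([a, b]), ["a"] * 200 + ["b"] * 200,
                             family="continuous")
        assert res[0].test == "t-test"


class TestSeriousOutcomeTest:
    def _cohort(self, table):
        rows = []
        for g, (serious, nonserious) in table.items():
            rows += [{"drug": g, "outcome_class": "serious"}] * serious
            rows += [{"drug": g, "outcome_class": "nonserious"}] * nonserious
        return pd.DataFrame(rows)

    def test_reported_serious_proportions(self):
        res = serious_outcome_test(
            self._cohort({"cemiplimab": (75, 33), "pembrolizumab": (1866, 1226)}), "drug"
        )
        assert res.group_stats["cemiplimab"]["serious_pct"] == pytest.approx(69.44, abs=0.01)
        assert res.group_stats["pembrolizumab"]["serious_pct"] == pytest.approx(60.35, abs=0.01)

    def test_equal_proportions_null(self):
        res = serious_outcome_test(self._cohort({"a": (50, 50), "b": (50, 50)}), "drug")
        assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)

    def test_closed_form_two_by_two(self):
        # N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 80*800^2/40^4 = 20
        res = serious_outcome_test(self._cohort({"a": (30, 10), "b": (10, 30)}), "drug")
        assert res.statistic == pytest.approx(20.0, rel=1e-12)

    def test_low_expected_cell_warning(self):
        res = serious_outcome_test(self._cohort({"a": (1, 120), "b": (0, 2)}), "drug")
        assert "low_expected_cell" in res.warnings


class TestQuarterlyTrend:
    def test_exact_line(self):
        fit = quarterly_trend([10, 20, 30, 40])
        assert fit.slope == pytest.approx(10.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_counts(self):
        fit = quarterly_trend([5, 5, 5, 5, 5])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_too_few_quarters(self):
        with pytest.raises(ValueError):
            quarterly_trend([1, 2])

    def test_estimator_wrapper_predicts(self):
        reg = TrendRegressor().fit([10, 20, 30, 40])
        assert reg.slope_ == pytest.approx(10.0)
        assert reg.predict([4])[0] == pytest.approx(50.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e4), min_size=3, max_size=40))
    def test_matches_closed_form_ols(self, counts):
        y = np.asarray(counts)
        x = np.arange(len(y), dtype=float)
        denom = ((x - x.mean()) ** 2).sum()
        if denom == 0:
            return
        slope = float(((x - x.mean()) * (y - y.mean())).sum() / denom)
        fit = quarterly_trend(y)
        assert fit.slope == pytest.approx(slope, rel=1e-10, abs=1e-10)
        assert fit.intercept == pytest.approx(y.mean() - slope * x.mean(), rel=1e-10, abs=1e-8)
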