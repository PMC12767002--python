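"""Time-to-onset, group comparisons, severity tests and quarterly trends.

Onset is the number of whole days from the earliest primary-suspect therapy
start to the adverse-event onset date.  Spontaneous reports carry no
censoring information, so log-rank comparisons treat every onset as an
observed event — a documented approximation.  Continuous comparisons pass
through a normality gate (Shapiro-Wilk for n <= 50, Kolmogorov-Smirnov
above) that selects parametric vs rank-based tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "time_to_onset",
    "OnsetSummary",
    "summarize_onset",
    "ComparisonResult",
    "compare_groups",
    "serious_outcome_test",
    "TrendFit",
    "quarterly_trend",
    "TrendRegressor",
]


def time_to_onset(report) -> tuple[Optional[int], Optional[str]]:
    """Onset days = event date minus the earliest PS therapy start.

    Returns ``(days, None)`` when computable, otherwise ``(None, reason)``
    with reason in {"no_event_date", "no_therapy_start", "negative"}.
    Negative differences are data inconsistencies: excluded, never clipped.
    """
    if report.event_dt is None:
        return None, "no_event_date"
    starts = [d.therapy_start for d in report.drugs if d.role == "PS" and d.therapy_start]
    if not starts:
        return None, "no_therapy_start"
    days = (report.event_dt - min(starts)).days
    if days < 0:
        return None, "negative"
    return days, None


@dataclass
class OnsetSummary:
    group: str
    n: int
    median: float
    q1: float
    q3: float
    mean: float
    sd: float
    within_60d: float  # fraction of onsets within 2 months


def _quantiles(x: np.ndarray) -> tuple[float, float, float]:
    # linear interpolation between order statistics
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return float(q1), float(med), float(q3)


def summarize_onset(
    onset_days: Sequence[float],
    groups: Optional[Sequence] = None,
) -> list:
    """Per-group onset summaries (median, IQR, mean, SD, <=60-day fraction).

    Missing onsets must be excluded upstream; empty groups are omitted.
    """
    x = np.asarray(onset_days, dtype=float)
    if groups is None:
        groups = ["all"] * len(x)
    df = pd.DataFrame({"onset": x, "group": list(groups)})
    out = []
    for g, sub in df.groupby("group", sort=True):
        vals = sub["onset"].to_numpy()
        if len(vals) == 0:
            continue
        q1, med, q3 = _quantiles(vals)
        out.append(
            OnsetSummary(
                group=str(g),
                n=len(vals),
                median=med,
                q1=q1,
                q3=q3,
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                within_60d=float((vals <= 60).mean()),
            )
        )
    return out


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    group_stats: dict = field(default_factory=dict)
    warnings: tuple = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0) and not np.isnan(self.p_value):
            raise ValueError("p-value outside [0, 1]")


def _split_groups(values, groups) -> dict:
    df = pd.DataFrame({"v": np.asarray(values, dtype=float)})
    df["g"] = pd.Series(list(groups), index=df.index)
    split = {g: sub["v"].to_numpy() for g, sub in df.groupby("g", sort=True, observed=False)}
    # declared-but-unobserved levels (categorical labels) are empty groups
    if isinstance(groups, pd.Series) and isinstance(groups.dtype, pd.CategoricalDtype):
        declared = list(groups.cat.categories)
    elif isinstance(groups, pd.Categorical):
        declared = list(groups.categories)
    else:
        declared = list(split)
    for g in declared:
        if len(split.get(g, ())) == 0:
            raise ValueError(f"group {g!r} is empty")
    if len(split) < 2:
        raise ValueError("need at least two groups to compare")
    return split


def _rank_test(split: dict) -> ComparisonResult:
    samples = list(split.values())
    if len(samples) == 2:
        stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        name = "Mann-Whitney U"
    else:
        stat, p = stats.kruskal(*samples)
        name = "Kruskal-Wallis"
    return ComparisonResult(
        test=name,
        statistic=float(stat),
        p_value=float(p),
        group_stats={g: _group_stats(v) for g, v in split.items()},
    )


def _group_stats(vals: np.ndarray) -> dict:
    q1, med, q3 = _quantiles(vals)
    return {"n": int(len(vals)), "median": med, "iqr": (q1, q3)}


def _is_normal(vals: np.ndarray, alpha: float = 0.05) -> bool:
    """Normality gate: Shapiro-Wilk for n <= 50, else KS against a fitted normal."""
    if len(vals) < 3 or np.ptp(vals) == 0:
        return False
    if len(vals) <= 50:
        return stats.shapiro(vals).pvalue > alpha
    z = (vals - vals.mean()) / vals.std(ddof=1)
    return stats.kstest(z, "norm").pvalue > alpha


def compare_groups(values, groups, family: str = "onset") -> list:
    """Compare a quantity across groups.

    family="onset": report both a log-rank test (all events observed, no
    censoring) and the rank test (Mann-Whitney for two groups, Kruskal-
    Wallis for more).  family="continuous": the normality gate selects
    t-test/ANOVA vs the rank-based alternative; a single result is returned
    in a one-element list.  All tests two-sided.
    """
    split = _split_groups(values, groups)
    if family == "onset":
        durations = np.asarray(values, dtype=float)
        labels = np.asarray(list(groups))
        lr = multivariate_logrank_test(durations, labels, np.ones(len(durations)))
        results = [
            ComparisonResult(
                test="log-rank",
                statistic=float(lr.test_statistic),
                p_value=float(lr.p_value),
                group_stats={g: _group_stats(v) for g, v in split.items()},
            ),
            _rank_test(split),
        ]
        return results
    if family == "continuous":
        if all(_is_normal(v) for v in split.values()):
            samples = list(split.values())
            if len(samples) == 2:
                stat, p = stats.ttest_ind(samples[0], samples[1])
                name = "t-test"
            else:
                stat, p = stats.f_oneway(*samples)
                name = "ANOVA"
            return [
                ComparisonResult(
                    test=name,
                    statistic=float(stat),
                    p_value=float(p),
                    group_stats={g: _group_stats(v) for g, v in split.items()},
                )
            ]
        return [_rank_test(split)]
    raise ValueError(f"unknown family {family!r}")


def serious_outcome_test(
    cohort: pd.DataFrame,
    grouping: str,
    correction: bool = False,
) -> ComparisonResult:
    """Pearson chi-square on the (group x serious/nonserious) table.

    Rows with missing outcome class or missing group label are excluded and
    counted; expected cells below 1 raise a warning flag but the statistic
    is still computed.
    """
    sub = cohort[cohort["outcome_class"].isin(["serious", "nonserious"])]
    sub = sub[sub[grouping].notna()]
    n_excluded = len(cohort) - len(sub)
    table = pd.crosstab(sub[grouping], sub["outcome_class"])
    if table.shape[0] < 2:
        raise ValueError(f"grouping {grouping!r} has fewer than two observed levels")
    counts = table.to_numpy()
    chi2, p, _dof, expected = stats.chi2_contingency(counts, correction=correction)
    warnings = []
    if (expected < 1).any():
        warnings.append("low_expected_cell")
    group_stats = {}
    for g, row in table.iterrows():
        tot = int(row.sum())
        group_stats[g] = {
            "n": tot,
            "serious": int(row.get("serious", 0)),
            "serious_pct": 100.0 * row.get("serious", 0) / tot if tot else float("nan"),
        }
    group_stats["_excluded_missing"] = n_excluded
    return ComparisonResult(
        test="chi-square",
        statistic=float(chi2),
        p_value=float(p),
        group_stats=group_stats,
        warnings=tuple(warnings),
    )


@dataclass
class TrendFit:
    slope: float
    slope_low: float
    slope_high: float
    p_value: float
    r_squared: float
    intercept: float
    n_quarters: int

    def __post_init__(self) -> None:
        if self.n_quarters >= 3 and not (self.slope_low <= self.slope <= self.slope_high):
            raise ValueError("confidence interval does not bracket the slope")


def quarterly_trend(quarter_counts: Sequence[float]) -> TrendFit:
    """OLS of quarterly event counts on the quarter index 0,1,2,...

    Slope units are cases per quarter; the 95% CI uses the t distribution
    with n-2 degrees of freedom.
    """
    y = np.asarray(quarter_counts, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("quarterly trend needs at least 3 quarters")
    import statsmodels.api as sm

    x = np.arange(n, dtype=float)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    # constant counts have zero total variance: R^2 is 0 by convention
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = float(fit.rsquared) if tss > 0 else 0.0
    return TrendFit(
        slope=float(fit.params[1]),
        slope_low=float(ci[1, 0]),
        slope_high=float(ci[1, 1]),
        p_value=float(fit.pvalues[1]),
        r_squared=r2,
        intercept=float(fit.params[0]),
        n_quarters=n,
    )


class TrendRegressor(BaseEstimator):
    """Linear trend of quarterly aggregated event counts (sklearn-style).

    fit(y) regresses counts on the quarter index; fitted attributes carry
    the slope (cases per quarter), its 95% CI, p-value and R^2.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, y, X=None) -> "TrendRegressor":
        res = quarterly_trend(y)
        self.result_ = res
        self.slope_ = res.slope
        self.intercept_ = res.intercept
        self.conf_int_ = (res.slope_low, res.slope_high)
        self.p_value_ = res.p_value
        self.r_squared_ = res.r_squared
        self.n_quarters_ = res.n_quarters
        return self

    def predict(self, quarter_index) -> np.ndarray:
        q = np.asarray(quarter_index, dtype=float)
        return self.intercept_ + self.slope_ * q
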