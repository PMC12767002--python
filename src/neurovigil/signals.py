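"""Case/noncase disproportionality statistics: ROR, PRR, IC and signal rules.

The 2x2 table partitions deduplicated reports by (target drug as primary
suspect) x (target event reported):

    a  target drug & target event        b  target drug, other events
    c  other drugs, target event         d  other drugs, other events

ROR = ad/bc with a Wald CI on the log scale; PRR = [a/(a+b)]/[c/(c+d)];
IC = log2 of observed over expected joint reporting probability.  The
compound per-PT signal rule requires at least three reports, IC025 > 0 and
the ROR lower bound above one; the class-level rule requires only the ROR
lower bound above one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "ContingencyTable",
    "EstimateCI",
    "SignalResult",
    "build_2x2",
    "ror",
    "prr",
    "ic",
    "signal_result",
    "evaluate_signal",
    "SignalScreen",
]

Z95 = 1.959963984540054  # standard normal 0.975 quantile


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def corrected(self) -> tuple[float, float, float, float]:
        """Haldane-Anscombe 0.5 continuity correction applied to all cells."""
        return self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5


@dataclass(frozen=True)
class EstimateCI:
    estimate: float
    low: float
    high: float
    defined: bool = True
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.defined and not (self.low <= self.estimate <= self.high):
            raise ValueError("confidence interval does not bracket the estimate")


_UNDEFINED = EstimateCI(float("nan"), float("nan"), float("nan"), defined=False)


def _cells(t: ContingencyTable, policy: str) -> Optional[tuple]:
    has_zero = 0 in (t.a, t.b, t.c, t.d)
    if not has_zero:
        return (float(t.a), float(t.b), float(t.c), float(t.d), False)
    if policy == "strict":
        return None
    if policy == "haldane":
        return (*t.corrected(), True)
    raise ValueError(f"unknown zero-cell policy {policy!r}")


def _wald_se(a: float, b: float, c: float, d: float) -> float:
    return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def ror(t: ContingencyTable, policy: str = "strict") -> EstimateCI:
    """Reporting odds ratio ad/bc with 95% CI exp(ln ROR +- 1.96 SE).

    policy="strict" marks any zero cell undefined; policy="haldane" adds
    0.5 to every cell and flags the result corrected.
    """
    cells = _cells(t, policy)
    if cells is None:
        return _UNDEFINED
    a, b, c, d, corrected = cells
    est = (a * d) / (b * c)
    se = _wald_se(a, b, c, d)
    return EstimateCI(est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se), corrected=corrected)


def prr(t: ContingencyTable, policy: str = "strict", se_style: str = "conventional") -> EstimateCI:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)] with 95% CI.

    se_style="conventional" uses SE = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d));
    se_style="ror" reproduces the printed ROR-style SE sqrt(1/a+1/b+1/c+1/d).
    """
    cells = _cells(t, policy)
    if cells is None:
        return _UNDEFINED
    a, b, c, d, corrected = cells
    est = (a / (a + b)) / (c / (c + d))
    if se_style == "conventional":
        se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    elif se_style == "ror":
        se = _wald_se(a, b, c, d)
    else:
        raise ValueError(f"unknown se_style {se_style!r}")
    return EstimateCI(est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se), corrected=corrected)


def ic(t: ContingencyTable, policy: str = "strict", se_scale: str = "log2") -> EstimateCI:
    """Information component log2(a*N / ((a+b)(a+c))) with 95% CI.

    se_scale="log2" (default) divides the Wald SE sqrt(1/a+1/b+1/c+1/d) by
    ln 2, the delta-method scale matching the base-2 statistic; the
    anti-conservative variant that applies the natural-log-scale SE
    additively (se_scale="printed") is kept for comparison with published
    interval forms.
    """
    cells = _cells(t, policy)
    if cells is None:
        return _UNDEFINED
    a, b, c, d, corrected = cells
    n = a + b + c + d
    est = math.log2(a * n / ((a + b) * (a + c)))
    se = _wald_se(a, b, c, d)
    if se_scale == "log2":
        se /= math.log(2)
    elif se_scale != "printed":
        raise ValueError(f"unknown se_scale {se_scale!r}")
    return EstimateCI(est, est - Z95 * se, est + Z95 * se, corrected=corrected)


@dataclass(frozen=True)
class SignalResult:
    drug: str
    event: str
    table: ContingencyTable
    ror: EstimateCI
    prr: EstimateCI
    ic: EstimateCI
    signal_overall: bool
    signal_pt: bool
    failed_criteria: tuple

    @property
    def n_cases(self) -> int:
        return self.table.a

    @property
    def ic025(self) -> float:
        return self.ic.low


def _exposed_mask(cohort: pd.DataFrame, drug) -> pd.Series:
    if drug == "any" or drug is None:
        return cohort["exposed"].astype(bool)
    if isinstance(drug, (list, tuple, set, frozenset)):
        targets = set(drug)
        return cohort["ps_ingredients"].map(lambda s: bool(targets & set(s)))
    return cohort["ps_ingredients"].map(lambda s: drug in s)


def _case_mask(cohort: pd.DataFrame, event: str) -> pd.Series:
    if event == "nae":
        return cohort["nae_case"].astype(bool)
    return cohort["reactions"].map(lambda pts: event in pts)


def build_2x2(cohort: pd.DataFrame, drug, event: str) -> ContingencyTable:
    """Partition the cohort into the a/b/c/d cells for one (drug, event).

    ``drug`` is an ingredient, a collection of ingredients, or "any" for the
    whole target class; ``event`` is "nae" for the aggregate neurological
    flag or a single PT name.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    exposed = _exposed_mask(cohort, drug)
    case = _case_mask(cohort, event)
    a = int((exposed & case).sum())
    b = int((exposed & ~case).sum())
    c = int((~exposed & case).sum())
    d = int((~exposed & ~case).sum())
    return ContingencyTable(a, b, c, d)


def evaluate_signal(
    n_cases: int,
    ror_ci: EstimateCI,
    ic_ci: EstimateCI,
    level: str = "pt",
) -> tuple[bool, tuple]:
    """Apply the signal criterion; returns (verdict, failed criteria).

    level="overall": ROR lower bound > 1.  level="pt": additionally at least
    three reports and IC025 > 0.  Undefined components fail with reason
    "undefined".
    """
    failed = []
    if level not in {"overall", "pt"}:
        raise ValueError(f"unknown signal level {level!r}")
    if not ror_ci.defined:
        failed.append("undefined")
    elif not ror_ci.low > 1.0:
        failed.append("ror_low<=1")
    if level == "pt":
        if n_cases < 3:
            failed.append("n<3")
        if not ic_ci.defined:
            if "undefined" not in failed:
                failed.append("undefined")
        elif not ic_ci.low > 0.0:
            failed.append("ic025<=0")
    return (not failed), tuple(failed)


def signal_result(
    cohort: pd.DataFrame,
    drug,
    event: str,
    policy: str = "strict",
    prr_se_style: str = "conventional",
    ic_se_scale: str = "log2",
) -> SignalResult:
    """Full disproportionality result for one (drug, event) pair."""
    t = build_2x2(cohort, drug, event)
    r = ror(t, policy=policy)
    p = prr(t, policy=policy, se_style=prr_se_style)
    i = ic(t, policy=policy, se_scale=ic_se_scale)
    overall, _ = evaluate_signal(t.a, r, i, level="overall")
    pt_verdict, failed = evaluate_signal(t.a, r, i, level="pt")
    drug_label = drug if isinstance(drug, str) else "+".join(sorted(drug))
    return SignalResult(
        drug=drug_label or "any",
        event=event,
        table=t,
        ror=r,
        prr=p,
        ic=i,
        signal_overall=overall,
        signal_pt=pt_verdict,
        failed_criteria=failed,
    )


class SignalScreen(BaseEstimator):
    """Disproportionality screen over (drug, PT) pairs (sklearn-style).

    Parameters
    ----------
    drugs : list of ingredients to screen ("any" entries screen the whole
        exposed class).
    events : list of PT names, or None to screen every PT reported on at
        least one case row plus the aggregate "nae" flag.
    policy : zero-cell policy, "strict" or "haldane".

    After ``fit(cohort)`` the attribute ``signals_`` holds one row per pair
    with counts, ROR/PRR/IC estimates and CIs, and both signal verdicts.
    No multiple-testing adjustment is applied across PTs.
    """

    def __init__(
        self,
        drugs: Sequence = ("any",),
        events: Optional[Sequence[str]] = None,
        policy: str = "strict",
        prr_se_style: str = "conventional",
        ic_se_scale: str = "log2",
    ):
        self.drugs = drugs
        self.events = events
        self.policy = policy
        self.prr_se_style = prr_se_style
        self.ic_se_scale = ic_se_scale

    def fit(self, cohort: pd.DataFrame, y=None) -> "SignalScreen":
        if self.events is None:
            pts: set = set()
            for tup in cohort.loc[cohort["nae_case"], "nae_pts"]:
                pts.update(tup)
            events = ["nae"] + sorted(pts)
        else:
            events = list(self.events)
        rows = []
        self.results_ = []
        for drug in self.drugs:
            for event in events:
                res = signal_result(
                    cohort,
                    drug,
                    event,
                    policy=self.policy,
                    prr_se_style=self.prr_se_style,
                    ic_se_scale=self.ic_se_scale,
                )
                self.results_.append(res)
                rows.append(
                    {
                        "drug": res.drug,
                        "event": event,
                        "a": res.table.a,
                        "b": res.table.b,
                        "c": res.table.c,
                        "d": res.table.d,
                        "ror": res.ror.estimate,
                        "ror_low": res.ror.low,
                        "ror_high": res.ror.high,
                        "prr": res.prr.estimate,
                        "prr_low": res.prr.low,
                        "prr_high": res.prr.high,
                        "ic": res.ic.estimate,
                        "ic025": res.ic.low,
                        "ic_high": res.ic.high,
                        "signal_overall": res.signal_overall,
                        "signal_pt": res.signal_pt,
                        "failed": ";".join(res.failed_criteria),
                    }
                )
        self.signals_ = pd.DataFrame(rows)
        self.n_pairs_ = len(rows)
        return self
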