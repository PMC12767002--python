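"""Logistic risk-factor models and E-value sensitivity analysis.

Risk factors for the neurological-event outcome are assessed with
complete-case logistic regression (maximum likelihood, Wald intervals).
Two sequential adjustment sets mirror a minimal and an extended confounder
model: Model 1 = reporter type + US-vs-other region + mono/polypharmacy;
Model 2 additionally adjusts for age (continuous), sex and body weight
(continuous).  E-values quantify the minimum risk-ratio association an
unmeasured confounder would need with both exposure and outcome to explain
away an estimate, treating reporting odds ratios as risk-ratio
approximations under the rare-outcome assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = [
    "ModelSpec",
    "MODEL1",
    "MODEL2",
    "ORResult",
    "AdjustedModelResult",
    "EValueResult",
    "univariate_or",
    "fit_adjusted",
    "evalue",
    "LogisticRiskModel",
]

Z95 = 1.959963984540054

# Canonical adjustment sets; names refer to cohort-table columns.
MODEL1_ADJUSTMENT = ("reporter_professional", "us", "polypharmacy")
MODEL2_ADJUSTMENT = MODEL1_ADJUSTMENT + ("age_years", "male", "weight_kg")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one adjusted logistic model."""

    outcome: str = "nae_case"
    exposure: str = "exposed"
    adjustment: tuple = MODEL1_ADJUSTMENT
    min_complete: int = 50  # floor below which the fit is non-estimable


MODEL1 = ModelSpec(adjustment=MODEL1_ADJUSTMENT)
MODEL2 = ModelSpec(adjustment=MODEL2_ADJUSTMENT)


@dataclass
class ORResult:
    term: str
    odds_ratio: float
    low: float
    high: float
    p_value: float
    n: int
    estimable: bool = True
    reason: Optional[str] = None


@dataclass
class AdjustedModelResult:
    aror: float
    low: float
    high: float
    p_value: float
    n_complete: int
    n_dropped: int
    cells: dict = field(default_factory=dict)  # exposure x outcome counts
    estimable: bool = True
    reason: Optional[str] = None
    terms: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.estimable and not (self.low <= self.aror <= self.high):
            raise ValueError("confidence interval does not bracket the aROR")


def _design_columns(cohort: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    """Derive model columns from the cohort table; NaN marks missing."""
    out = pd.DataFrame(index=cohort.index)
    for name in names:
        if name == "reporter_professional":
            col = cohort["reporter"].map(
                {"professional": 1.0, "nonprofessional": 0.0}
            )
        elif name == "us":
            col = cohort["us"].map({True: 1.0, False: 0.0})
        elif name == "male":
            col = cohort["sex"].map({"M": 1.0, "F": 0.0})
        elif name == "polypharmacy":
            col = cohort["polypharmacy"].astype(float)
        elif name in cohort.columns:
            raw = cohort[name]
            if raw.dtype == object:
                col = raw.map(lambda v: np.nan if v is None else float(v))
            else:
                col = raw.astype(float)
        else:
            raise KeyError(f"unknown model variable {name!r}")
        out[name] = col
    return out


def _logit_fit(y: np.ndarray, X: pd.DataFrame):
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    return model.fit(disp=0, maxiter=200)


def univariate_or(
    cohort: pd.DataFrame,
    factor: str,
    outcome: str = "nae_case",
    reference_level=None,
) -> list:
    """Single-covariate logistic odds ratios for each non-reference level.

    Complete-case on {factor, outcome}.  For a binary factor the OR equals
    the 2x2 cross-product ratio (an algebraic identity of the logistic MLE).
    Separation (a zero cell against the outcome) flags the level
    non-estimable instead of silently returning a diverged fit.
    """
    sub = cohort[[factor, outcome]].copy()
    sub = sub[sub[factor].notna() & sub[outcome].notna()]
    n = len(sub)
    levels = sorted(sub[factor].unique(), key=str)
    if len(levels) < 2:
        return [
            ORResult(
                term=f"{factor}", odds_ratio=float("nan"), low=float("nan"),
                high=float("nan"), p_value=float("nan"), n=n,
                estimable=False, reason="single_level",
            )
        ]
    if reference_level is None:
        reference_level = levels[0]
    y = sub[outcome].astype(float).to_numpy()
    results = []
    for level in levels:
        if level == reference_level:
            continue
        mask = sub[factor].isin([reference_level, level])
        x = (sub.loc[mask, factor] == level).astype(float)
        yy = y[mask.to_numpy()]
        tab = pd.crosstab(x, yy)
        if tab.shape != (2, 2) or (tab.to_numpy() == 0).any():
            results.append(
                ORResult(
                    term=f"{factor}={level}", odds_ratio=float("nan"),
                    low=float("nan"), high=float("nan"), p_value=float("nan"),
                    n=int(mask.sum()), estimable=False, reason="separation",
                )
            )
            continue
        fit = _logit_fit(yy, x.to_frame(name=factor))
        beta = fit.params[factor]
        se = fit.bse[factor]
        results.append(
            ORResult(
                term=f"{factor}={level}",
                odds_ratio=math.exp(beta),
                low=math.exp(beta - Z95 * se),
                high=math.exp(beta + Z95 * se),
                p_value=float(fit.pvalues[factor]),
                n=int(mask.sum()),
            )
        )
    return results


def fit_adjusted(cohort: pd.DataFrame, spec: ModelSpec = MODEL1) -> AdjustedModelResult:
    """Multivariable logistic fit of outcome on exposure + adjustment set.

    Complete-case: rows missing any model variable are dropped and counted.
    Continuous covariates enter untransformed.  Fits with fewer complete
    rows than ``spec.min_complete`` are flagged non-estimable.
    """
    names = [spec.exposure, *spec.adjustment]
    X = _design_columns(cohort, names)
    y = cohort[spec.outcome].astype(float)
    keep = X.notna().all(axis=1) & y.notna()
    n_complete = int(keep.sum())
    n_dropped = len(cohort) - n_complete
    Xc, yc = X[keep], y[keep].to_numpy()

    exp_col = Xc[spec.exposure]
    cells = {
        "exposed_case": int(((exp_col == 1) & (yc == 1)).sum()),
        "exposed_noncase": int(((exp_col == 1) & (yc == 0)).sum()),
        "unexposed_case": int(((exp_col == 0) & (yc == 1)).sum()),
        "unexposed_noncase": int(((exp_col == 0) & (yc == 0)).sum()),
    }

    def _failed(reason: str) -> AdjustedModelResult:
        return AdjustedModelResult(
            aror=float("nan"), low=float("nan"), high=float("nan"),
            p_value=float("nan"), n_complete=n_complete, n_dropped=n_dropped,
            cells=cells, estimable=False, reason=reason,
        )

    if n_complete < spec.min_complete:
        return _failed("below_min_complete")
    if min(cells.values()) == 0:
        return _failed("separation")
    # drop adjustment columns with no variation among complete cases
    varying = [c for c in Xc.columns if Xc[c].nunique() > 1 or c == spec.exposure]
    if spec.exposure not in varying or Xc[spec.exposure].nunique() < 2:
        return _failed("constant_exposure")
    try:
        fit = _logit_fit(yc, Xc[varying])
    except Exception:
        return _failed("fit_failure")
    beta = fit.params[spec.exposure]
    se = fit.bse[spec.exposure]
    if not np.isfinite(beta) or not np.isfinite(se) or se > 50:
        return _failed("fit_failure")
    terms = pd.DataFrame(
        {
            "term": fit.params.index,
            "or": np.exp(fit.params.values),
            "low": np.exp(fit.params.values - Z95 * fit.bse.values),
            "high": np.exp(fit.params.values + Z95 * fit.bse.values),
            "p": fit.pvalues.values,
        }
    )
    return AdjustedModelResult(
        aror=math.exp(beta),
        low=math.exp(beta - Z95 * se),
        high=math.exp(beta + Z95 * se),
        p_value=float(fit.pvalues[spec.exposure]),
        n_complete=n_complete,
        n_dropped=n_dropped,
        cells=cells,
        terms=terms,
    )


@dataclass(frozen=True)
class EValueResult:
    rr: float
    evalue_point: float
    evalue_ci: Optional[float]

    def __post_init__(self) -> None:
        if self.evalue_point < 1:
            raise ValueError("E-value below 1")
        if self.evalue_ci is not None and self.evalue_point + 1e-12 < self.evalue_ci:
            raise ValueError("point E-value below CI E-value")


def _evalue_scalar(rr: float) -> float:
    if rr <= 0:
        raise ValueError("risk ratio must be positive")
    if rr < 1:
        rr = 1.0 / rr
    if rr == 1.0:
        return 1.0
    return rr + math.sqrt(rr * (rr - 1.0))


def evalue(
    rr_point: float,
    rr_low: Optional[float] = None,
    rr_high: Optional[float] = None,
) -> EValueResult:
    """E-value for a risk ratio and (optionally) its confidence interval.

    E = RR + sqrt(RR*(RR-1)) for RR > 1; protective estimates are inverted
    first; RR = 1 gives E = 1.  The CI E-value uses the bound closer to the
    null and is 1 when the interval includes 1.
    """
    if rr_point is None or rr_point <= 0:
        raise ValueError("risk ratio must be positive")
    point = _evalue_scalar(rr_point)
    ci = None
    if rr_low is not None and rr_high is not None:
        if rr_low <= 0 or rr_high <= 0 or rr_low > rr_high:
            raise ValueError("invalid confidence bounds")
        if rr_low <= 1.0 <= rr_high:
            ci = 1.0
        else:
            bound = rr_low if rr_point >= 1 else rr_high
            ci = _evalue_scalar(bound)
    return EValueResult(rr=rr_point, evalue_point=point, evalue_ci=ci)


class LogisticRiskModel(BaseEstimator):
    """Adjusted logistic model for a drug-exposure outcome (sklearn-style).

    Parameters name the model ("model1" / "model2") or give an explicit
    adjustment tuple.  ``fit(cohort)`` runs the complete-case ML fit;
    fitted attributes expose the aROR, its 95% CI, p-value, analysable-cell
    counts and the E-values for the point estimate and the CI bound closer
    to the null.
    """

    def __init__(
        self,
        model: str = "model1",
        outcome: str = "nae_case",
        exposure: str = "exposed",
        adjustment: Optional[tuple] = None,
        min_complete: int = 50,
    ):
        self.model = model
        self.outcome = outcome
        self.exposure = exposure
        self.adjustment = adjustment
        self.min_complete = min_complete

    def _spec(self) -> ModelSpec:
        if self.adjustment is not None:
            adj = tuple(self.adjustment)
        elif self.model == "model1":
            adj = MODEL1_ADJUSTMENT
        elif self.model == "model2":
            adj = MODEL2_ADJUSTMENT
        else:
            raise ValueError(f"unknown model {self.model!r}")
        return ModelSpec(
            outcome=self.outcome,
            exposure=self.exposure,
            adjustment=adj,
            min_complete=self.min_complete,
        )

    def fit(self, cohort: pd.DataFrame, y=None) -> "LogisticRiskModel":
        res = fit_adjusted(cohort, self._spec())
        self.result_ = res
        self.aror_ = res.aror
        self.conf_int_ = (res.low, res.high)
        self.p_value_ = res.p_value
        self.n_complete_ = res.n_complete
        self.estimable_ = res.estimable
        if res.estimable and res.aror > 0:
            ev = evalue(res.aror, res.low, res.high)
            self.evalue_point_ = ev.evalue_point
            self.evalue_ci_ = ev.evalue_ci
        else:
            self.evalue_point_ = None
            self.evalue_ci_ = None
        return self
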