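"""Synthetic FAERS-like report generator with known ground truth.

Every downstream stage (ingestion, deduplication, signal detection, risk
models, onset and trend analyses) is testable against planted truth: each
report draws one exposure drug and a set of reaction PTs whose inclusion
probability is baseline rate x a per-(drug, PT) multiplier x a logistic
covariate adjustment, so for rare events the marginal 2x2 odds ratio
approaches the planted multiplier.  Field-level missingness, near-copy
duplicate submissions, drug role codes, brand/generic naming and outcome
codes emulate the structure and data-quality profile of real spontaneous
reports (weight missing in ~70% of reports, onset information in ~61%,
age in ~25%).

Random streams are split per field (fixed stream keys) so adding a field
does not perturb the draws of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.special import expit, logit

from .cohort import MeddraHierarchy, NEURO_SOC
from .io import CaseReport, DrugRecord

__all__ = [
    "DrugSpec",
    "PTSpec",
    "CovariateModel",
    "SimConfig",
    "GroundTruth",
    "generate_reports",
    "inject_duplicates",
    "default_hierarchy",
    "default_config",
    "default_drug_dictionary",
    "simulate_logistic_cohort",
    "TARGET_INGREDIENTS",
]

TARGET_INGREDIENTS = ("nivolumab", "pembrolizumab", "cemiplimab")

# fixed per-field stream keys (seed, key) -> independent generator
_STREAMS = {
    "drug": 1, "age": 2, "sex": 3, "weight": 4, "country": 5, "reporter": 6,
    "indication": 7, "concomitant": 8, "reactions": 9, "onset": 10,
    "event_dt": 11, "serious": 12, "missing": 13, "names": 14, "fda_dt": 15,
    "duplicates": 16, "fill": 17,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


def parse_quarter(label: str) -> Tuple[int, int]:
    year, q = label.upper().split("Q")
    y, q = int(year), int(q)
    if not 1 <= q <= 4:
        raise ValueError(f"invalid quarter {label!r}")
    return y, q


def quarter_start(label: str) -> date:
    y, q = parse_quarter(label)
    return date(y, 3 * (q - 1) + 1, 1)


def quarter_length(label: str) -> int:
    y, q = parse_quarter(label)
    nxt = date(y + 1, 1, 1) if q == 4 else date(y, 3 * q + 1, 1)
    return (nxt - quarter_start(label)).days


def quarter_index(label: str) -> int:
    y, q = parse_quarter(label)
    return 4 * y + (q - 1)


class DrugSpec(BaseModel):
    ingredient: str
    brands: List[str] = Field(default_factory=list)
    share: float = Field(gt=0)  # relative reporting weight
    start_quarter: Optional[str] = None  # marketing start; None = always
    is_target: bool = False
    onset_median_days: float = Field(default=34.0, gt=0)
    onset_sigma: float = Field(default=1.6, gt=0)
    serious_prob: float = Field(default=0.6, ge=0, le=1)


class PTSpec(BaseModel):
    name: str
    baseline_rate: float = Field(gt=0, lt=1)  # per-report inclusion probability


class CovariateModel(BaseModel):
    age_mean: float = 64.0
    age_sd: float = Field(default=14.0, gt=0)
    p_female: float = Field(default=0.42, ge=0, le=1)
    weight_mean: float = 72.0
    weight_sd: float = Field(default=21.0, gt=0)
    country_probs: Dict[str, float] = Field(
        default_factory=lambda: {
            "US": 0.33, "JP": 0.24, "FR": 0.08, "DE": 0.05, "GB": 0.03,
            "CN": 0.02, "OTHER": 0.25,
        }
    )
    p_professional: float = Field(default=0.70, ge=0, le=1)
    indication_probs: Dict[str, float] = Field(
        default_factory=lambda: {
            "Lung neoplasm malignant": 0.27, "Malignant melanoma": 0.21,
            "Renal cancer": 0.16, "Gastric cancer": 0.08,
            "Breast cancer": 0.05, "Hepatic cancer": 0.04, "OTHER": 0.19,
        }
    )
    concomitant_class_probs: Dict[str, float] = Field(
        default_factory=lambda: {
            "platinum": 0.11, "kinase_inhibitor": 0.07, "alkaloid": 0.07,
            "antimetabolite": 0.05,
        }
    )
    #: log-odds added to neurological-PT inclusion (centred covariates)
    log_odds: Dict[str, float] = Field(
        default_factory=lambda: {"age_per_year": 0.004, "female": 0.04, "weight_per_kg": 0.0}
    )

    @field_validator("country_probs", "indication_probs", "concomitant_class_probs")
    @classmethod
    def _probs_valid(cls, v):
        for k, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {k!r} outside [0, 1]")
        return v


class SimConfig(BaseModel):
    quarters: List[str]
    n_reports_per_quarter: List[int]
    drug_catalog: List[DrugSpec]
    pt_catalog: List[PTSpec]
    #: drug ingredient -> PT name -> reporting-rate multiplier (1 = null)
    effect_matrix: Dict[str, Dict[str, float]] = Field(default_factory=dict)
    covariate_model: CovariateModel = Field(default_factory=CovariateModel)
    #: per-field missing probabilities
    missingness: Dict[str, float] = Field(
        default_factory=lambda: {
            "age": 0.25, "sex": 0.076, "weight": 0.70, "therapy_start": 0.60,
            "event_dt": 0.03, "reporter": 0.15, "country": 0.02, "outcome": 0.078,
        }
    )
    duplicate_rate: float = Field(default=0.0, ge=0, lt=1)
    neuro_soc: str = NEURO_SOC
    hierarchy_links: Optional[List[Tuple[str, str, str, str, bool]]] = None
    seed: int = 0

    @field_validator("quarters")
    @classmethod
    def _quarters_increasing(cls, v):
        if not v:
            raise ValueError("quarters must be non-empty")
        idx = [quarter_index(q) for q in v]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("quarters must be strictly increasing")
        return v

    @field_validator("n_reports_per_quarter")
    @classmethod
    def _n_positive(cls, v):
        if any(n <= 0 for n in v):
            raise ValueError("n_reports_per_quarter entries must be positive")
        return v

    @field_validator("missingness")
    @classmethod
    def _missing_valid(cls, v):
        for k, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"missingness for {k!r} outside [0, 1]")
        return v

    @model_validator(mode="after")
    def _cross_checks(self):
        if len(self.n_reports_per_quarter) != len(self.quarters):
            raise ValueError("n_reports_per_quarter must match quarters in length")
        pts = {p.name for p in self.pt_catalog}
        drugs = {d.ingredient for d in self.drug_catalog}
        for drug, row in self.effect_matrix.items():
            if drug not in drugs:
                raise ValueError(f"effect_matrix drug {drug!r} not in drug_catalog")
            for pt, mult in row.items():
                if pt not in pts:
                    raise ValueError(f"effect_matrix PT {pt!r} not in pt_catalog")
                if mult < 0:
                    raise ValueError(f"multiplier for ({drug!r}, {pt!r}) must be >= 0")
        return self

    def hierarchy(self) -> MeddraHierarchy:
        if self.hierarchy_links is not None:
            return MeddraHierarchy([tuple(r) for r in self.hierarchy_links])
        return default_hierarchy()

    def multiplier(self, drug: str, pt: str) -> float:
        return self.effect_matrix.get(drug, {}).get(pt, 1.0)


@dataclass
class GroundTruth:
    """Planted generative quantities for recovery checks."""

    multipliers: dict  # (drug, pt) -> multiplier (1 where unplanted)
    covariate_log_odds: dict
    onset_medians: dict  # drug -> median onset days
    trend_slope: float  # expected neurological cases per quarter (OLS slope)
    expected_nae_rate: float


# --- default study conditions -------------------------------------------------

_NEURO_PTS = [
    # (name, HLT, HLGT, baseline per-report rate)
    ("Dizziness", "Neurological signs", "Neurological disorders NEC", 0.0060),
    ("Headache", "Headaches NEC", "Headaches", 0.0050),
    ("Peripheral neuropathy", "Peripheral neuropathies", "Neuropathies", 0.0030),
    ("Myasthenia gravis", "Myasthenic syndromes", "Neuromuscular disorders", 0.0008),
    ("Encephalitis", "Encephalitides", "CNS infections and inflammations", 0.0007),
    ("Cerebrovascular accident", "CNS haemorrhages and strokes", "Vascular CNS disorders", 0.0020),
    ("Seizure", "Seizures NEC", "Seizure disorders", 0.0015),
    ("Guillain-Barre syndrome", "Acute polyneuropathies", "Neuropathies", 0.0003),
    ("Myasthenic syndrome", "Myasthenic syndromes", "Neuromuscular disorders", 0.0002),
    ("Optic neuritis", "Optic nerve disorders", "Cranial nerve disorders", 0.0002),
    ("Tremor", "Tremor disorders", "Movement disorders", 0.0012),
    ("Syncope", "Disturbances of consciousness", "Neurological disorders NEC", 0.0025),
    ("Aphasia", "Speech disorders", "Neurological disorders NEC", 0.0004),
    ("Meningitis aseptic", "Meningitides", "CNS infections and inflammations", 0.0002),
    ("Facial paralysis", "Facial nerve disorders", "Cranial nerve disorders", 0.0004),
    ("Neuropathy cranial", "Cranial nerve palsies", "Cranial nerve disorders", 0.0001),
]

_BACKGROUND_PTS = [
    ("Fatigue", "Asthenic conditions", "General system disorders",
     "General disorders and administration site conditions", 0.070),
    ("Nausea", "Nausea and vomiting", "GI signs and symptoms",
     "Gastrointestinal disorders", 0.050),
    ("Malignant neoplasm progression", "Neoplasm progression", "Neoplasms malignant",
     "Neoplasms benign, malignant and unspecified", 0.060),
    ("Diarrhoea", "Diarrhoea", "GI motility disorders", "Gastrointestinal disorders", 0.040),
    ("Rash", "Rashes", "Epidermal conditions", "Skin and subcutaneous tissue disorders", 0.030),
    ("Pyrexia", "Febrile disorders", "Body temperature conditions",
     "General disorders and administration site conditions", 0.030),
    ("Pneumonitis", "Lower respiratory tract inflammations", "Respiratory disorders NEC",
     "Respiratory, thoracic and mediastinal disorders", 0.020),
    ("Hypothyroidism", "Thyroid hypofunction", "Thyroid disorders", "Endocrine disorders", 0.015),
    ("Colitis", "Colitis", "GI inflammatory conditions", "Gastrointestinal disorders", 0.015),
    ("Anaemia", "Anaemias NEC", "Anaemias", "Blood and lymphatic system disorders", 0.020),
    ("Vomiting", "Nausea and vomiting", "GI signs and symptoms",
     "Gastrointestinal disorders", 0.030),
    ("Decreased appetite", "Appetite disorders", "Appetite and general nutrition disorders",
     "Metabolism and nutrition disorders", 0.025),
]

# a PT whose *secondary* link is neurological must not qualify as a case
_MULTIAXIAL = [
    ("Visual impairment", "Visual disorders NEC", "Vision disorders",
     "Eye disorders", True, 0.004),
    ("Visual impairment", "Neuro-ophthalmological signs", "Cranial nerve disorders",
     NEURO_SOC, False, None),
]


def default_hierarchy() -> MeddraHierarchy:
    """Synthetic PT->HLT->HLGT->SOC table with a primary-SOC flag per PT."""
    links = [(pt, hlt, hlgt, NEURO_SOC, True) for pt, hlt, hlgt, _ in _NEURO_PTS]
    links += [(pt, hlt, hlgt, soc, True) for pt, hlt, hlgt, soc, _ in _BACKGROUND_PTS]
    links += [(pt, hlt, hlgt, soc, primary) for pt, hlt, hlgt, soc, primary, _ in _MULTIAXIAL]
    return MeddraHierarchy(links)


def _default_drugs() -> List[DrugSpec]:
    return [
        DrugSpec(ingredient="nivolumab", brands=["OPDIVO"], share=0.17, is_target=True,
                 start_quarter="2014Q4", onset_median_days=39, serious_prob=0.63),
        DrugSpec(ingredient="pembrolizumab", brands=["KEYTRUDA"], share=0.14, is_target=True,
                 start_quarter="2014Q4", onset_median_days=26, serious_prob=0.60),
        DrugSpec(ingredient="cemiplimab", brands=["LIBTAYO"], share=0.01, is_target=True,
                 start_quarter="2018Q4", onset_median_days=52, serious_prob=0.69),
        DrugSpec(ingredient="docetaxel", brands=["TAXOTERE"], share=0.14, onset_median_days=30,
                 serious_prob=0.55),
        DrugSpec(ingredient="carboplatin", brands=["PARAPLATIN"], share=0.13,
                 onset_median_days=25, serious_prob=0.58),
        DrugSpec(ingredient="osimertinib", brands=["TAGRISSO"], share=0.12,
                 onset_median_days=45, serious_prob=0.52),
        DrugSpec(ingredient="bevacizumab", brands=["AVASTIN"], share=0.15,
                 onset_median_days=40, serious_prob=0.57),
        DrugSpec(ingredient="sorafenib", brands=["NEXAVAR"], share=0.14,
                 onset_median_days=35, serious_prob=0.54),
    ]


def default_drug_dictionary() -> dict:
    """Brand/generic -> ingredient dictionary for the default catalog."""
    d = {}
    for spec in _default_drugs():
        d[spec.ingredient] = spec.ingredient
        for b in spec.brands:
            d[b] = spec.ingredient
    return d


def default_config(
    total_reports: int = 115_000,
    seed: int = 0,
    duplicate_rate: float = 0.02,
    effect_matrix: Optional[dict] = None,
) -> SimConfig:
    """Study-scale default: 39 quarters, linearly growing volume.

    The default effect matrix plants a mild class-level association of the
    three target drugs with the neurological PTs (multiplier 1.2) plus a
    stronger cemiplimab signal (1.4), mirroring the kind of signal the
    screen is meant to find; pass ``effect_matrix={}`` for a global null.
    """
    quarters = []
    y, q = 2014, 4
    for _ in range(39):
        quarters.append(f"{y}Q{q}")
        q += 1
        if q == 5:
            y, q = y + 1, 1
    # linear growth a + b*i scaled to the requested total
    weights = np.linspace(1.0, 6.4, num=39)
    n_q = np.maximum(1, np.round(weights / weights.sum() * total_reports)).astype(int)

    if effect_matrix is None:
        neuro = [name for name, *_ in _NEURO_PTS]
        effect_matrix = {
            "nivolumab": {pt: 1.2 for pt in neuro},
            "pembrolizumab": {pt: 1.25 for pt in neuro},
            "cemiplimab": {pt: 1.4 for pt in neuro},
        }
    return SimConfig(
        quarters=quarters,
        n_reports_per_quarter=[int(n) for n in n_q],
        drug_catalog=_default_drugs(),
        pt_catalog=[PTSpec(name=n, baseline_rate=r) for n, _h, _g, r in _NEURO_PTS]
        + [PTSpec(name=n, baseline_rate=r) for n, _h, _g, _s, r in _BACKGROUND_PTS]
        + [PTSpec(name="Visual impairment", baseline_rate=0.004)],
        effect_matrix=effect_matrix,
        duplicate_rate=duplicate_rate,
        seed=seed,
    )


def _expected_nae_rate(config: SimConfig, drug: DrugSpec, neuro_pts: list) -> float:
    p_none = 1.0
    for pt in neuro_pts:
        p_none *= 1.0 - min(1.0, pt.baseline_rate * config.multiplier(drug.ingredient, pt.name))
    return 1.0 - p_none


def _ground_truth(config: SimConfig, hierarchy: MeddraHierarchy) -> GroundTruth:
    neuro_pts = [p for p in config.pt_catalog if hierarchy.primary_soc(p.name) == config.neuro_soc]
    multipliers = {
        (d.ingredient, p.name): config.multiplier(d.ingredient, p.name)
        for d in config.drug_catalog
        for p in config.pt_catalog
    }
    # expected neurological cases per quarter under the drug mix
    rates = np.array([_expected_nae_rate(config, d, neuro_pts) for d in config.drug_catalog])
    shares = np.array([d.share for d in config.drug_catalog], dtype=float)
    starts = [d.start_quarter for d in config.drug_catalog]
    exp_counts = []
    for qi, (label, n_q) in enumerate(zip(config.quarters, config.n_reports_per_quarter)):
        avail = np.array(
            [s is None or quarter_index(s) <= quarter_index(label) for s in starts], dtype=float
        )
        w = shares * avail
        w = w / w.sum()
        exp_counts.append(n_q * float(w @ rates))
    x = np.arange(len(exp_counts), dtype=float)
    slope = float(np.polyfit(x, np.array(exp_counts), 1)[0]) if len(exp_counts) >= 2 else 0.0
    overall_rate = float(np.sum(exp_counts) / np.sum(config.n_reports_per_quarter))
    return GroundTruth(
        multipliers=multipliers,
        covariate_log_odds=dict(config.covariate_model.log_odds),
        onset_medians={d.ingredient: d.onset_median_days for d in config.drug_catalog},
        trend_slope=slope,
        expected_nae_rate=overall_rate,
    )


def generate_reports(config: SimConfig) -> Tuple[list, GroundTruth]:
    """Generate a reproducible report collection from a validated config.

    Returns the reports (including any injected duplicates) and the planted
    :class:`GroundTruth`.  Identical configs give byte-identical bundles.
    """
    hierarchy = config.hierarchy()
    cov = config.covariate_model
    seed = config.seed

    n_per_q = np.asarray(config.n_reports_per_quarter)
    n = int(n_per_q.sum())
    q_idx = np.repeat(np.arange(len(config.quarters)), n_per_q)

    drugs = config.drug_catalog
    n_drugs = len(drugs)
    shares = np.array([d.share for d in drugs], dtype=float)
    start_idx = np.array(
        [-(10**9) if d.start_quarter is None else quarter_index(d.start_quarter) for d in drugs]
    )
    q_abs = np.array([quarter_index(q) for q in config.quarters])

    rng_drug = _rng(seed, "drug")
    drug_idx = np.empty(n, dtype=int)
    pos = 0
    for qi, n_q in enumerate(n_per_q):
        avail = (start_idx <= q_abs[qi]).astype(float)
        w = shares * avail
        if w.sum() == 0:
            raise ValueError(f"no drug marketed in quarter {config.quarters[qi]}")
        w = w / w.sum()
        drug_idx[pos : pos + n_q] = rng_drug.choice(n_drugs, size=int(n_q), p=w)
        pos += int(n_q)

    age = np.clip(_rng(seed, "age").normal(cov.age_mean, cov.age_sd, size=n), 18, 95)
    female = _rng(seed, "sex").random(n) < cov.p_female
    weight = np.clip(_rng(seed, "weight").normal(cov.weight_mean, cov.weight_sd, size=n), 30, 200)

    countries = list(cov.country_probs)
    cp = np.array([cov.country_probs[c] for c in countries], dtype=float)
    country_idx = _rng(seed, "country").choice(len(countries), size=n, p=cp / cp.sum())
    professional = _rng(seed, "reporter").random(n) < cov.p_professional

    indics = list(cov.indication_probs)
    ip = np.array([cov.indication_probs[i] for i in indics], dtype=float)
    indi_idx = _rng(seed, "indication").choice(len(indics), size=n, p=ip / ip.sum())

    classes = list(cov.concomitant_class_probs)
    rng_con = _rng(seed, "concomitant")
    con_mask = rng_con.random((n, len(classes))) < np.array(
        [cov.concomitant_class_probs[c] for c in classes]
    )

    # reaction PT inclusion: logit(base * mult) + centred covariate term on
    # neurological PTs
    pts = config.pt_catalog
    pt_names = [p.name for p in pts]
    base = np.array([p.baseline_rate for p in pts])
    is_neuro = np.array([hierarchy.primary_soc(nm) == config.neuro_soc for nm in pt_names])
    mult = np.ones((n_drugs, len(pts)))
    for di, d in enumerate(drugs):
        for pi, p in enumerate(pts):
            mult[di, pi] = config.multiplier(d.ingredient, p.name)
    p0 = np.clip(base[None, :] * mult, 1e-12, 1 - 1e-9)
    logit0 = logit(p0)  # (drug, pt)

    lo = config.covariate_model.log_odds
    x_beta = (
        lo.get("age_per_year", 0.0) * (age - cov.age_mean)
        + lo.get("female", 0.0) * female.astype(float)
        + lo.get("weight_per_kg", 0.0) * (weight - cov.weight_mean)
    )
    logits = logit0[drug_idx, :] + np.where(is_neuro[None, :], x_beta[:, None], 0.0)
    probs = expit(logits)
    react_mask = _rng(seed, "reactions").random((n, len(pts))) < probs

    # every spontaneous report carries at least one reaction: fill empties
    # from the non-neurological background pool, weighted by baseline rate
    empty = ~react_mask.any(axis=1)
    if empty.any():
        bg = np.flatnonzero(~is_neuro)
        bw = base[bg] / base[bg].sum()
        fill = _rng(seed, "fill").choice(bg, size=int(empty.sum()), p=bw)
        react_mask[np.flatnonzero(empty), fill] = True

    # dates: event uniform within quarter; therapy start = event - onset
    q_starts = [quarter_start(q) for q in config.quarters]
    q_lens = np.array([quarter_length(q) for q in config.quarters])
    day_off = (_rng(seed, "event_dt").random(n) * q_lens[q_idx]).astype(int)
    mus = np.array([math.log(d.onset_median_days) for d in drugs])
    sigmas = np.array([d.onset_sigma for d in drugs])
    # lognormal(0,1)**sigma * e^mu == lognormal(mu, sigma) with per-drug params
    onset = np.round(
        _rng(seed, "onset").lognormal(0.0, 1.0, size=n) ** sigmas[drug_idx]
        * np.exp(mus[drug_idx])
    ).astype(int)
    fda_lag = _rng(seed, "fda_dt").integers(7, 120, size=n)

    serious_p = np.array([d.serious_prob for d in drugs])[drug_idx]
    rng_ser = np.random.default_rng([seed, _STREAMS["serious"]])
    serious = rng_ser.random(n) < serious_p
    serious_code = rng_ser.choice(["HO", "DE", "LT"], size=n, p=[0.60, 0.25, 0.15])

    miss = config.missingness
    rng_miss = _rng(seed, "missing")
    miss_mask = {
        k: rng_miss.random(n) < miss.get(k, 0.0)
        for k in ("age", "sex", "weight", "therapy_start", "event_dt",
                  "reporter", "country", "outcome")
    }

    rng_names = _rng(seed, "names")
    use_brand = rng_names.random(n) < 0.5
    brand_pick = rng_names.random(n)

    reports: list[CaseReport] = []
    react_lists = [[pt_names[j] for j in np.flatnonzero(react_mask[i])] for i in range(n)]
    for i in range(n):
        d = drugs[drug_idx[i]]
        event = q_starts[q_idx[i]] + timedelta(days=int(day_off[i]))
        therapy = event - timedelta(days=int(onset[i]))
        fda = event + timedelta(days=int(fda_lag[i]))
        if d.brands and use_brand[i]:
            raw = d.brands[int(brand_pick[i] * len(d.brands))]
        else:
            raw = d.ingredient.upper()
        drug_records = [
            DrugRecord(
                drug_seq=1,
                role="PS",
                raw_name=raw,
                ingredient=d.ingredient,
                therapy_start=None if miss_mask["therapy_start"][i] else therapy,
            )
        ]
        seq = 2
        for ci, cls in enumerate(classes):
            if con_mask[i, ci]:
                drug_records.append(
                    DrugRecord(drug_seq=seq, role="C", raw_name=cls.upper(), ingredient=cls)
                )
                seq += 1
        if miss_mask["outcome"][i]:
            outcomes = frozenset()
        elif serious[i]:
            outcomes = frozenset({str(serious_code[i])})
        else:
            outcomes = frozenset({"OT"})
        indication = indics[indi_idx[i]]
        reports.append(
            CaseReport(
                primaryid=str(10_000_000 + i),
                caseid=str(20_000_000 + i),
                fda_dt=fda,
                event_dt=None if miss_mask["event_dt"][i] else event,
                age_years=None if miss_mask["age"][i] else float(round(age[i], 1)),
                sex="U" if miss_mask["sex"][i] else ("F" if female[i] else "M"),
                weight_kg=None if miss_mask["weight"][i] else float(round(weight[i], 1)),
                reporter="unknown" if miss_mask["reporter"][i]
                else ("professional" if professional[i] else "nonprofessional"),
                country=None if miss_mask["country"][i] else countries[country_idx[i]],
                outcomes=outcomes,
                indications=(indication,) if indication != "OTHER" else (),
                drugs=drug_records,
                reactions=tuple(react_lists[i]),
            )
        )

    if config.duplicate_rate > 0:
        reports = inject_duplicates(reports, config.duplicate_rate, seed)

    return reports, _ground_truth(config, hierarchy)


def inject_duplicates(reports: list, rate: float, seed: int) -> list:
    """Re-emit a random subset of reports as near-copy duplicate submissions.

    Each duplicate shares its source's case identifier and all matching
    fields, gets a strictly higher primaryid and an equal-or-later tracking
    date.  Originals keep their order; duplicates are appended.
    """
    if not 0 <= rate < 1:
        raise ValueError(f"duplicate rate must be in [0, 1), got {rate}")
    if rate == 0 or not reports:
        return list(reports)
    rng = _rng(seed, "duplicates")
    pick = rng.random(len(reports)) < rate
    max_pid = max(int(r.primaryid) for r in reports if r.primaryid.isdigit())
    out = list(reports)
    k = 0
    for i in np.flatnonzero(pick):
        src = reports[i]
        dup = src.copy()
        dup.primaryid = str(max_pid + 1 + k)
        dup.fda_dt = src.fda_dt + timedelta(days=int(rng.integers(0, 30)))
        out.append(dup)
        k += 1
    return out


def simulate_logistic_cohort(
    n: int,
    beta_exposure: float,
    seed: int,
    outcome_intercept: float = -2.2,
) -> pd.DataFrame:
    """Cohort-shaped table from a known logistic model, for recovery tests.

    Confounders (reporter type, region, polypharmacy, age, sex, weight)
    influence both exposure and outcome; the exposure coefficient is
    ``beta_exposure`` on the log-odds scale, so the generative adjusted OR
    is exp(beta_exposure).
    """
    rng = np.random.default_rng(seed)
    prof = rng.random(n) < 0.6
    us = rng.random(n) < 0.33
    poly = rng.random(n) < 0.5
    age = np.clip(rng.normal(67, 10, size=n), 20, 95)
    male = rng.random(n) < 0.55
    weight = np.clip(rng.normal(72, 15, size=n), 35, 160)

    lin_exp = (
        -0.4 + 0.3 * prof + 0.2 * us + 0.3 * poly + 0.01 * (age - 67) + 0.2 * male
    )
    exposed = rng.random(n) < expit(lin_exp)
    lin_out = (
        outcome_intercept
        + beta_exposure * exposed
        + 0.3 * prof
        - 0.2 * us
        + 0.25 * poly
        + 0.01 * (age - 67)
        - 0.15 * male
        + 0.005 * (weight - 72)
    )
    outcome = rng.random(n) < expit(lin_out)
    return pd.DataFrame(
        {
            "exposed": exposed,
            "nae_case": outcome,
            "reporter": np.where(prof, "professional", "nonprofessional"),
            "us": us,
            "polypharmacy": poly,
            "age_years": age,
            "sex": np.where(male, "M", "F"),
            "weight_kg": weight,
        }
    )
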