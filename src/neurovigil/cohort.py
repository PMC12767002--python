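"""Cohort construction: deduplication, exposure/case flagging, analysis table.

Deduplication follows the two-pass FDA convention for spontaneous reports:
first keep the latest FDA-tracked version of each case (ties broken by the
higher report number), then collapse residual duplicates that agree on a
tuple of matching fields (age, sex, country, event date, reactions, drugs,
indications).  Missing fields never match anything, so sparse unrelated
reports are not collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io import CaseReport, SERIOUS_OUTCOMES
from .timing import time_to_onset

__all__ = [
    "MeddraHierarchy",
    "DedupAudit",
    "deduplicate",
    "flag_exposure",
    "flag_nae",
    "CohortClassifiers",
    "build_cohort",
    "NEURO_SOC",
    "AGE_BINS",
    "WEIGHT_BINS",
]

NEURO_SOC = "Nervous system disorders"

# Table-style covariate bins: age {<45, 45-65, >=65}, weight {<50, 50-100, >=100}
AGE_BINS = ("<45", "45-65", ">=65")
WEIGHT_BINS = ("<50", "50-100", ">=100")


@dataclass
class MeddraHierarchy:
    """PT -> (HLT, HLGT, SOC) links with a single primary SOC per PT.

    Multiaxial links are allowed: a PT may map to several SOCs, but exactly
    one link per PT is flagged primary.  This is a synthetic stand-in for
    the licensed dictionary: the structure (five levels, primary-SOC flag)
    is faithful, the content is invented.
    """

    #: rows of (pt, hlt, hlgt, soc, is_primary)
    links: list

    def __post_init__(self) -> None:
        primary = {}
        for pt, _hlt, _hlgt, soc, is_primary in self.links:
            if is_primary:
                if pt in primary and primary[pt] != soc:
                    raise ValueError(f"PT {pt!r} has more than one primary SOC")
                primary[pt] = soc
        self._primary_soc = primary

    def primary_soc(self, pt: str) -> Optional[str]:
        """Primary SOC for a PT, or None if the PT is not covered."""
        return self._primary_soc.get(pt)

    def covers(self, pt: str) -> bool:
        return pt in self._primary_soc

    @property
    def pts(self) -> set:
        return set(self._primary_soc)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.links, columns=["pt", "hlt", "hlgt", "soc", "primary"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MeddraHierarchy":
        rows = [
            (r.pt, r.hlt, r.hlgt, r.soc, bool(int(r.primary)))
            for r in df.itertuples(index=False)
        ]
        return cls(rows)

    def to_table(self, path, sep: str = "\t") -> None:
        df = self.to_frame()
        df["primary"] = df["primary"].astype(int)
        df.to_csv(path, sep=sep, index=False)

    @classmethod
    def from_table(cls, path, sep: str = "\t") -> "MeddraHierarchy":
        return cls.from_frame(pd.read_csv(path, sep=sep, dtype={"primary": int}))


@dataclass
class DedupAudit:
    n_input: int = 0
    removed_pass1: int = 0
    removed_pass2: int = 0

    @property
    def n_output(self) -> int:
        return self.n_input - self.removed_pass1 - self.removed_pass2


def _pid_key(primaryid: str):
    # numeric report numbers compare numerically, others lexically
    try:
        return (0, int(primaryid))
    except ValueError:
        return (1, primaryid)


def _recency(rep: CaseReport):
    return (rep.fda_dt, _pid_key(rep.primaryid))


def _match_tuple(rep: CaseReport):
    """Pass-2 matching key; None when any matching field is missing."""
    if rep.age_years is None or rep.sex == "U" or rep.country is None or rep.event_dt is None:
        return None
    if not rep.reactions or not rep.drugs:
        return None
    drugs = tuple(sorted((d.ingredient or d.raw_name.casefold()) for d in rep.drugs))
    return (
        round(rep.age_years, 6),
        rep.sex,
        rep.country,
        rep.event_dt,
        tuple(sorted(rep.reactions)),
        drugs,
        tuple(sorted(rep.indications)),
    )


def deduplicate(reports: Sequence[CaseReport]) -> tuple[list, DedupAudit]:
    """Two-pass deduplication; returns survivors and per-pass removal counts.

    Pass 1: per case identifier keep the report with the latest fda_dt,
    ties resolved toward the higher report number.  Pass 2: among survivors,
    reports agreeing on the full matching tuple collapse to the most recent
    one (same tie rule).  Idempotent.
    """
    audit = DedupAudit(n_input=len(reports))

    best: dict[str, CaseReport] = {}
    for rep in reports:
        cur = best.get(rep.caseid)
        if cur is None or _recency(rep) > _recency(cur):
            best[rep.caseid] = rep
    survivors = list(best.values())
    audit.removed_pass1 = len(reports) - len(survivors)

    groups: dict[tuple, CaseReport] = {}
    unmatched = []
    for rep in survivors:
        key = _match_tuple(rep)
        if key is None:
            unmatched.append(rep)
            continue
        cur = groups.get(key)
        if cur is None or _recency(rep) > _recency(cur):
            groups[key] = rep
    out = unmatched + list(groups.values())
    audit.removed_pass2 = len(survivors) - len(out)

    out.sort(key=lambda r: _pid_key(r.primaryid))
    return out, audit


def flag_exposure(report: CaseReport, target_ingredients: Iterable[str]) -> frozenset:
    """Ingredients among ``target_ingredients`` held as primary suspect (PS).

    Only the PS role confers exposure; SS/C/I never do.
    """
    targets = set(target_ingredients)
    return frozenset(
        d.ingredient for d in report.drugs if d.role == "PS" and d.ingredient in targets
    )


def flag_nae(report: CaseReport, hierarchy: MeddraHierarchy) -> tuple[bool, tuple, int]:
    """Neurological-case flag via the primary-SOC rule.

    A report is a case iff at least one reaction PT has the neurological SOC
    as its *primary* SOC; secondary multiaxial links do not qualify.
    Returns ``(is_case, matched PTs, uncovered PT count)``.
    """
    matched = []
    uncovered = 0
    for pt in report.reactions:
        soc = hierarchy.primary_soc(pt)
        if soc is None:
            uncovered += 1
        elif soc == NEURO_SOC:
            matched.append(pt)
    return bool(matched), tuple(matched), uncovered


def age_group(age_years: Optional[float]) -> Optional[str]:
    if age_years is None:
        return None
    if age_years < 45:
        return "<45"
    if age_years < 65:
        return "45-65"
    return ">=65"


def weight_group(weight_kg: Optional[float]) -> Optional[str]:
    # half-open [50, 100) avoids double counting at the 100 kg boundary
    if weight_kg is None:
        return None
    if weight_kg < 50:
        return "<50"
    if weight_kg < 100:
        return "50-100"
    return ">=100"


def outcome_class(outcomes: frozenset) -> Optional[str]:
    """serious / nonserious / None(missing) per the death, life-threatening,
    hospitalization rule."""
    if not outcomes:
        return None
    return "serious" if outcomes & SERIOUS_OUTCOMES else "nonserious"


@dataclass
class CohortClassifiers:
    """Optional lookup tables grouping drugs and indications.

    ``drug_class_map`` maps a concomitant ingredient to a therapeutic class
    (e.g. platinum-based compounds); ``indication_map`` maps an indication
    PT to a cancer-type group.
    """

    drug_class_map: Mapping[str, str] = field(default_factory=dict)
    indication_map: Mapping[str, str] = field(default_factory=dict)


def build_cohort(
    reports: Sequence[CaseReport],
    hierarchy: MeddraHierarchy,
    target_ingredients: Sequence[str],
    classifiers: Optional[CohortClassifiers] = None,
) -> pd.DataFrame:
    """Assemble the one-row-per-report analysis table.

    Columns include exposure (any-target and the set of PS target
    ingredients), the neurological-case flag with matched PTs, binned
    covariates, serious/nonserious/missing outcome class and onset days.
    """
    classifiers = classifiers or CohortClassifiers()
    drug_classes = sorted(set(classifiers.drug_class_map.values()))
    rows = []
    for rep in reports:
        exposed = flag_exposure(rep, target_ingredients)
        is_case, matched, uncovered = flag_nae(rep, hierarchy)
        onset, onset_reason = time_to_onset(rep)
        ingredients = {d.ingredient or d.raw_name.casefold() for d in rep.drugs}
        con_classes = {
            classifiers.drug_class_map[i] for i in ingredients if i in classifiers.drug_class_map
        }
        indication_groups = {
            classifiers.indication_map[pt]
            for pt in rep.indications
            if pt in classifiers.indication_map
        }
        row = {
            "primaryid": rep.primaryid,
            "caseid": rep.caseid,
            "exposed": bool(exposed),
            "ps_ingredients": exposed,
            "nae_case": is_case,
            "nae_pts": matched,
            "reactions": tuple(rep.reactions),
            "uncovered_pts": uncovered,
            "age_years": rep.age_years,
            "age_group": age_group(rep.age_years),
            "sex": rep.sex,
            "weight_kg": rep.weight_kg,
            "weight_group": weight_group(rep.weight_kg),
            "reporter": rep.reporter,
            "country": rep.country,
            "us": None if rep.country is None else rep.country == "US",
            "indications": tuple(rep.indications),
            "indication_groups": frozenset(indication_groups),
            "con_classes": frozenset(con_classes),
            "n_ingredients": len(ingredients),
            "polypharmacy": len(ingredients) > 1,
            "outcome_class": outcome_class(rep.outcomes),
            "onset_days": onset,
            "onset_missing_reason": onset_reason,
            "event_dt": rep.event_dt,
            "fda_dt": rep.fda_dt,
        }
        for cls in drug_classes:
            row[f"con_{cls}"] = cls in con_classes
        rows.append(row)
    return pd.DataFrame(rows)
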