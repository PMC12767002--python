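"""Reading and writing FAERS-dialect quarterly bundles.

A quarterly bundle is a directory with seven "$"-delimited ASCII tables
(DEMO, DRUG, REAC, OUTC, RPSR, THER, INDI) keyed by PRIMARYID / CASEID /
drug_seq, mirroring the public FAERS quarterly extract layout.  Reports are
materialised as :class:`CaseReport` objects; child rows that reference a
PRIMARYID absent from DEMO are counted as orphans, never fabricated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "DrugRecord",
    "CaseReport",
    "BundleReadResult",
    "read_bundle",
    "write_bundle",
    "normalize_drug_name",
    "normalize_reports",
    "UNMAPPED",
    "BUNDLE_TABLES",
    "parse_faers_date",
    "age_to_years",
]

#: sentinel returned for drug names that cannot be mapped to an ingredient
UNMAPPED = None

BUNDLE_TABLES = ("DEMO", "DRUG", "REAC", "OUTC", "RPSR", "THER", "INDI")

# FAERS outcome codes; "near death" is the life-threatening code LT
OUTCOME_CODES = {"DE", "LT", "HO", "DS", "CA", "RI", "OT"}
SERIOUS_OUTCOMES = frozenset({"DE", "LT", "HO"})

PROFESSIONAL_OCCP = {"MD", "PH", "OT", "HP", "RN"}
NONPROFESSIONAL_OCCP = {"CN", "LW"}

_AGE_FACTORS = {"DEC": 10.0, "YR": 1.0, "MON": 1.0 / 12.0, "DY": 1.0 / 365.25}


@dataclass
class DrugRecord:
    """One DRUG-table row: a drug as reported on a single case."""

    drug_seq: int
    role: str  # PS | SS | C | I
    raw_name: str
    ingredient: Optional[str] = None
    therapy_start: Optional[date] = None
    therapy_start_imprecise: bool = False

    def __post_init__(self) -> None:
        if self.role not in {"PS", "SS", "C", "I"}:
            raise ValueError(f"invalid drug role code: {self.role!r}")


@dataclass
class CaseReport:
    """One spontaneous report (one DEMO row with joined children)."""

    primaryid: str
    caseid: str
    fda_dt: date
    event_dt: Optional[date] = None
    event_dt_imprecise: bool = False
    age_years: Optional[float] = None
    sex: str = "U"  # M | F | U
    weight_kg: Optional[float] = None
    reporter: str = "unknown"  # professional | nonprofessional | unknown
    country: Optional[str] = None
    outcomes: frozenset = frozenset()
    indications: tuple = ()
    drugs: list = field(default_factory=list)
    reactions: tuple = ()

    def copy(self) -> "CaseReport":
        return replace(self, drugs=[replace(d) for d in self.drugs])


@dataclass
class BundleReadResult:
    """Reports plus data-quality counters from a bundle read."""

    reports: list
    orphan_rows: int = 0
    bad_dates: int = 0
    bad_ages: int = 0

    def __iter__(self) -> Iterator[CaseReport]:
        return iter(self.reports)

    def __len__(self) -> int:
        return len(self.reports)


def parse_faers_date(raw) -> tuple[Optional[date], bool]:
    """Parse YYYYMMDD / YYYYMM / YYYY; partial dates map to the period start.

    Returns ``(date or None, imprecise_flag)``.  Unparseable values return
    ``(None, False)`` and are counted by the caller.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None, False
    s = str(raw).strip()
    if not s or s.lower() == "nan":
        return None, False
    s = s.split(".")[0]  # tolerate float-formatted ints
    try:
        if len(s) == 8:
            return date(int(s[:4]), int(s[4:6]), int(s[6:8])), False
        if len(s) == 6:
            return date(int(s[:4]), int(s[4:6]), 1), True
        if len(s) == 4:
            return date(int(s), 1, 1), True
    except ValueError:
        return None, False
    return None, False


def format_faers_date(d: Optional[date]) -> str:
    return "" if d is None else f"{d.year:04d}{d.month:02d}{d.day:02d}"


def age_to_years(value, unit) -> Optional[float]:
    """Convert an (age value, FAERS unit code) pair to years.

    DEC x10, YR x1, MON /12, DY /365.25.  Unknown units or unparseable
    values yield ``None``.
    """
    if value is None or unit is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    factor = _AGE_FACTORS.get(str(unit).strip().upper())
    if factor is None:
        return None
    return v * factor


_PUNCT_RE = re.compile(r"[^\w\s]", re.UNICODE)
_WS_RE = re.compile(r"\s+")


def _canon_name(name: str) -> str:
    s = _PUNCT_RE.sub(" ", name.casefold())
    return _WS_RE.sub(" ", s).strip()


def normalize_drug_name(raw_name: Optional[str], dictionary: Mapping[str, str]):
    """Map a verbatim drug name to an ingredient, or :data:`UNMAPPED`.

    Matching is case- and punctuation-insensitive.  Names absent from the
    dictionary are returned as :data:`UNMAPPED` (``None``), never guessed.
    The dictionary keys are canonicalised once per call site via
    :func:`build_name_index`; plain dicts of raw brand/generic names also
    work.
    """
    if not raw_name:
        return UNMAPPED
    canon = _canon_name(raw_name)
    if not canon:
        return UNMAPPED
    if canon in dictionary:
        return dictionary[canon]
    # fall back to canonicalising dictionary keys lazily
    for k, v in dictionary.items():
        if _canon_name(k) == canon:
            return v
    return UNMAPPED


def build_name_index(dictionary: Mapping[str, str]) -> dict:
    """Pre-canonicalise a brand/generic -> ingredient dictionary."""
    return {_canon_name(k): v for k, v in dictionary.items()}


def normalize_reports(reports: Iterable[CaseReport], dictionary: Mapping[str, str]) -> int:
    """Normalise drug names in place; returns the count of unmapped records."""
    index = build_name_index(dictionary)
    unmapped = 0
    for rep in reports:
        for d in rep.drugs:
            d.ingredient = normalize_drug_name(d.raw_name, index)
            if d.ingredient is UNMAPPED:
                unmapped += 1
    return unmapped


def _table_path(path: Path, name: str) -> Path:
    return path / f"{name}.txt"


def write_bundle(reports: Sequence[CaseReport], path, sep: str = "$") -> None:
    """Write reports as the seven delimited tables, ordered by primaryid."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    reports = sorted(reports, key=lambda r: (len(r.primaryid), r.primaryid))

    demo, drug, reac, outc, rpsr, ther, indi = [], [], [], [], [], [], []
    for r in reports:
        demo.append(
            {
                "primaryid": r.primaryid,
                "caseid": r.caseid,
                "fda_dt": format_faers_date(r.fda_dt),
                "event_dt": format_faers_date(r.event_dt),
                "event_dt_imprecise": int(r.event_dt_imprecise),
                "age": "" if r.age_years is None else repr(float(r.age_years)),
                "age_cod": "" if r.age_years is None else "YR",
                "sex": "" if r.sex == "U" else r.sex,
                "wt": "" if r.weight_kg is None else repr(float(r.weight_kg)),
                "wt_cod": "" if r.weight_kg is None else "KG",
                "occp_cod": {"professional": "MD", "nonprofessional": "CN"}.get(r.reporter, ""),
                "reporter_country": r.country or "",
            }
        )
        for d in r.drugs:
            drug.append(
                {
                    "primaryid": r.primaryid,
                    "caseid": r.caseid,
                    "drug_seq": d.drug_seq,
                    "role_cod": d.role,
                    "drugname": d.raw_name,
                    "prod_ai": d.ingredient or "",
                }
            )
            if d.therapy_start is not None:
                ther.append(
                    {
                        "primaryid": r.primaryid,
                        "caseid": r.caseid,
                        "dsg_drug_seq": d.drug_seq,
                        "start_dt": format_faers_date(d.therapy_start),
                    }
                )
        for pt in r.reactions:
            reac.append({"primaryid": r.primaryid, "caseid": r.caseid, "pt": pt})
        for code in sorted(r.outcomes):
            outc.append({"primaryid": r.primaryid, "caseid": r.caseid, "outc_cod": code})
        rpsr.append({"primaryid": r.primaryid, "caseid": r.caseid, "rpsr_cod": "FGN"})
        for i, pt in enumerate(r.indications, start=1):
            indi.append(
                {"primaryid": r.primaryid, "caseid": r.caseid, "indi_drug_seq": i, "indi_pt": pt}
            )

    columns = {
        "DEMO": [
            "primaryid", "caseid", "fda_dt", "event_dt", "event_dt_imprecise",
            "age", "age_cod", "sex", "wt", "wt_cod", "occp_cod", "reporter_country",
        ],
        "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"],
        "REAC": ["primaryid", "caseid", "pt"],
        "OUTC": ["primaryid", "caseid", "outc_cod"],
        "RPSR": ["primaryid", "caseid", "rpsr_cod"],
        "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt"],
        "INDI": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
    }
    rows = {"DEMO": demo, "DRUG": drug, "REAC": reac, "OUTC": outc,
            "RPSR": rpsr, "THER": ther, "INDI": indi}
    for name in BUNDLE_TABLES:
        df = pd.DataFrame(rows[name], columns=columns[name])
        df.to_csv(_table_path(path, name), sep=sep, index=False, encoding="utf-8")


def _read_table(path: Path, name: str, sep: str) -> pd.DataFrame:
    p = _table_path(path, name)
    if not p.exists():
        raise FileNotFoundError(f"bundle is missing mandatory table {name} ({p})")
    return pd.read_csv(p, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")


def read_bundle(path, sep: str = "$") -> BundleReadResult:
    """Read a quarterly bundle directory into :class:`CaseReport` objects.

    One report per DEMO row; DRUG/REAC/OUTC/THER/INDI rows referencing a
    primaryid absent from DEMO are counted in ``orphan_rows``.  Unparseable
    dates leave the field missing and increment ``bad_dates``.
    """
    path = Path(path)
    tables = {name: _read_table(path, name, sep) for name in BUNDLE_TABLES}
    result = BundleReadResult(reports=[])

    reports: dict[str, CaseReport] = {}
    for row in tables["DEMO"].itertuples(index=False):
        fda_dt, _ = parse_faers_date(row.fda_dt)
        if fda_dt is None:
            result.bad_dates += 1
            fda_dt = date(1900, 1, 1)
        event_dt, imprecise = parse_faers_date(row.event_dt)
        if row.event_dt and event_dt is None:
            result.bad_dates += 1
        if getattr(row, "event_dt_imprecise", "") in {"1", "True"}:
            imprecise = True
        age = age_to_years(row.age or None, row.age_cod or None)
        if row.age and age is None:
            result.bad_ages += 1
        occp = (row.occp_cod or "").upper()
        if occp in PROFESSIONAL_OCCP:
            reporter = "professional"
        elif occp in NONPROFESSIONAL_OCCP:
            reporter = "nonprofessional"
        else:
            reporter = "unknown"
        try:
            weight = float(row.wt) if row.wt else None
        except ValueError:
            weight = None
        rep = CaseReport(
            primaryid=row.primaryid,
            caseid=row.caseid,
            fda_dt=fda_dt,
            event_dt=event_dt,
            event_dt_imprecise=imprecise,
            age_years=age,
            sex=row.sex if row.sex in {"M", "F"} else "U",
            weight_kg=weight,
            reporter=reporter,
            country=row.reporter_country or None,
        )
        reports[rep.primaryid] = rep

    for row in tables["DRUG"].itertuples(index=False):
        rep = reports.get(row.primaryid)
        if rep is None:
            result.orphan_rows += 1
            continue
        rep.drugs.append(
            DrugRecord(
                drug_seq=int(row.drug_seq),
                role=row.role_cod,
                raw_name=row.drugname,
                ingredient=row.prod_ai or None,
            )
        )
    for row in tables["THER"].itertuples(index=False):
        rep = reports.get(row.primaryid)
        if rep is None:
            result.orphan_rows += 1
            continue
        start, imprecise = parse_faers_date(row.start_dt)
        if row.start_dt and start is None:
            result.bad_dates += 1
        seq = int(row.dsg_drug_seq)
        for d in rep.drugs:
            if d.drug_seq == seq:
                d.therapy_start = start
                d.therapy_start_imprecise = imprecise
    for row in tables["REAC"].itertuples(index=False):
        rep = reports.get(row.primaryid)
        if rep is None:
            result.orphan_rows += 1
            continue
        rep.reactions = rep.reactions + (row.pt,)
    for row in tables["OUTC"].itertuples(index=False):
        rep = reports.get(row.primaryid)
        if rep is None:
            result.orphan_rows += 1
            continue
        rep.outcomes = rep.outcomes | {row.outc_cod}
    for row in tables["INDI"].itertuples(index=False):
        rep = reports.get(row.primaryid)
        if rep is None:
            result.orphan_rows += 1
            continue
        rep.indications = rep.indications + (row.indi_pt,)

    result.reports = sorted(reports.values(), key=lambda r: (len(r.primaryid), r.primaryid))
    return result
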