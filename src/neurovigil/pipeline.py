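"""End-to-end analysis pipeline and descriptive summaries.

``run_full_analysis`` executes ingest -> dedup -> cohort -> descriptive ->
signals -> adjusted models / E-values -> onset & severity -> quarterly
trend, writing every table as a delimited file plus a JSON manifest that
records the seed, policies and a row-count audit for each stage.  Reruns
with an identical config reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as fio
from .cohort import (
    CohortClassifiers,
    MeddraHierarchy,
    build_cohort,
    deduplicate,
)
from .confounding import LogisticRiskModel
from .signals import SignalScreen
from .simulate import SimConfig, default_drug_dictionary, generate_reports
from .timing import TrendRegressor, compare_groups, serious_outcome_test, summarize_onset

__all__ = ["RunConfig", "run_full_analysis", "descriptive_summary", "proportion"]


def proportion(count: int, denominator: int, decimals: int = 1) -> float:
    """Percentage 100*count/denominator rounded half-up to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(count) * 100 / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``bundle_path`` (a FAERS-dialect directory on disk) or
    ``sim_config`` (a synthetic-generator config) must be set.
    """

    target_ingredients: Sequence[str]
    bundle_path: Optional[str] = None
    sim_config: Optional[SimConfig] = None
    hierarchy: Optional[MeddraHierarchy] = None
    drug_dictionary: Optional[dict] = None
    classifiers: Optional[CohortClassifiers] = None
    signal_policy: str = "strict"
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.bundle_path is None) == (self.sim_config is None):
            raise ValueError("exactly one of bundle_path or sim_config must be set")


def descriptive_summary(cohort: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Per-stratum counts and percentages with explicit missing rows.

    Within each stratification the counts (including missing) sum to the
    cohort size, and percentages are taken against that full denominator.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    denom = len(cohort)
    rows = []

    def add(variable: str, series: pd.Series, order: Optional[list] = None) -> None:
        counts = series.value_counts(dropna=False)
        levels = order if order is not None else sorted(
            (k for k in counts.index if not pd.isna(k)), key=str
        )
        for level in levels:
            c = int(counts.get(level, 0))
            rows.append(
                {"variable": variable, "level": str(level), "count": c,
                 "percent": proportion(c, denom, decimals)}
            )
        n_missing = int(series.isna().sum())
        rows.append(
            {"variable": variable, "level": "missing", "count": n_missing,
             "percent": proportion(n_missing, denom, decimals)}
        )

    add("sex", cohort["sex"].map({"M": "male", "F": "female"}))
    add("age_group", cohort["age_group"], order=["<45", "45-65", ">=65"])
    add("weight_group", cohort["weight_group"], order=["<50", "50-100", ">=100"])
    add("outcome", cohort["outcome_class"], order=["serious", "nonserious"])
    add("reporter", cohort["reporter"].map(
        {"professional": "professional", "nonprofessional": "nonprofessional"}))
    add("country", cohort["country"])
    df = pd.DataFrame(rows)
    df.attrs["denominator"] = denom
    return df


def _manifest_entry(stage: str, **info) -> dict:
    return {"stage": stage, **info}


def run_full_analysis(config: RunConfig) -> dict:
    """Run the full pipeline; returns a dict of result tables and the manifest.

    When ``config.output_dir`` is set, every table is also written as a
    tab-delimited file and the manifest as JSON.
    """
    manifest: list = []
    results: dict = {}

    if config.sim_config is not None:
        reports, truth = generate_reports(config.sim_config)
        hierarchy = config.hierarchy or config.sim_config.hierarchy()
        dictionary = config.drug_dictionary or default_drug_dictionary()
        results["ground_truth"] = truth
        quarters = list(config.sim_config.quarters)
    else:
        read = fio.read_bundle(config.bundle_path)
        reports = read.reports
        manifest.append(
            _manifest_entry("ingest", rows=len(reports), orphan_rows=read.orphan_rows,
                            bad_dates=read.bad_dates)
        )
        hierarchy = config.hierarchy
        if hierarchy is None:
            raise ValueError("a hierarchy is required when reading a bundle")
        dictionary = config.drug_dictionary or {}
        quarters = None
    manifest.append(_manifest_entry("reports", rows=len(reports), seed=config.seed))

    unmapped = fio.normalize_reports(reports, dictionary)
    manifest.append(_manifest_entry("normalize", unmapped_drug_rows=unmapped))

    deduped, audit = deduplicate(reports)
    manifest.append(
        _manifest_entry(
            "dedup", reports_in=audit.n_input, reports_out=audit.n_output,
            removed_pass1=audit.removed_pass1, removed_pass2=audit.removed_pass2,
        )
    )
    assert audit.n_input == audit.n_output + audit.removed_pass1 + audit.removed_pass2

    cohort = build_cohort(deduped, hierarchy, config.target_ingredients, config.classifiers)
    manifest.append(_manifest_entry("cohort", rows=len(cohort)))

    exposed = cohort[cohort["exposed"]]
    if len(exposed):
        results["descriptive"] = descriptive_summary(
            exposed[exposed["nae_case"]] if exposed["nae_case"].any() else exposed
        )

    drugs = ["any"] + list(config.target_ingredients)
    screen = SignalScreen(drugs=drugs, policy=config.signal_policy).fit(cohort)
    results["signals"] = screen.signals_
    manifest.append(_manifest_entry("signals", pairs=screen.n_pairs_,
                                    policy=config.signal_policy,
                                    multiple_testing_adjustment="none"))

    model_rows = []
    for model_name in ("model1", "model2"):
        for drug in ["any"] + list(config.target_ingredients):
            sub = cohort.copy()
            if drug != "any":
                sub["exposed"] = sub["ps_ingredients"].map(lambda s, d=drug: d in s)
            m = LogisticRiskModel(model=model_name).fit(sub)
            r = m.result_
            model_rows.append(
                {
                    "drug": drug, "model": model_name, "aror": r.aror, "low": r.low,
                    "high": r.high, "p": r.p_value, "n_complete": r.n_complete,
                    "n_dropped": r.n_dropped, "estimable": r.estimable,
                    "reason": r.reason or "",
                    "evalue_point": m.evalue_point_, "evalue_ci": m.evalue_ci_,
                }
            )
    results["models"] = pd.DataFrame(model_rows)
    manifest.append(_manifest_entry("models", fits=len(model_rows),
                                    missing_data_rule="complete-case"))

    nae = cohort[cohort["exposed"] & cohort["nae_case"]]
    onset_known = nae[nae["onset_days"].notna()]
    manifest.append(
        _manifest_entry("onset", records=len(onset_known),
                        excluded_missing=int(len(nae) - len(onset_known)))
    )
    if len(onset_known):
        summaries = summarize_onset(onset_known["onset_days"])
        results["onset_summary"] = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
        drug_labels = onset_known["ps_ingredients"].map(lambda s: sorted(s)[0])
        if drug_labels.nunique() >= 2:
            comps = compare_groups(onset_known["onset_days"], drug_labels, family="onset")
            results["onset_tests"] = pd.DataFrame(
                [{"test": c.test, "statistic": c.statistic, "p": c.p_value} for c in comps]
            )
    if (
        len(nae)
        and nae["outcome_class"].isin(["serious", "nonserious"]).any()
    ):
        nae_out = nae.assign(drug=nae["ps_ingredients"].map(lambda s: sorted(s)[0]))
        if nae_out[nae_out["outcome_class"].notna()]["drug"].nunique() >= 2:
            sev = serious_outcome_test(nae_out, "drug")
            results["serious_test"] = sev

    if quarters is not None and len(nae):
        from datetime import timedelta

        from .simulate import quarter_length, quarter_start

        sub = nae[nae["event_dt"].notna()]
        counts = []
        for q in quarters:
            start = quarter_start(q)
            end = start + timedelta(days=quarter_length(q))
            counts.append(int(((sub["event_dt"] >= start) & (sub["event_dt"] < end)).sum()))
        if len(counts) >= 3:
            trend = TrendRegressor().fit(counts)
            results["trend"] = trend.result_
            manifest.append(
                _manifest_entry("trend", slope=trend.slope_, ci=list(trend.conf_int_),
                                p=trend.p_value_, r2=trend.r_squared_, n_quarters=len(counts))
            )

    results["manifest"] = manifest

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("descriptive", "signals", "models", "onset_summary", "onset_tests"):
            if name in results and isinstance(results[name], pd.DataFrame):
                results[name].to_csv(out / f"{name}.tsv", sep="\t", index=False)
        if "trend" in results:
            (out / "trend.json").write_text(
                json.dumps(dataclasses.asdict(results["trend"]), indent=2, sort_keys=True)
            )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return results
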