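"""Shared fixtures: synthetic bundles at several scales, hierarchy, dictionary."""

from __future__ import annotations

import pytest

from neurovigil import TARGET_INGREDIENTS, build_cohort, deduplicate
from neurovigil.simulate import default_config, default_drug_dictionary, default_hierarchy, generate_reports

# planted associations for the large recovery bundle: one strong pair for the
# compound signal criterion and one moderate pair for odds-ratio consistency
PLANTED = {
    "nivolumab": {"Encephalitis": 5.0},
    "pembrolizumab": {"Seizure": 3.0},
}


@pytest.fixture(scope="session")
def hierarchy():
    return default_hierarchy()


@pytest.fixture(scope="session")
def drug_dictionary():
    return default_drug_dictionary()


@pytest.fixture(scope="session")
def big_sim():
    """200k-report bundle with planted (drug, PT) multipliers, deduplicated cohort."""
    cfg = default_config(total_reports=200_000, seed=0, effect_matrix=PLANTED)
    reports, truth = generate_reports(cfg)
    deduped, audit = deduplicate(reports)
    cohort = build_cohort(deduped, cfg.hierarchy(), TARGET_INGREDIENTS)
    return {"config": cfg, "reports": reports, "truth": truth,
            "audit": audit, "cohort": cohort,
            "planted": {(d, pt) for d, row in PLANTED.items() for pt in row}}


@pytest.fixture(scope="session")
def small_sim():
    """20k-report null bundle (no planted effects) for fast end-to-end checks."""
    cfg = default_config(total_reports=20_000, seed=42, effect_matrix={})
    reports, truth = generate_reports(cfg)
    deduped, _ = deduplicate(reports)
    cohort = build_cohort(deduped, cfg.hierarchy(), TARGET_INGREDIENTS)
    return {"config": cfg, "reports": reports, "truth": truth, "cohort": cohort}
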