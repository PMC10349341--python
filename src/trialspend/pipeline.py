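"""End-to-end pipeline: classify → attribute → analyze → report.

Wires the search/classification, cost-attribution and statistics stages over
the documented CSV interfaces, producing the report tables (per-phase
publication and funding table, paired industry comparison, designation
strata, activity-code categories), a ``summary.json`` of headline quantities
and a run manifest.  Identical config and inputs yield byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import aggregation_stats as stats
from .cost_attribution import AttributionLedger, build_ledger
from .data_model import Corpus, InflationIndex, Phase, read_corpus
from .term_search import classify_corpus


@dataclass
class RunConfig:
    """Reproducible-run parameters.

    ``fiscal_year_offset`` shifts publication years before matching them to
    funding years (0 treats the fiscal year as the calendar year of
    publication); ``lag_window`` is the number of post-project years credited
    to the last funded year.
    """

    input_dir: str
    output_dir: str
    base_year: int = 2018
    fiscal_year_offset: int = 0
    lag_window: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag_window < 0:
            raise ValueError("lag_window must be >= 0")


def make_table1(classified: pd.DataFrame, ledger: AttributionLedger,
                n_drugs_total: int) -> pd.DataFrame:
    """Per-phase publication counts, funded publication counts, project
    years, costs, funded-drug counts and per-funded-drug means."""
    dev = classified[(classified.category == "applied") & classified.is_trial
                     & (classified.phase != Phase.UNASSIGNED.value)]
    pmid_phase = dev.drop_duplicates("pmid").set_index("pmid").phase
    funded_pmids = set(
        ledger.audit[ledger.audit.status.isin(("within_period", "lag_assigned"))].pmid)
    phase_totals = ledger.phase_totals().set_index("phase")
    drug_phase = ledger.drug_phase_totals()
    funded_drugs_total = drug_phase.drug_id.nunique()

    rows = []
    order = [p.value for p in (Phase.P1, Phase.P2, Phase.P3, Phase.P4, Phase.NCT_OTHER)]
    n_pmids_all = len(pmid_phase)
    n_funded_all = sum(1 for p in pmid_phase.index if p in funded_pmids)
    for ph in order:
        pmids = pmid_phase[pmid_phase == ph]
        n_funded = sum(1 for p in pmids.index if p in funded_pmids)
        py = int(phase_totals.project_years.get(ph, 0))
        cost = float(phase_totals.adjusted_cost.get(ph, 0.0))
        nd = int(drug_phase[drug_phase.phase == ph].drug_id.nunique())
        mean = stats.mean_per_funded_drug(cost, nd)
        rows.append({"phase": ph, "pmids": len(pmids),
                     "pmids_pct": round(100 * len(pmids) / n_pmids_all, 1)
                     if n_pmids_all else 0.0,
                     "funded_pmids": n_funded,
                     "funded_pmids_pct": round(100 * n_funded / n_funded_all, 1)
                     if n_funded_all else 0.0,
                     "project_years": py, "adjusted_cost": cost,
                     "funded_drugs": nd,
                     "funded_drugs_pct": round(100 * nd / funded_drugs_total, 1)
                     if funded_drugs_total else 0.0,
                     "mean_cost_per_funded_drug": mean if mean is not None else ""})
    total_cost = float(phase_totals.adjusted_cost.sum())
    total_py = int(phase_totals.project_years.sum())
    mean = stats.mean_per_funded_drug(total_cost, funded_drugs_total)
    rows.append({"phase": "total", "pmids": n_pmids_all, "pmids_pct": 100.0,
                 "funded_pmids": n_funded_all, "funded_pmids_pct": 100.0,
                 "project_years": total_py, "adjusted_cost": total_cost,
                 "funded_drugs": funded_drugs_total,
                 "funded_drugs_pct": 100.0 if funded_drugs_total else 0.0,
                 "mean_cost_per_funded_drug": mean if mean is not None else ""})
    return pd.DataFrame(rows)


def analyze(corpus: Corpus, classified: pd.DataFrame,
            ledger: AttributionLedger) -> dict:
    """All report tables plus the headline summary from one classified,
    attributed corpus."""
    profiles = stats.per_drug_profiles(ledger.drug_phase_totals(),
                                       corpus.industry_costs, corpus.drugs)
    table1 = make_table1(classified, ledger, len(corpus.drugs))
    table2 = stats.industry_comparison(profiles)
    table3 = stats.designation_comparisons(profiles)
    activity = ledger.activity_category_totals()
    if not activity.empty and activity.adjusted_cost.sum() > 0:
        activity = activity.copy()
        activity["cost_share_pct"] = (100 * activity.adjusted_cost
                                      / activity.adjusted_cost.sum()).round(1)
        activity["project_year_share_pct"] = (100 * activity.project_years
                                              / activity.project_years.sum()).round(1)

    cats = ledger.category_totals().set_index("category")
    applied_pubs = classified[classified.category == "applied"].pmid.nunique()
    trial_pubs = classified[(classified.category == "applied")
                            & classified.is_trial].pmid.nunique()
    phased_pubs = classified[(classified.category == "applied") & classified.is_trial
                             & (classified.phase != Phase.UNASSIGNED.value)
                             ].pmid.nunique()
    dev_total = float(cats.adjusted_cost.get("development", 0.0))
    applied_total = float(cats.adjusted_cost.get("applied", 0.0))
    all_total = float(cats.adjusted_cost.get("all", 0.0))

    funded_per_phase = {
        r["phase"]: r["mean_cost_per_funded_drug"]
        for _, r in table1.iterrows() if r["mean_cost_per_funded_drug"] != ""
    }
    summary = {
        "publications": {
            "total": int(len(corpus.publications)),
            "applied": int(applied_pubs),
            "basic": int(classified[classified.category == "basic"].pmid.nunique()),
            "clinical_trial": int(trial_pubs),
            "phased": int(phased_pubs),
            "trial_pct_of_applied": round(100 * trial_pubs / applied_pubs, 1)
            if applied_pubs else None,
            "phased_pct_of_trials": round(100 * phased_pubs / trial_pubs, 1)
            if trial_pubs else None,
        },
        "totals_adjusted_musd": {
            "basic": float(cats.adjusted_cost.get("basic", 0.0)),
            "applied": applied_total,
            "development": dev_total,
            "all": all_total,
            "development_pct_of_applied": round(100 * dev_total / applied_total, 1)
            if applied_total else None,
            "development_pct_of_all": round(100 * dev_total / all_total, 1)
            if all_total else None,
        },
        "per_funded_drug_mean_musd": funded_per_phase,
        "rule_counts": {k: int(v) for k, v in ledger.rule_counts().items()},
    }
    if not table2.empty:
        total_row = table2[table2.phase == "total_P1_P3"].iloc[0]
        summary["industry_comparison"] = {
            "n_paired_drugs": int(total_row.n_drugs),
            "nih_mean_P1_P3": float(total_row.nih_mean),
            "industry_mean_P1_P3": float(total_row.industry_mean),
            "nih_pct_of_industry_P1_P3": float(total_row.nih_pct_of_industry),
            "mean_difference": float(total_row.mean_difference),
            "p_value": float(total_row.p_value),
        }
    return {"profiles": profiles, "table1": table1, "table2": table2,
            "table3": table3, "activity_categories": activity, "summary": summary}


def run_pipeline(config: RunConfig) -> dict:
    """Execute classify → attribute → analyze on ``config.input_dir`` and
    write all outputs (tables, ledger, audit, summary, manifest) to
    ``config.output_dir``.  Returns the in-memory results dict."""
    corpus = read_corpus(config.input_dir, base_year=config.base_year)
    index = InflationIndex.from_frame(corpus.inflation, config.base_year)

    classified = classify_corpus(corpus)
    ledger = build_ledger(classified, corpus, index, lag_window=config.lag_window,
                          fiscal_year_offset=config.fiscal_year_offset)
    results = analyze(corpus, classified, ledger)
    results["classified"] = classified
    results["ledger"] = ledger

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    classified.to_csv(out / "classification.csv", index=False)
    ledger.audit.to_csv(out / "attribution_audit.csv", index=False)
    ledger.development_keys(by_drug=True).rename(
        columns={"entity_id": "drug_id"}).to_csv(out / "ledger.csv", index=False)
    for name in ("table1", "table2", "table3", "activity_categories", "profiles"):
        results[name].to_csv(out / f"{name}.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(results["summary"], fh, indent=2, sort_keys=True)

    cfg = asdict(config)
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "row_counts": {
            "publications": int(len(corpus.publications)),
            "links": int(len(corpus.links)),
            "classified": int(len(classified)),
            "audit": int(len(ledger.audit)),
            "development_project_years": int(
                results["summary"]["rule_counts"].get("within_period", 0)
                + results["summary"]["rule_counts"].get("lag_assigned", 0)),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
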