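"""Project-year cost attribution with lag rules and deduplicated totals.

Each (publication, project) link is assigned at most one fiscal year of
project funding:

* a publication inside the project period is assigned its publication year,
* a publication 1-4 years after the project end is credited to the last
  funded year (publication lag),
* publications before the project start, or more than ``lag_window`` years
  after its end, are excluded.

Totals are computed after eliminating duplicates: within an accounting scope
(overall, per category, per phase, per drug) each (project, fiscal-year) key
contributes its cost exactly once no matter how many publications reach it.
A project-year that serves two drugs is therefore counted once in the
overall total but once per drug in per-drug tables.  Keys whose project has
no cost row for the assigned year are retained with a ``no_cost_row`` status
and contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data_model import Corpus, InflationIndex, Phase

STATUS_WITHIN = "within_period"
STATUS_LAG = "lag_assigned"
STATUS_BEFORE = "excluded_before_start"
STATUS_BEYOND = "excluded_beyond_lag"
STATUS_NO_COST = "no_cost_row"
INCLUDED_STATUSES = (STATUS_WITHIN, STATUS_LAG)


@dataclass(frozen=True)
class Attribution:
    """Outcome of the project-year rule for one (publication, project) pair."""

    pmid: str
    project_id: str
    status: str
    fiscal_year: int | None


def assign_project_year(pub_year: int, start_year: int, end_year: int,
                        pmid: str = "", project_id: str = "",
                        lag_window: int = 4) -> Attribution:
    """Apply the single-project-year rule with a publication-lag window.

    ``fiscal_year`` is defined only for included statuses; a lag-assigned
    publication is always credited to the last project year.
    """
    if pub_year < start_year:
        return Attribution(pmid, project_id, STATUS_BEFORE, None)
    if pub_year <= end_year:
        return Attribution(pmid, project_id, STATUS_WITHIN, pub_year)
    if pub_year <= end_year + lag_window:
        return Attribution(pmid, project_id, STATUS_LAG, end_year)
    return Attribution(pmid, project_id, STATUS_BEYOND, None)


class AttributionLedger:
    """Audit of every attributed link plus scope-deduplicated totals.

    ``audit`` has one row per (pmid, entity, project) with the rule outcome;
    totals are recomputed per requested grouping so that deduplication always
    happens within the reported scope.
    """

    def __init__(self, audit: pd.DataFrame, index: InflationIndex):
        self.audit = audit
        self.index = index

    # -- helpers ---------------------------------------------------------
    def _included(self, category: str | None = None,
                  development_only: bool = False) -> pd.DataFrame:
        rows = self.audit[self.audit.status.isin(INCLUDED_STATUSES)]
        if category is not None:
            rows = rows[rows.category == category]
        if development_only:
            rows = rows[(rows.category == "applied") & rows.is_trial
                        & (rows.phase != Phase.UNASSIGNED.value)]
        return rows

    @staticmethod
    def _dedup_totals(rows: pd.DataFrame) -> tuple[int, float, float]:
        keys = rows.drop_duplicates(["project_id", "fiscal_year"])
        return len(keys), float(keys.nominal_cost.sum()), float(keys.adjusted_cost.sum())

    # -- public API ------------------------------------------------------
    def category_totals(self) -> pd.DataFrame:
        """Project-year counts and costs per research category (deduplicated
        within category scope), plus the development subset and grand total."""
        rows = []
        for cat in ("basic", "applied"):
            n, nom, adj = self._dedup_totals(self._included(category=cat))
            rows.append({"category": cat, "project_years": n,
                         "nominal_cost": nom, "adjusted_cost": adj})
        n, nom, adj = self._dedup_totals(self._included(development_only=True))
        rows.append({"category": "development", "project_years": n,
                     "nominal_cost": nom, "adjusted_cost": adj})
        n, nom, adj = self._dedup_totals(self._included())
        rows.append({"category": "all", "project_years": n,
                     "nominal_cost": nom, "adjusted_cost": adj})
        return pd.DataFrame(rows)

    def development_keys(self, by_drug: bool = False) -> pd.DataFrame:
        """Deduplicated development project-years with their ledger phase.

        One row per (project, fiscal-year) key — or per (drug, project,
        fiscal-year) when ``by_drug`` — carrying the highest phase among
        contributing publications, nominal and adjusted cost, and the number
        of contributing publications.
        """
        rows = self._included(development_only=True)
        group_cols = (["entity_id"] if by_drug else []) + ["project_id", "fiscal_year"]
        out = []
        for key, grp in rows.groupby(group_cols, sort=True):
            phase = Phase.highest(Phase(p) for p in grp.phase)
            rec = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
            rec.update({"phase": phase.value,
                        "activity_code": grp.activity_code.iloc[0],
                        "nominal_cost": float(grp.nominal_cost.iloc[0]),
                        "adjusted_cost": float(grp.adjusted_cost.iloc[0]),
                        "n_pmids": grp.pmid.nunique()})
            out.append(rec)
        cols = group_cols + ["phase", "activity_code", "nominal_cost",
                             "adjusted_cost", "n_pmids"]
        return pd.DataFrame(out, columns=cols)

    def phase_totals(self) -> pd.DataFrame:
        """Development totals partitioned by ledger phase (overall scope)."""
        keys = self.development_keys()
        if keys.empty:
            return pd.DataFrame(columns=["phase", "project_years", "adjusted_cost"])
        out = keys.groupby("phase", sort=True).agg(
            project_years=("phase", "size"),
            adjusted_cost=("adjusted_cost", "sum")).reset_index()
        return out

    def drug_phase_totals(self) -> pd.DataFrame:
        """Per-drug per-phase development totals (deduplicated per drug)."""
        keys = self.development_keys(by_drug=True)
        if keys.empty:
            return pd.DataFrame(columns=["drug_id", "phase", "project_years",
                                         "adjusted_cost"])
        out = keys.groupby(["entity_id", "phase"], sort=True).agg(
            project_years=("phase", "size"),
            adjusted_cost=("adjusted_cost", "sum")).reset_index()
        return out.rename(columns={"entity_id": "drug_id"})

    def activity_category_totals(self) -> pd.DataFrame:
        """Development totals grouped by grant activity-code category."""
        from .aggregation_stats import classify_activity_code

        keys = self.development_keys()
        if keys.empty:
            return pd.DataFrame(columns=["activity_category", "project_years",
                                         "adjusted_cost"])
        keys = keys.copy()
        keys["activity_category"] = keys.activity_code.map(classify_activity_code)
        return keys.groupby("activity_category", sort=True).agg(
            project_years=("activity_category", "size"),
            adjusted_cost=("adjusted_cost", "sum")).reset_index()

    def rule_counts(self) -> pd.Series:
        """Number of (pmid, entity, project) rows per attribution status."""
        return self.audit.status.value_counts().sort_index()


def build_ledger(classified: pd.DataFrame, corpus: Corpus, index: InflationIndex,
                 lag_window: int = 4, fiscal_year_offset: int = 0) -> AttributionLedger:
    """Attribute one fiscal year of funding to every classified, linked pair.

    ``classified`` is the classification table (pmid, entity_id, category,
    is_trial, phase).  ``fiscal_year_offset`` shifts the publication year
    before matching it to a funding year, for callers whose fiscal years are
    offset from calendar years.  Missing cost rows are recorded with status
    ``no_cost_row`` and zero cost; duplicates are eliminated later, at
    totalling time, within each reported scope.
    """
    projects = {r.project_id: (int(r.start_year), int(r.end_year), r.activity_code)
                for r in corpus.projects.itertuples()}
    pub_year = {r.pmid: int(r.year) for r in corpus.publications.itertuples()}
    cost = {(r.project_id, int(r.fiscal_year)): float(r.cost)
            for r in corpus.project_costs.itertuples()}
    links_by_pmid: dict[str, list[str]] = {}
    for r in corpus.links.itertuples():
        links_by_pmid.setdefault(r.pmid, []).append(r.project_id)

    rows = []
    for c in classified.itertuples():
        for project_id in links_by_pmid.get(c.pmid, []):
            start, end, code = projects[project_id]
            att = assign_project_year(pub_year[c.pmid] + fiscal_year_offset, start, end,
                                      c.pmid, project_id, lag_window)
            status, fy = att.status, att.fiscal_year
            nominal = adjusted = 0.0
            if status in INCLUDED_STATUSES:
                if (project_id, fy) in cost:
                    nominal = cost[(project_id, fy)]
                    adjusted = index.adjust(nominal, fy)
                else:
                    status = STATUS_NO_COST
            rows.append({"pmid": c.pmid, "entity_id": c.entity_id,
                         "category": c.category, "is_trial": bool(c.is_trial),
                         "phase": c.phase, "project_id": project_id,
                         "activity_code": code, "status": status,
                         "fiscal_year": fy if status in INCLUDED_STATUSES else pd.NA,
                         "nominal_cost": nominal, "adjusted_cost": adjusted})
    cols = ["pmid", "entity_id", "category", "is_trial", "phase", "project_id",
            "activity_code", "status", "fiscal_year", "nominal_cost", "adjusted_cost"]
    return AttributionLedger(pd.DataFrame(rows, columns=cols), index)
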