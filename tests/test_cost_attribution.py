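"""Project-year assignment rules, deduplication, and ledger totals."""

import pandas as pd
import pytest

from trialspend import (InflationIndex, Phase, assign_project_year, build_ledger,
                        classify_corpus)
from trialspend.cost_attribution import (STATUS_BEFORE, STATUS_BEYOND, STATUS_LAG,
                                         STATUS_NO_COST, STATUS_WITHIN)

from conftest import make_corpus, pub, drug


def oracle_status(pub_year, start, end, lag_window=4):
    """Brute-force restatement of the window rule for the oracle check."""
    if pub_year < start:
        return STATUS_BEFORE, None
    if start <= pub_year <= end:
        return STATUS_WITHIN, pub_year
    if end < pub_year <= end + lag_window:
        return STATUS_LAG, end
    return STATUS_BEYOND, None


class TestAssignProjectYear:
    @pytest.mark.parametrize("pub_year,status,fy", [
        (2009, STATUS_BEFORE, None),   # published before project start: excluded
        (2012, STATUS_WITHIN, 2012),   # inside the funding period: that year
        (2016, STATUS_LAG, 2014),      # 2 years after end: last project year
        (2018, STATUS_LAG, 2014),      # 4 years after end: still credited
        (2019, STATUS_BEYOND, None),   # 5 years after end: excluded
    ])
    def test_stated_rule_cases(self, pub_year, status, fy):
        att = assign_project_year(pub_year, 2010, 2014)
        assert (att.status, att.fiscal_year) == (status, fy)

    def test_every_offset_matches_brute_force_enumeration(self):
        for start, end in [(2010, 2014), (2005, 2005), (2002, 2009)]:
            for lag_window in (0, 1, 4, 7):
                for year in range(start - 3, end + 7):
                    att = assign_project_year(year, start, end, lag_window=lag_window)
                    assert (att.status, att.fiscal_year) == \
                        oracle_status(year, start, end, lag_window)

    def test_zero_lag_window_credits_only_within_period(self):
        att = assign_project_year(2015, 2010, 2014, lag_window=0)
        assert att.status == STATUS_BEYOND


def trial_corpus(extra_pubs=(), extra_links=(), costs=None):
    """Two trial publications of one drug, one project funded 2010-2012."""
    publications = [
        pub("PM1", 2011, title="alpha phase study",
            pub_types="clinical-trial;clinical-trial-phase-2", subject_tags="human"),
        pub("PM2", 2011, title="alpha repeat report",
            pub_types="clinical-trial;clinical-trial-phase-2", subject_tags="human"),
        *extra_pubs,
    ]
    links = [{"pmid": "PM1", "project_id": "PR1"},
             {"pmid": "PM2", "project_id": "PR1"}, *extra_links]
    projects = [{"project_id": "PR1", "activity_code": "U01",
                 "start_year": 2010, "end_year": 2012},
                {"project_id": "PR2", "activity_code": "R01",
                 "start_year": 2010, "end_year": 2012}]
    if costs is None:
        costs = [{"project_id": p, "fiscal_year": y, "cost": 10.0}
                 for p in ("PR1", "PR2") for y in (2010, 2011, 2012)]
    return make_corpus(publications=publications, links=links, projects=projects,
                       project_costs=costs, drugs=[drug("D1", "alpha")])


def ledger_for(corpus, lag_window=4):
    index = InflationIndex.from_frame(corpus.inflation, 2018)
    return build_ledger(classify_corpus(corpus), corpus, index, lag_window=lag_window)


class TestLedgerDeduplication:
    def test_two_pmids_same_project_year_count_once(self):
        led = ledger_for(trial_corpus())
        cats = led.category_totals().set_index("category")
        assert cats.project_years["development"] == 1
        assert cats.adjusted_cost["development"] == pytest.approx(10.0)

    def test_same_pmid_linked_to_two_projects_counts_twice(self):
        led = ledger_for(trial_corpus(
            extra_links=[{"pmid": "PM1", "project_id": "PR2"}]))
        cats = led.category_totals().set_index("category")
        assert cats.project_years["development"] == 2
        assert cats.adjusted_cost["development"] == pytest.approx(20.0)

    def test_duplicate_publication_never_changes_totals(self):
        base = ledger_for(trial_corpus()).category_totals()
        dup = ledger_for(trial_corpus(
            extra_pubs=[pub("PM3", 2011, title="alpha third report",
                            pub_types="clinical-trial;clinical-trial-phase-2",
                            subject_tags="human")],
            extra_links=[{"pmid": "PM3", "project_id": "PR1"}])).category_totals()
        pd.testing.assert_frame_equal(base, dup)

    def test_adding_includable_link_never_decreases_totals(self):
        base = ledger_for(trial_corpus()).category_totals().set_index("category")
        more = ledger_for(trial_corpus(
            extra_links=[{"pmid": "PM2", "project_id": "PR2"}]
        )).category_totals().set_index("category")
        assert (more.adjusted_cost >= base.adjusted_cost - 1e-12).all()

    def test_missing_cost_row_recorded_and_contributes_zero(self):
        costs = [{"project_id": "PR1", "fiscal_year": 2010, "cost": 10.0}]
        led = ledger_for(trial_corpus(costs=costs))
        assert (led.audit.status == STATUS_NO_COST).any()
        cats = led.category_totals().set_index("category")
        assert cats.adjusted_cost["development"] == 0.0

    def test_ledger_phase_is_highest_contributor(self):
        corpus = trial_corpus(extra_pubs=[
            pub("PM4", 2011, title="alpha escalation",
                pub_types="clinical-trial;clinical-trial-phase-3",
                subject_tags="human")],
            extra_links=[{"pmid": "PM4", "project_id": "PR1"}])
        led = ledger_for(corpus)
        keys = led.development_keys()
        assert list(keys.phase) == [Phase.P3.value]


class TestLedgerAgainstRescanOracle:
    def test_totals_match_naive_rescan_on_generated_corpus(self, corpus, truth):
        index = InflationIndex.from_frame(corpus.inflation, 2018)
        classified = classify_corpus(corpus)
        led = build_ledger(classified, corpus, index)

        # independent oracle: plain-dict accumulation from the raw tables
        projects = {r.project_id: (int(r.start_year), int(r.end_year))
                    for r in corpus.projects.itertuples()}
        years = {r.pmid: int(r.year) for r in corpus.publications.itertuples()}
        costs = {(r.project_id, int(r.fiscal_year)): float(r.cost)
                 for r in corpus.project_costs.itertuples()}
        links = corpus.links.groupby("pmid").project_id.apply(list).to_dict()
        dev_pmids = set(
            classified[(classified.category == "applied") & classified.is_trial
                       & (classified.phase != "UNASSIGNED")].pmid)
        seen = {}
        for pmid in dev_pmids:
            for pr in links.get(pmid, []):
                start, end = projects[pr]
                y = years[pmid]
                if y < start or y > end + 4:
                    continue
                fy = y if y <= end else end
                if (pr, fy) in costs:
                    seen[(pr, fy)] = index.adjust(costs[(pr, fy)], fy)
        cats = led.category_totals().set_index("category")
        assert cats.project_years["development"] == len(seen)
        assert cats.adjusted_cost["development"] == pytest.approx(
            sum(seen.values()), rel=1e-12)

    def test_phase_project_years_partition_development_total(self, corpus):
        led = ledger_for(corpus)
        phases = led.phase_totals()
        cats = led.category_totals().set_index("category")
        assert phases.project_years.sum() == cats.project_years["development"]
        assert phases.adjusted_cost.sum() == pytest.approx(
            cats.adjusted_cost["development"], rel=1e-12)

    def test_totals_monotone_in_lag_window(self, corpus):
        totals = [ledger_for(corpus, lag_window=w).category_totals()
                  .set_index("category").adjusted_cost["development"]
                  for w in (0, 2, 4, 8)]
        assert all(a <= b + 1e-9 for a, b in zip(totals, totals[1:]))
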