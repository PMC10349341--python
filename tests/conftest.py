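import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from trialspend import Corpus, GeneratorConfig, InflationIndex, generate, validate_corpus

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_bundle():
    """Default-condition synthetic corpus with ground truth (fixed seed)."""
    return generate(GeneratorConfig(seed=123))


@pytest.fixture(scope="session")
def corpus(default_bundle):
    return default_bundle[0]


@pytest.fixture(scope="session")
def truth(default_bundle):
    return default_bundle[1]


@pytest.fixture()
def flat_index():
    """Inflation index equal to 1 everywhere: adjusted == nominal."""
    return InflationIndex({y: 1.0 for y in range(1999, 2022)}, base_year=2018)


def make_corpus(publications=None, links=None, projects=None, project_costs=None,
                registry=None, drugs=None, targets=None, industry_costs=None,
                inflation=None) -> Corpus:
    """Hand-built corpus with sensible empty defaults for unit tests."""
    def frame(rows, cols):
        return pd.DataFrame(rows if rows is not None else [], columns=cols)

    corpus = Corpus(
        publications=frame(publications, ["pmid", "year", "title", "abstract",
                                          "pub_types", "subject_tags"]),
        links=frame(links, ["pmid", "project_id"]),
        projects=frame(projects, ["project_id", "activity_code",
                                  "start_year", "end_year"]),
        project_costs=frame(project_costs, ["project_id", "fiscal_year", "cost"]),
        registry=frame(registry, ["nct_id", "phase"]),
        drugs=frame(drugs, ["drug_id", "synonyms", "approval_year", "target_ids",
                            "first_in_class", "orphan", "accelerated",
                            "breakthrough", "fast_track", "priority"]),
        targets=frame(targets, ["target_id", "synonyms"]),
        industry_costs=frame(industry_costs, ["drug_id", "phase", "cost"]),
        inflation=frame(inflation if inflation is not None else
                        [{"year": y, "index": 1.0} for y in range(1999, 2022)],
                        ["year", "index"]),
    )
    return validate_corpus(corpus)


def pub(pmid, year=2010, title="", abstract="", pub_types="", subject_tags=""):
    return {"pmid": pmid, "year": year, "title": title, "abstract": abstract,
            "pub_types": pub_types, "subject_tags": subject_tags}


def drug(drug_id, synonyms, approval_year=2015, target_ids="", **flags):
    row = {"drug_id": drug_id, "synonyms": synonyms,
           "approval_year": approval_year, "target_ids": target_ids,
           "first_in_class": 0, "orphan": 0, "accelerated": 0,
           "breakthrough": 0, "fast_track": 0, "priority": 0}
    row.update({k: int(v) for k, v in flags.items()})
    return row
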