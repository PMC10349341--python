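"""Publication search and classification.

Splits a corpus into applied research (publications naming a drug), basic
research (publications naming a biological target but no drug), clinical-trial
reports, and phased development publications, and assigns each trial
publication an ordered phase label.

Trial detection follows the metatag rule — any clinical-trial or phase
publication-type tag, not a review, with the human subject-heading — or the
presence of an extractable trial-registry (NCT) identifier in the text.
Phase assignment pools candidates from phase metatags and registry lookups of
every cited NCT number, then applies the highest-phase rule; registry entries
without a phase designation (or NCT numbers absent from the registry) yield
the ``NCT_OTHER`` label only when no numbered candidate exists.

Synonym matching is case-insensitive whole-token-sequence matching over
title, abstract, and tag cells; the matcher is deliberately simple and
swappable — reproducing any particular search engine's Boolean syntax is out
of scope.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

import pandas as pd

from .data_model import Corpus, Phase, split_tags

NCT_PATTERN = re.compile(r"NCT\d{8}(?!\d)")

#: publication-type tags that mark a clinical-trial report
TRIAL_TAGS = frozenset({
    "clinical-trial",
    "clinical-trial-phase-1",
    "clinical-trial-phase-2",
    "clinical-trial-phase-3",
    "clinical-trial-phase-4",
})
PHASE_FROM_TAG = {
    "clinical-trial-phase-1": Phase.P1,
    "clinical-trial-phase-2": Phase.P2,
    "clinical-trial-phase-3": Phase.P3,
    "clinical-trial-phase-4": Phase.P4,
}
REVIEW_TAG = "review"
HUMAN_TAG = "human"

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _tokens(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


class SynonymMatcher:
    """Case-insensitive whole-token-sequence matcher over a synonym lexicon.

    Built once per entity set; ``hits`` returns the entity ids whose synonym
    token sequences occur contiguously in the publication's title, abstract,
    or tag cells.
    """

    def __init__(self, synonyms_by_entity: Mapping[str, Iterable[str]]):
        self._index: dict[tuple[str, ...], set[str]] = {}
        self._max_len = 1
        for entity, syns in synonyms_by_entity.items():
            for syn in syns:
                toks = tuple(_tokens(syn))
                if not toks:
                    continue
                self._index.setdefault(toks, set()).add(entity)
                self._max_len = max(self._max_len, len(toks))

    def hits(self, *texts: str) -> set[str]:
        found: set[str] = set()
        for text in texts:
            toks = _tokens(text)
            for n in range(1, self._max_len + 1):
                for i in range(len(toks) - n + 1):
                    entities = self._index.get(tuple(toks[i:i + n]))
                    if entities:
                        found |= entities
        return found


def _pub_texts(pub) -> tuple[str, str, str]:
    return pub.title, pub.abstract, (pub.pub_types + " " + pub.subject_tags).replace(";", " ")


def match_drug_publications(corpus: Corpus, drugs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Search hits of drug synonyms: one row per (pmid, drug_id).

    A publication hits a drug iff any of its synonyms occurs as a
    case-insensitive token sequence in title, abstract, or tags.
    """
    drugs = corpus.drugs if drugs is None else drugs
    matcher = SynonymMatcher({r.drug_id: split_tags(r.synonyms) for r in drugs.itertuples()})
    rows = [{"pmid": p.pmid, "entity_id": e}
            for p in corpus.publications.itertuples()
            for e in sorted(matcher.hits(*_pub_texts(p)))]
    return pd.DataFrame(rows, columns=["pmid", "entity_id"])


def match_target_publications(corpus: Corpus, targets: pd.DataFrame | None = None,
                              drug_hits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Search hits of target synonyms, excluding any pmid hit by a drug search.

    The remaining publications constitute the basic-research set; the
    exclusion makes basic and applied sets disjoint by construction.
    """
    targets = corpus.targets if targets is None else targets
    if drug_hits is None:
        drug_hits = match_drug_publications(corpus)
    drug_pmids = set(drug_hits.pmid)
    matcher = SynonymMatcher({r.target_id: split_tags(r.synonyms)
                              for r in targets.itertuples()})
    rows = [{"pmid": p.pmid, "entity_id": e}
            for p in corpus.publications.itertuples() if p.pmid not in drug_pmids
            for e in sorted(matcher.hits(*_pub_texts(p)))]
    return pd.DataFrame(rows, columns=["pmid", "entity_id"])


def extract_nct_ids(text: str) -> list[str]:
    """Every NCT identifier ("NCT" + exactly 8 digits) in first-occurrence order.

    A digit run longer than 8 after "NCT" is not an identifier; duplicates are
    dropped, keeping the first occurrence.
    """
    seen: list[str] = []
    for m in NCT_PATTERN.finditer(text):
        if m.group() not in seen:
            seen.append(m.group())
    return seen


def detect_clinical_trial(pub) -> bool:
    """True iff the publication reports a clinical trial.

    Either the metatag rule holds (a trial/phase publication-type tag, no
    review tag, and the human subject tag) or an NCT identifier is extractable
    from its title or abstract.
    """
    tags = split_tags(pub.pub_types)
    subject = split_tags(pub.subject_tags)
    if tags & TRIAL_TAGS and REVIEW_TAG not in tags and HUMAN_TAG in subject:
        return True
    return bool(NCT_PATTERN.search(pub.title + " " + pub.abstract))


def assign_phase(pub, registry: Mapping[str, Phase | None]) -> Phase:
    """Phase label of a trial publication under the highest-phase rule.

    Candidates come from phase metatags and from registry lookups of every
    extracted NCT identifier; NCT numbers missing from the registry (or
    registered without a phase) contribute no candidate.  With no candidates,
    the label is ``NCT_OTHER`` if an NCT number was cited, else
    ``UNASSIGNED``.  Raises ``ValueError`` when called on a non-trial
    publication.
    """
    if not detect_clinical_trial(pub):
        raise ValueError(f"assign_phase called on non-trial publication {pub.pmid}")
    tags = split_tags(pub.pub_types)
    candidates = [PHASE_FROM_TAG[t] for t in sorted(tags & PHASE_FROM_TAG.keys())]
    ncts = extract_nct_ids(pub.title + " " + pub.abstract)
    for nct in ncts:
        phase = registry.get(nct)
        if phase is not None:
            candidates.append(phase)
    if candidates:
        return max(candidates)
    return Phase.NCT_OTHER if ncts else Phase.UNASSIGNED


def classify_corpus(corpus: Corpus) -> pd.DataFrame:
    """Full classification table: one row per (pmid, matched entity).

    Columns: pmid, entity_id, category ∈ {applied, basic}, is_trial,
    phase ∈ {P1..P4, NCT_OTHER, UNASSIGNED} (UNASSIGNED for non-trials).
    Trial detection and phase labels are computed for applied (drug)
    publications; trial-like target publications remain basic research.
    """
    drug_hits = match_drug_publications(corpus)
    target_hits = match_target_publications(corpus, drug_hits=drug_hits)
    registry = corpus.registry_phases()
    pubs = {p.pmid: p for p in corpus.publications.itertuples()}

    trial_cache: dict[str, tuple[bool, Phase]] = {}

    def trial_info(pmid: str) -> tuple[bool, Phase]:
        if pmid not in trial_cache:
            pub = pubs[pmid]
            is_trial = detect_clinical_trial(pub)
            phase = assign_phase(pub, registry) if is_trial else Phase.UNASSIGNED
            trial_cache[pmid] = (is_trial, phase)
        return trial_cache[pmid]

    rows = []
    for r in drug_hits.itertuples():
        is_trial, phase = trial_info(r.pmid)
        rows.append({"pmid": r.pmid, "entity_id": r.entity_id, "category": "applied",
                     "is_trial": is_trial, "phase": phase.value})
    for r in target_hits.itertuples():
        rows.append({"pmid": r.pmid, "entity_id": r.entity_id, "category": "basic",
                     "is_trial": False, "phase": Phase.UNASSIGNED.value})
    return pd.DataFrame(rows, columns=["pmid", "entity_id", "category",
                                       "is_trial", "phase"])
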