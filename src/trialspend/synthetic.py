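"""Synthetic corpus generator with known ground truth.

Generates the nine-table input bundle (publications, project links, project
periods and yearly costs, trial registry, drug/target lexicon, industry cost
benchmarks, inflation index) together with a :class:`GroundTruth` record of
the true publication category, true clinical phase, and true per-drug
deduplicated funding totals.  Every downstream stage — term search, trial
detection, phase assignment, cost attribution, per-drug statistics — is then
testable by exact recovery.

Default rates mirror the observed composition of drug-related literature:
about 9% of drug publications report clinical trials, about half of those are
phased, roughly one publication in ten carries public-agency funding, and the
phase mix of phased trial reports is dominated by phase 2/3 studies.  Corpus
size (drugs, targets, publications per entity) is scaled down to desk scale;
the generator documents what it does and does not emulate in the methods
note.

Synonym strings are collision-free across drugs and targets by construction,
so search errors in recovery tests come only from injected noise
(:func:`inject_noise`); ``synonym_collisions=True`` produces deliberate
collisions for stress tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import (
    DESIGNATION_FLAGS,
    ConfigError,
    Corpus,
    InflationIndex,
    Phase,
    join_tags,
    split_tags,
    validate_corpus,
)

#: publication-year offset classes relative to the linked project's period
OFFSET_CLASSES = ["before_start", "within", "lag1", "lag2", "lag3", "lag4", "beyond"]

PHASE_TAG = {
    Phase.P1: "clinical-trial-phase-1",
    Phase.P2: "clinical-trial-phase-2",
    Phase.P3: "clinical-trial-phase-3",
    Phase.P4: "clinical-trial-phase-4",
}

# industry per-phase cost scales (mean, sd) in 2018 M$, matching published
# per-drug audited-spending benchmarks for phases 1-3
INDUSTRY_COST_SCALE = {"P1": (54.9, 56.9), "P2": (103.6, 110.1), "P3": (298.3, 272.2)}

_ACTIVITY_CODES_DEV = [
    ("U01", 0.22), ("UL1", 0.08), ("U10", 0.05), ("P30", 0.15), ("P50", 0.08),
    ("M01", 0.04), ("R01", 0.18), ("R21", 0.04), ("K08", 0.05), ("T32", 0.04),
    ("F32", 0.02), ("S10", 0.05),
]
_ACTIVITY_CODES_BASIC = [
    ("R01", 0.55), ("R21", 0.10), ("P01", 0.10), ("U01", 0.05), ("K08", 0.08),
    ("T32", 0.06), ("F32", 0.03), ("S10", 0.03),
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic corpus; the seed fully determines output.

    ``phase_mix`` is the distribution of true phase labels among phased trial
    publications; ``lag_mix`` is the distribution of publication-year offsets
    relative to the funding period of the linked project (publications before
    the project start and more than four years after its end are excluded by
    the attribution rule downstream).
    """

    n_drugs: int = 40
    n_targets: int = 25
    n_projects: int = 260
    corpus_span: tuple[int, int] = (1999, 2021)
    pubs_per_drug: float = 200.0      # Poisson mean, min 1
    pubs_per_target: float = 100.0    # Poisson mean, min 1
    nih_funded_fraction: float = 0.108
    trial_fraction: float = 0.091     # drug publications reporting clinical trials
    phased_fraction: float = 0.497    # trials that are phased (incl. registry-only)
    phase_mix: Mapping[str, float] = field(default_factory=lambda: {
        "P1": 0.152, "P2": 0.271, "P3": 0.347, "P4": 0.036, "NCT_OTHER": 0.194})
    lag_mix: Mapping[str, float] = field(default_factory=lambda: {
        "before_start": 0.05, "within": 0.70, "lag1": 0.08, "lag2": 0.06,
        "lag3": 0.04, "lag4": 0.03, "beyond": 0.04})
    cost_range: tuple[float, float] = (0.5, 5.5)   # M$ per project-year, uniform
    designation_prevalences: Mapping[str, float] = field(default_factory=lambda: {
        "first_in_class": 0.361, "orphan": 0.431, "accelerated": 0.127,
        "breakthrough": 0.203, "fast_track": 0.369, "priority": 0.535})
    multi_phase_rate: float = 0.10    # phased pubs carrying a second, lower phase tag
    nct_signal_fraction: float = 0.40  # phased pubs whose phase comes via registry lookup
    second_link_rate: float = 0.15    # funded pubs linked to a second project
    review_decoy_rate: float = 0.05   # non-trial pubs tagged review (+ phase tag decoy)
    target_trial_fraction: float = 0.02  # trial-like target pubs (remain basic research)
    industry_coverage: float = 0.60   # drugs with an industry per-phase benchmark
    first_in_class_cost_multiplier: float = 1.0
    synonym_collisions: bool = False
    base_year: int = 2018
    seed: int = 0

    def validate(self) -> None:
        if self.n_drugs < 1 or self.n_targets < 0 or self.n_projects < 2:
            raise ConfigError("degenerate corpus: need >=1 drug and >=2 projects")
        if self.corpus_span[0] >= self.corpus_span[1]:
            raise ConfigError("corpus_span must be a nonempty year range")
        for name, mix in (("phase_mix", self.phase_mix), ("lag_mix", self.lag_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} probabilities must sum to 1")
        if set(self.lag_mix) != set(OFFSET_CLASSES):
            raise ConfigError(f"lag_mix must cover exactly {OFFSET_CLASSES}")
        if not (0 <= self.nih_funded_fraction <= 1):
            raise ConfigError("nih_funded_fraction must be a probability")
        if self.cost_range[0] < 0 or self.cost_range[0] >= self.cost_range[1]:
            raise ConfigError("cost_range must be a nonnegative, nonempty interval")


@dataclass
class GroundTruth:
    """True labels and true deduplicated funding totals for one corpus.

    ``publications`` — per-publication true category/trial/phase labels.
    ``links`` — per-(publication, project) realized offset class, inclusion
    flag and assigned fiscal year.  ``drug_costs`` / ``drug_totals`` — true
    per-drug (per-phase) development totals, deduplicated within each drug's
    scope.  ``phase_totals`` and ``category_totals`` — corpus-wide totals,
    deduplicated within each reported scope.  All costs in base-year M$.
    """

    publications: pd.DataFrame   # pmid, entity_id, category, is_trial, phase
    links: pd.DataFrame          # pmid, project_id, offset_class, included, fiscal_year
    drug_costs: pd.DataFrame     # drug_id, phase, project_years, adjusted_cost
    drug_totals: pd.DataFrame    # drug_id, project_years, adjusted_cost
    phase_totals: pd.DataFrame   # phase, project_years, adjusted_cost
    category_totals: pd.DataFrame  # category, project_years, adjusted_cost

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        long = []
        for r in self.drug_costs.itertuples():
            long.append(("drug_phase", r.drug_id, r.phase, r.project_years, r.adjusted_cost))
        for r in self.drug_totals.itertuples():
            long.append(("drug_total", r.drug_id, "", r.project_years, r.adjusted_cost))
        for r in self.phase_totals.itertuples():
            long.append(("phase", r.phase, "", r.project_years, r.adjusted_cost))
        for r in self.category_totals.itertuples():
            long.append(("category", r.category, "", r.project_years, r.adjusted_cost))
        pd.DataFrame(long, columns=["scope", "key", "subkey", "project_years",
                                    "adjusted_cost"]).to_csv(
            directory / "ground_truth.csv", index=False)
        self.publications.to_csv(directory / "ground_truth_publications.csv", index=False)
        self.links.to_csv(directory / "ground_truth_links.csv", index=False)


def _pick(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    keys = list(mix)
    return keys[rng.choice(len(keys), p=np.array([mix[k] for k in keys]))]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2, np.sqrt(sigma2)


def generate(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus bundle and its ground truth from ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    span_lo, span_hi = config.corpus_span

    # --- lexicon: collision-free synonyms unless collisions are requested
    drug_rows, target_rows = [], []
    drug_syns: dict[str, list[str]] = {}
    target_syns: dict[str, list[str]] = {}
    for i in range(config.n_drugs):
        did = f"DRG{i:04d}"
        syns = [f"drugbrand{i:04d}", f"ingredient{i:04d}", f"cc{i:04d}x"]
        if config.synonym_collisions and i % 2 == 1:
            syns.append(f"drugbrand{i - 1:04d}")
        drug_syns[did] = syns
        tgt = f"TGT{i % max(config.n_targets, 1):04d}" if config.n_targets else ""
        flags = {f: int(rng.random() < config.designation_prevalences.get(f, 0.0))
                 for f in DESIGNATION_FLAGS}
        drug_rows.append({"drug_id": did, "synonyms": join_tags(syns),
                          "approval_year": int(rng.integers(2010, 2020)),
                          "target_ids": tgt, **flags})
    for j in range(config.n_targets):
        tid = f"TGT{j:04d}"
        syns = [f"targetprot{j:04d}", f"gene{j:04d}sym"]
        target_syns[tid] = syns
        target_rows.append({"target_id": tid, "synonyms": join_tags(syns)})

    # --- project pools: each project is owned by exactly one drug or target,
    # so category scopes (and per-drug scopes) dedup over disjoint key sets
    exp_drug = config.n_drugs * config.pubs_per_drug
    exp_target = config.n_targets * config.pubs_per_target
    share = exp_drug / max(exp_drug + exp_target, 1e-9)
    n_drug_proj = min(max(config.n_drugs, round(config.n_projects * share)),
                      config.n_projects - (1 if config.n_targets else 0))
    owners = [("drug", f"DRG{i % config.n_drugs:04d}") for i in range(n_drug_proj)]
    owners += [("target", f"TGT{j % config.n_targets:04d}")
               for j in range(config.n_projects - n_drug_proj)] if config.n_targets else []

    fic = {r["drug_id"]: bool(r["first_in_class"]) for r in drug_rows}
    project_rows, cost_rows = [], []
    pool: dict[str, list[dict]] = {}
    code_dev = [c for c, _ in _ACTIVITY_CODES_DEV]
    p_dev = np.array([p for _, p in _ACTIVITY_CODES_DEV]); p_dev /= p_dev.sum()
    code_basic = [c for c, _ in _ACTIVITY_CODES_BASIC]
    p_basic = np.array([p for _, p in _ACTIVITY_CODES_BASIC]); p_basic /= p_basic.sum()
    for k, (kind, owner) in enumerate(owners):
        start = int(rng.integers(2002, 2011))
        end = start + int(rng.integers(3, 6))  # duration 3-5 fiscal years
        code = code_dev[rng.choice(len(code_dev), p=p_dev)] if kind == "drug" \
            else code_basic[rng.choice(len(code_basic), p=p_basic)]
        pid = f"PRJ{k:05d}"
        mult = config.first_in_class_cost_multiplier if (kind == "drug" and fic[owner]) else 1.0
        project_rows.append({"project_id": pid, "activity_code": code,
                             "start_year": start, "end_year": end})
        for fy in range(start, end + 1):
            cost = round(float(rng.uniform(*config.cost_range)) * mult, 4)
            cost_rows.append({"project_id": pid, "fiscal_year": fy, "cost": cost})
        pool.setdefault(owner, []).append({"project_id": pid, "start": start, "end": end})

    cost_lookup = {(r["project_id"], r["fiscal_year"]): r["cost"] for r in cost_rows}

    # --- inflation index: written first so ground truth uses the same table
    inflation_rows = [{"year": y, "index": round(1.02 ** (y - config.base_year), 6)}
                      for y in range(span_lo, span_hi + 1)]
    index = InflationIndex.from_frame(pd.DataFrame(inflation_rows), config.base_year)

    pub_rows, link_rows, registry_rows = [], [], []
    truth_pub_rows, truth_link_rows = [], []
    nct_counter = 0
    pmid_counter = 0

    def next_nct(phase: Phase | None) -> str:
        nonlocal nct_counter
        nct = f"NCT{nct_counter:08d}"
        nct_counter += 1
        registry_rows.append({"nct_id": nct,
                              "phase": "none" if phase is None else str(phase.rank)})
        return nct

    def draw_pub_year(offset: str, start: int, end: int) -> int:
        if offset == "before_start":
            return max(span_lo, start - int(rng.integers(1, 4)))
        if offset == "within":
            return int(rng.integers(start, end + 1))
        if offset.startswith("lag"):
            return end + int(offset[3:])
        return min(span_hi, end + 5 + int(rng.integers(0, 3)))  # beyond

    def offset_of(year: int, start: int, end: int) -> str:
        if year < start:
            return "before_start"
        if year <= end:
            return "within"
        if year <= end + 4:
            return f"lag{year - end}"
        return "beyond"

    def emit_links(pmid: str, owner: str) -> None:
        projects = pool.get(owner, [])
        if not projects:
            return
        chosen = [projects[int(rng.integers(len(projects)))]]
        if len(projects) > 1 and rng.random() < config.second_link_rate:
            other = projects[int(rng.integers(len(projects)))]
            if other["project_id"] != chosen[0]["project_id"]:
                chosen.append(other)
        primary = chosen[0]
        offset = _pick(rng, config.lag_mix)
        year = draw_pub_year(offset, primary["start"], primary["end"])
        for proj in chosen:
            off = offset_of(year, proj["start"], proj["end"])
            included = off in ("within", "lag1", "lag2", "lag3", "lag4")
            fy = year if off == "within" else (proj["end"] if included else None)
            link_rows.append({"pmid": pmid, "project_id": proj["project_id"]})
            truth_link_rows.append({"pmid": pmid, "project_id": proj["project_id"],
                                    "offset_class": off, "included": included,
                                    "fiscal_year": "" if fy is None else fy})
        emit_links.last_year = year  # type: ignore[attr-defined]

    # --- drug (applied) publications
    for did in sorted(drug_syns):
        n_pubs = max(1, int(rng.poisson(config.pubs_per_drug)))
        for _ in range(n_pubs):
            pmid = f"PM{pmid_counter:07d}"
            pmid_counter += 1
            syn = drug_syns[did][int(rng.integers(len(drug_syns[did])))]
            is_trial = rng.random() < config.trial_fraction
            phase = Phase.UNASSIGNED
            pub_types: set[str] = set()
            subject: set[str] = {"adult"}
            abstract = f"Findings on {syn} in cohort study {pmid.lower()}."
            title = f"Clinical evaluation of {syn}"
            if is_trial:
                subject.add("human")
                if rng.random() < config.phased_fraction:
                    key = _pick(rng, config.phase_mix)
                    if key == "NCT_OTHER":
                        phase = Phase.NCT_OTHER
                        abstract += f" Registered as {next_nct(None)}."
                    else:
                        phase = Phase(key)
                        pub_types.add("clinical-trial")
                        if rng.random() < config.nct_signal_fraction:
                            abstract += f" Registered as {next_nct(phase)}."
                            if rng.random() < config.multi_phase_rate and phase.rank > 1:
                                pub_types.add(PHASE_TAG[Phase(f"P{phase.rank - 1}")])
                        else:
                            pub_types.add(PHASE_TAG[phase])
                            if rng.random() < config.multi_phase_rate and phase.rank > 1:
                                pub_types.add(PHASE_TAG[Phase(f"P{phase.rank - 1}")])
                else:
                    pub_types.add("clinical-trial")  # trial with no phase information
            else:
                if rng.random() < config.review_decoy_rate:
                    # review of trials: phase tag present but excluded by rule
                    pub_types |= {"review", PHASE_TAG[Phase.P2]}
                    subject.add("human")
            pub_rows.append({"pmid": pmid, "year": 0, "title": title,
                             "abstract": abstract, "pub_types": join_tags(pub_types),
                             "subject_tags": join_tags(subject)})
            emit_links.last_year = None  # type: ignore[attr-defined]
            if rng.random() < config.nih_funded_fraction:
                emit_links(pmid, did)
            year = emit_links.last_year  # type: ignore[attr-defined]
            if year is None:
                year = int(rng.integers(2002, 2019))
            pub_rows[-1]["year"] = year
            truth_pub_rows.append({"pmid": pmid, "entity_id": did, "category": "applied",
                                   "is_trial": is_trial, "phase": phase.value})

    # --- target (basic) publications: no drug synonyms by construction
    for tid in sorted(target_syns):
        n_pubs = max(1, int(rng.poisson(config.pubs_per_target)))
        for _ in range(n_pubs):
            pmid = f"PM{pmid_counter:07d}"
            pmid_counter += 1
            syn = target_syns[tid][int(rng.integers(len(target_syns[tid])))]
            is_trial = rng.random() < config.target_trial_fraction
            pub_types, subject = set(), {"adult"}
            if is_trial:
                pub_types |= {"clinical-trial", PHASE_TAG[Phase.P2]}
                subject.add("human")
            pub_rows.append({"pmid": pmid, "year": 0,
                             "title": f"Mechanistic role of {syn}",
                             "abstract": f"Signaling by {syn} in disease models.",
                             "pub_types": join_tags(pub_types),
                             "subject_tags": join_tags(subject)})
            emit_links.last_year = None  # type: ignore[attr-defined]
            if rng.random() < config.nih_funded_fraction:
                emit_links(pmid, tid)
            year = emit_links.last_year  # type: ignore[attr-defined]
            if year is None:
                year = int(rng.integers(2002, 2019))
            pub_rows[-1]["year"] = year
            truth_pub_rows.append({"pmid": pmid, "entity_id": tid, "category": "basic",
                                   "is_trial": is_trial, "phase": Phase.UNASSIGNED.value})

    # spare registry entries never cited by any publication
    for _ in range(5):
        next_nct(Phase.P1)

    # --- industry benchmark table for a drug subset
    industry_rows = []
    for did in sorted(drug_syns):
        if rng.random() < config.industry_coverage:
            for ph, (mean, sd) in INDUSTRY_COST_SCALE.items():
                mu, sigma = _lognormal_params(mean, sd)
                industry_rows.append({"drug_id": did, "phase": ph,
                                      "cost": round(float(rng.lognormal(mu, sigma)), 4)})

    corpus = Corpus(
        publications=pd.DataFrame(pub_rows),
        links=pd.DataFrame(link_rows, columns=["pmid", "project_id"]).drop_duplicates(),
        projects=pd.DataFrame(project_rows),
        project_costs=pd.DataFrame(cost_rows),
        registry=pd.DataFrame(registry_rows, columns=["nct_id", "phase"]),
        drugs=pd.DataFrame(drug_rows),
        targets=pd.DataFrame(target_rows, columns=["target_id", "synonyms"]),
        industry_costs=pd.DataFrame(industry_rows, columns=["drug_id", "phase", "cost"]),
        inflation=pd.DataFrame(inflation_rows),
    )
    validate_corpus(corpus)

    truth = _build_truth(pd.DataFrame(truth_pub_rows), pd.DataFrame(
        truth_link_rows, columns=["pmid", "project_id", "offset_class", "included",
                                  "fiscal_year"]), cost_lookup, index)
    return corpus, truth


def _build_truth(pub_truth: pd.DataFrame, link_truth: pd.DataFrame,
                 cost_lookup: dict, index: InflationIndex) -> GroundTruth:
    """Derive the true deduplicated totals from the generator's own records.

    Works purely from the recorded per-link offsets and the cost table, by
    direct accumulation over (project, fiscal-year) keys — independent of the
    pipeline's attribution code.
    """
    pub_info = {r.pmid: r for r in pub_truth.itertuples()}

    def dev(pmid: str) -> bool:
        r = pub_info[pmid]
        return r.category == "applied" and r.is_trial and r.phase != "UNASSIGNED"

    included = link_truth[link_truth.included].copy() if len(link_truth) else link_truth
    scopes: dict[str, dict] = {"applied": {}, "basic": {}, "development": {}}
    per_drug: dict[str, dict] = {}
    for r in included.itertuples():
        info = pub_info[r.pmid]
        fy = int(r.fiscal_year)
        key = (r.project_id, fy)
        nominal = cost_lookup.get(key, 0.0)
        adjusted = index.adjust(nominal, fy)
        scopes[info.category].setdefault(key, adjusted)
        if dev(r.pmid):
            scopes["development"].setdefault(key, adjusted)
            entry = per_drug.setdefault(info.entity_id, {}).setdefault(
                key, {"adjusted": adjusted, "phases": set()})
            entry["phases"].add(Phase(info.phase))

    drug_cost_rows, drug_total_rows = [], []
    overall_phase: dict[str, dict[tuple, float]] = {}
    for did in sorted(per_drug):
        by_phase: dict[str, float] = {}
        by_phase_n: dict[str, int] = {}
        for key, entry in per_drug[did].items():
            ph = Phase.highest(entry["phases"]).value
            by_phase[ph] = by_phase.get(ph, 0.0) + entry["adjusted"]
            by_phase_n[ph] = by_phase_n.get(ph, 0) + 1
            overall_phase.setdefault(ph, {})[key] = entry["adjusted"]
        for ph in sorted(by_phase):
            drug_cost_rows.append({"drug_id": did, "phase": ph,
                                   "project_years": by_phase_n[ph],
                                   "adjusted_cost": by_phase[ph]})
        drug_total_rows.append({"drug_id": did,
                                "project_years": len(per_drug[did]),
                                "adjusted_cost": sum(v["adjusted"]
                                                     for v in per_drug[did].values())})

    phase_rows = [{"phase": ph, "project_years": len(keys),
                   "adjusted_cost": sum(keys.values())}
                  for ph, keys in sorted(overall_phase.items())]
    cat_rows = [{"category": cat, "project_years": len(keys),
                 "adjusted_cost": sum(keys.values())}
                for cat, keys in scopes.items()]

    cols_dc = ["drug_id", "phase", "project_years", "adjusted_cost"]
    cols_dt = ["drug_id", "project_years", "adjusted_cost"]
    return GroundTruth(
        publications=pub_truth,
        links=link_truth,
        drug_costs=pd.DataFrame(drug_cost_rows, columns=cols_dc),
        drug_totals=pd.DataFrame(drug_total_rows, columns=cols_dt),
        phase_totals=pd.DataFrame(phase_rows, columns=["phase", "project_years",
                                                       "adjusted_cost"]),
        category_totals=pd.DataFrame(cat_rows, columns=["category", "project_years",
                                                        "adjusted_cost"]),
    )


_NCT_RE = re.compile(r"NCT\d{8}")
_TRIAL_TAGS = {"clinical-trial"} | set(PHASE_TAG.values())


def inject_noise(corpus: Corpus, fp_rate: float, fn_rate: float,
                 seed: int) -> tuple[Corpus, pd.DataFrame]:
    """Flip the trial/non-trial signal of publications at the given rates.

    False negatives strip all trial metatags and NCT strings from a
    signal-bearing publication; false positives add a phase metatag (with the
    human subject tag, dropping any review tag) to a signal-free one.
    Returns the corrupted corpus and a table of flipped publications.
    """
    if not (0 <= fp_rate <= 1 and 0 <= fn_rate <= 1):
        raise ConfigError("noise rates must be probabilities")
    rng = np.random.default_rng(seed)
    out = corpus.copy()
    flips = []
    pubs = out.publications
    for i in pubs.index:
        tags = split_tags(pubs.at[i, "pub_types"])
        subject = split_tags(pubs.at[i, "subject_tags"])
        text = pubs.at[i, "title"] + " " + pubs.at[i, "abstract"]
        has_signal = (bool(tags & _TRIAL_TAGS) and "review" not in tags
                      and "human" in subject) or bool(_NCT_RE.search(text))
        if has_signal and rng.random() < fn_rate:
            tags -= _TRIAL_TAGS
            pubs.at[i, "title"] = _NCT_RE.sub("", pubs.at[i, "title"])
            pubs.at[i, "abstract"] = _NCT_RE.sub("", pubs.at[i, "abstract"])
            pubs.at[i, "pub_types"] = join_tags(tags)
            flips.append({"pmid": pubs.at[i, "pmid"], "flip": "fn"})
        elif not has_signal and rng.random() < fp_rate:
            tags |= {"clinical-trial", PHASE_TAG[Phase.P2]}
            tags.discard("review")
            subject.add("human")
            pubs.at[i, "pub_types"] = join_tags(tags)
            pubs.at[i, "subject_tags"] = join_tags(subject)
            flips.append({"pmid": pubs.at[i, "pmid"], "flip": "fp"})
    return out, pd.DataFrame(flips, columns=["pmid", "flip"])
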