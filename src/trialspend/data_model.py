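"""Shared domain types and delimited-text readers/writers.

The pipeline operates on a nine-table corpus bundle emulating the public
snapshots a funding-attribution study consumes:

* ``publications`` — PubMed-style records (PMID, year, title, abstract,
  publication-type metatags, subject-heading tags),
* ``links`` — a publication→project link table and ``projects`` /
  ``project_costs`` — per-project periods and per-fiscal-year costs, in the
  style of NIH RePORTER exports,
* ``registry`` — trial-registry entries mapping NCT identifiers to phases,
* ``drugs`` / ``targets`` — a search lexicon with approval years, FDA
  designation flags and target links,
* ``industry_costs`` — per-drug per-phase industry cost benchmarks,
* ``inflation`` — an annual price index used to restate all costs in
  base-year dollars.

All tables are serialized as comma-delimited text with a header row; set-like
cells (synonyms, tags) are semicolon-joined. Costs are carried in millions of
USD throughout.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


class SchemaError(ValueError):
    """A table is missing a required column or has a malformed value."""


class IntegrityError(ValueError):
    """A table references an identifier that does not exist."""


class ConfigError(ValueError):
    """A configuration value is missing, inconsistent, or degenerate."""


@functools.total_ordering
class Phase(enum.Enum):
    """Ordered clinical-phase label.

    Only the numbered phases P1 < P2 < P3 < P4 participate in the order used
    by the highest-phase rule.  ``NCT_OTHER`` marks trial publications whose
    registry entry carries no phase designation; ``UNASSIGNED`` marks trial
    publications with neither a phase metatag nor a resolvable NCT number.
    Comparing either of those two by order raises ``TypeError``.
    """

    P1 = "P1"
    P2 = "P2"
    P3 = "P3"
    P4 = "P4"
    NCT_OTHER = "NCT_OTHER"
    UNASSIGNED = "UNASSIGNED"

    @property
    def rank(self) -> int:
        if self in _PHASE_RANK:
            return _PHASE_RANK[self]
        raise TypeError(f"{self.value} has no position in the phase order")

    @property
    def is_numbered(self) -> bool:
        return self in _PHASE_RANK

    def __lt__(self, other: "Phase") -> bool:
        if not isinstance(other, Phase):
            return NotImplemented
        return self.rank < other.rank

    @staticmethod
    def highest(candidates: Iterable["Phase"]) -> "Phase":
        """Resolve a candidate set under the highest-phase rule.

        Numbered phases dominate; ``NCT_OTHER`` is returned only when no
        numbered candidate exists, and ``UNASSIGNED`` only when the set is
        empty or all-unassigned.
        """
        numbered = []
        saw_nct_other = False
        for c in candidates:
            if c.is_numbered:
                numbered.append(c)
            elif c is Phase.NCT_OTHER:
                saw_nct_other = True
        if numbered:
            return max(numbered)
        if saw_nct_other:
            return Phase.NCT_OTHER
        return Phase.UNASSIGNED


_PHASE_RANK = {Phase.P1: 1, Phase.P2: 2, Phase.P3: 3, Phase.P4: 4}

#: phases that carry development cost rows in reports, in display order
REPORT_PHASES = [Phase.P1, Phase.P2, Phase.P3, Phase.P4, Phase.NCT_OTHER]

DESIGNATION_FLAGS = [
    "first_in_class",
    "orphan",
    "accelerated",
    "breakthrough",
    "fast_track",
    "priority",
]

SCHEMAS: dict[str, list[str]] = {
    "publications": ["pmid", "year", "title", "abstract", "pub_types", "subject_tags"],
    "links": ["pmid", "project_id"],
    "projects": ["project_id", "activity_code", "start_year", "end_year"],
    "project_costs": ["project_id", "fiscal_year", "cost"],
    "registry": ["nct_id", "phase"],
    "drugs": ["drug_id", "synonyms", "approval_year", "target_ids"] + DESIGNATION_FLAGS,
    "targets": ["target_id", "synonyms"],
    "industry_costs": ["drug_id", "phase", "cost"],
    "inflation": ["year", "index"],
}

_INT_COLUMNS = {
    "publications": ["year"],
    "projects": ["start_year", "end_year"],
    "project_costs": ["fiscal_year"],
    "drugs": ["approval_year"] + DESIGNATION_FLAGS,
    "inflation": ["year"],
}
_FLOAT_COLUMNS = {
    "project_costs": ["cost"],
    "industry_costs": ["cost"],
    "inflation": ["index"],
}


def join_tags(tags: Iterable[str]) -> str:
    """Serialize a tag/synonym collection to a semicolon-joined cell."""
    return ";".join(sorted(set(tags)))


def split_tags(cell: object) -> set[str]:
    """Parse a semicolon-joined cell back into a set (empty cell → empty set)."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return set()
    text = str(cell).strip()
    return {t for t in text.split(";") if t} if text else set()


@dataclass
class InflationIndex:
    """Annual price index with a designated base year.

    ``adjust`` restates a nominal amount from ``year`` dollars into base-year
    dollars as ``amount * index[base_year] / index[year]``; at the base year
    the adjustment is the identity.  The deflator series is an explicit input
    table, never a built-in constant.
    """

    index: Mapping[int, float]
    base_year: int

    def __post_init__(self) -> None:
        if self.base_year not in self.index:
            raise ConfigError(f"base year {self.base_year} absent from inflation index")
        bad = [y for y, v in self.index.items() if v <= 0]
        if bad:
            raise ConfigError(f"non-positive index values for years {sorted(bad)}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, base_year: int) -> "InflationIndex":
        return cls({int(r.year): float(r.index) for r in frame.itertuples()}, base_year)

    def adjust(self, amount: float, year: int) -> float:
        if year not in self.index:
            raise ConfigError(f"year {year} absent from inflation index")
        return amount * self.index[self.base_year] / self.index[year]


def adjust_inflation(amount: float, year: int, index: InflationIndex) -> float:
    """Restate ``amount`` (nominal, ``year`` dollars) in base-year dollars."""
    return index.adjust(amount, year)


@dataclass
class Corpus:
    """Validated bundle of the nine input tables."""

    publications: pd.DataFrame
    links: pd.DataFrame
    projects: pd.DataFrame
    project_costs: pd.DataFrame
    registry: pd.DataFrame
    drugs: pd.DataFrame
    targets: pd.DataFrame
    industry_costs: pd.DataFrame
    inflation: pd.DataFrame

    def table_names(self) -> list[str]:
        return [f.name for f in fields(self)]

    def copy(self) -> "Corpus":
        return Corpus(**{n: getattr(self, n).copy() for n in self.table_names()})

    def registry_phases(self) -> dict[str, Phase | None]:
        """NCT id → registry phase (``None`` for entries with no designation)."""
        out: dict[str, Phase | None] = {}
        for row in self.registry.itertuples():
            p = str(row.phase)
            out[str(row.nct_id)] = None if p in ("none", "", "nan") else Phase(f"P{int(p)}")
        return out


def _coerce(name: str, frame: pd.DataFrame) -> pd.DataFrame:
    required = SCHEMAS[name]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"table '{name}' missing column(s): {', '.join(missing)}")
    frame = frame[required].copy()
    for col in _INT_COLUMNS.get(name, []):
        frame[col] = frame[col].astype(int)
    for col in _FLOAT_COLUMNS.get(name, []):
        frame[col] = frame[col].astype(float)
    for col in required:
        if col not in _INT_COLUMNS.get(name, []) and col not in _FLOAT_COLUMNS.get(name, []):
            frame[col] = frame[col].fillna("").astype(str)
    return frame


def _check_unique(frame: pd.DataFrame, cols: list[str], table: str) -> None:
    dup = frame[frame.duplicated(cols)]
    if not dup.empty:
        offenders = dup[cols].head(5).to_dict("records")
        raise IntegrityError(f"duplicate {cols} in '{table}': {offenders}")


def validate_corpus(corpus: Corpus) -> Corpus:
    """Check schemas, key uniqueness and referential integrity.

    Raises :class:`SchemaError` for missing columns and
    :class:`IntegrityError` for dangling references, naming the offenders.
    """
    for name in corpus.table_names():
        setattr(corpus, name, _coerce(name, getattr(corpus, name)))

    _check_unique(corpus.publications, ["pmid"], "publications")
    _check_unique(corpus.projects, ["project_id"], "projects")
    _check_unique(corpus.project_costs, ["project_id", "fiscal_year"], "project_costs")
    _check_unique(corpus.links, ["pmid", "project_id"], "links")
    _check_unique(corpus.registry, ["nct_id"], "registry")
    _check_unique(corpus.drugs, ["drug_id"], "drugs")
    _check_unique(corpus.targets, ["target_id"], "targets")
    _check_unique(corpus.industry_costs, ["drug_id", "phase"], "industry_costs")
    _check_unique(corpus.inflation, ["year"], "inflation")

    bad = corpus.projects[corpus.projects.start_year > corpus.projects.end_year]
    if not bad.empty:
        raise IntegrityError(f"projects with start_year > end_year: {bad.project_id.tolist()[:5]}")
    if (corpus.project_costs.cost < 0).any():
        raise IntegrityError("negative cost rows in project_costs")

    pmids = set(corpus.publications.pmid)
    projects = set(corpus.projects.project_id)
    drugs = set(corpus.drugs.drug_id)

    def _dangling(series: pd.Series, universe: set, label: str) -> None:
        missing = sorted(set(series) - universe)
        if missing:
            raise IntegrityError(f"dangling {label} reference(s): {missing[:5]}")

    _dangling(corpus.links.pmid, pmids, "links.pmid")
    _dangling(corpus.links.project_id, projects, "links.project_id")
    _dangling(corpus.project_costs.project_id, projects, "project_costs.project_id")
    _dangling(corpus.industry_costs.drug_id, drugs, "industry_costs.drug_id")

    empty_syn = corpus.drugs[corpus.drugs.synonyms.map(lambda c: not split_tags(c))]
    if not empty_syn.empty:
        raise IntegrityError(f"drugs with empty synonym set: {empty_syn.drug_id.tolist()[:5]}")
    empty_syn = corpus.targets[corpus.targets.synonyms.map(lambda c: not split_tags(c))]
    if not empty_syn.empty:
        raise IntegrityError(f"targets with empty synonym set: {empty_syn.target_id.tolist()[:5]}")

    cost_years = set(corpus.project_costs.fiscal_year)
    index_years = set(corpus.inflation.year)
    missing_years = sorted(cost_years - index_years)
    if missing_years:
        raise IntegrityError(f"inflation index missing years: {missing_years[:5]}")
    return corpus


def read_corpus(directory: str | Path, base_year: int | None = None) -> Corpus:
    """Read and validate a corpus bundle from ``directory``.

    Every table is expected at ``<directory>/<table>.csv``. ``base_year`` is
    only checked against the inflation table when given.
    """
    directory = Path(directory)
    frames = {}
    for name in SCHEMAS:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"missing input file: {path}")
        frames[name] = pd.read_csv(path, dtype=str, keep_default_na=False)
    corpus = validate_corpus(Corpus(**frames))
    if base_year is not None and base_year not in set(corpus.inflation.year):
        raise ConfigError(f"base year {base_year} absent from inflation table")
    return corpus


def write_corpus(corpus: Corpus, directory: str | Path) -> None:
    """Write all nine tables as ``<table>.csv`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in corpus.table_names():
        getattr(corpus, name).to_csv(directory / f"{name}.csv", index=False)
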