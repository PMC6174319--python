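"""Pedigree records, sibship structure, delimited-text I/O, and sample filters.

The data model is a flat table of individuals (one row per person with
calendar-year vital data and parent links) from which full-sib sibships are
derived.  Two filters mirror a genealogical-database study design:

* inclusion filters keep whole sibships only when every sibling was born on
  or before a cap year, every sibling has usable year data, and both parents
  are identifiable with year data;
* score eligibility additionally drops adoptees and anyone not known to have
  survived to the life-table conditioning age (default 40).

Individuals removed by a filter are moved to the sample's ``externals``
registry so they remain resolvable as parent references, which keeps the
filters idempotent.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import PedigreeDataError, PedigreeFormatError

log = logging.getLogger(__name__)

FEMALE = "F"
MALE = "M"
SEXES = (FEMALE, MALE)

#: canonical column order of the pedigree file dialect
PEDIGREE_COLUMNS = [
    "person_id",
    "sex",
    "birth_year",
    "death_year",
    "last_alive_year",
    "mother_id",
    "father_id",
    "adopted",
]

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no", ""}


@dataclass
class Individual:
    """One person: identifiers, sex, calendar-year vital data, parent links.

    ``death_year`` and ``last_alive_year`` are calendar years; at least one
    must be present for the person to be analyzable (both absent is allowed
    but such a person fails the inclusion filters).  All ages are integer
    calendar-year differences.
    """

    person_id: str
    sex: str
    birth_year: int
    death_year: int | None = None
    last_alive_year: int | None = None
    mother_id: str | None = None
    father_id: str | None = None
    adopted: bool = False

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise PedigreeDataError(
                f"{self.person_id}: sex must be one of {SEXES}, got {self.sex!r}"
            )
        if self.death_year is not None and self.death_year < self.birth_year:
            raise PedigreeDataError(
                f"{self.person_id}: death_year {self.death_year} before "
                f"birth_year {self.birth_year}"
            )
        if self.last_alive_year is not None and self.last_alive_year < self.birth_year:
            raise PedigreeDataError(
                f"{self.person_id}: last_alive_year {self.last_alive_year} before "
                f"birth_year {self.birth_year}"
            )

    @property
    def has_vital_info(self) -> bool:
        """True when a death year or a last-known-alive year is recorded."""
        return self.death_year is not None or self.last_alive_year is not None

    @property
    def is_deceased(self) -> bool:
        return self.death_year is not None

    @property
    def end_year(self) -> int | None:
        """Death year if known, else last-known-alive year."""
        if self.death_year is not None:
            return self.death_year
        return self.last_alive_year

    @property
    def attained_age(self) -> int | None:
        """Age at death, or age at last contact for the censored.

        Lifespan is the integer year difference (year of death minus year of
        birth); no month/day resolution is used anywhere in the package.
        """
        end = self.end_year
        return None if end is None else end - self.birth_year


@dataclass
class Sibship:
    """A set of full siblings treated as one family unit for scoring."""

    sibship_id: str
    mother_id: str | None
    father_id: str | None
    member_ids: list[str]

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class RowDiagnostic:
    """Row-level validation failure emitted by :func:`read_pedigree`."""

    row: int
    person_id: str
    rule: str


class PedigreeSample:
    """A collection of individuals with an optional sibship partition.

    ``externals`` holds records of people who are referenced as parents but
    are not analysis members (either never were, or were removed by a
    filter); parent references resolve against members first, then externals.
    """

    def __init__(
        self,
        individuals: Mapping[str, Individual] | Iterable[Individual],
        sibships: Mapping[str, Sibship] | None = None,
        externals: Mapping[str, Individual] | None = None,
        provenance: str = "",
        diagnostics: list[RowDiagnostic] | None = None,
    ) -> None:
        if not isinstance(individuals, Mapping):
            individuals = {ind.person_id: ind for ind in individuals}
        self.individuals: dict[str, Individual] = dict(individuals)
        self.sibships: dict[str, Sibship] | None = (
            dict(sibships) if sibships is not None else None
        )
        self.externals: dict[str, Individual] = dict(externals or {})
        self.provenance = provenance
        self.diagnostics = diagnostics or []
        #: optional simulation ground truth (per-person frailty), set by the generator
        self.truth: pd.DataFrame | None = None
        self._frame: pd.DataFrame | None = None
        self._sibship_of: dict[str, str] | None = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals.values())

    def __contains__(self, person_id: str) -> bool:
        return person_id in self.individuals

    def __getitem__(self, person_id: str) -> Individual:
        return self.individuals[person_id]

    # -- lookups ------------------------------------------------------------
    @property
    def has_sibships(self) -> bool:
        return self.sibships is not None

    def sibship_of(self, person_id: str) -> str:
        if self.sibships is None:
            raise ValueError("sibships not derived; call derive_sibships first")
        if self._sibship_of is None:
            self._sibship_of = {
                pid: sid for sid, sib in self.sibships.items() for pid in sib.member_ids
            }
        return self._sibship_of[person_id]

    def parent_record(self, person_id: str | None) -> Individual | None:
        """Resolve a parent reference among members, then externals."""
        if person_id is None:
            return None
        rec = self.individuals.get(person_id)
        if rec is None:
            rec = self.externals.get(person_id)
        return rec

    def frame(self) -> pd.DataFrame:
        """Members as a DataFrame (cached); used by the vectorized stages."""
        if self._frame is None:
            rows = {
                "person_id": [],
                "sex": [],
                "birth_year": [],
                "death_year": [],
                "last_alive_year": [],
                "mother_id": [],
                "father_id": [],
                "adopted": [],
            }
            for ind in self.individuals.values():
                rows["person_id"].append(ind.person_id)
                rows["sex"].append(ind.sex)
                rows["birth_year"].append(ind.birth_year)
                rows["death_year"].append(ind.death_year)
                rows["last_alive_year"].append(ind.last_alive_year)
                rows["mother_id"].append(ind.mother_id)
                rows["father_id"].append(ind.father_id)
                rows["adopted"].append(ind.adopted)
            df = pd.DataFrame(rows)
            df["death_year"] = df["death_year"].astype("float64")
            df["last_alive_year"] = df["last_alive_year"].astype("float64")
            df["end_year"] = df["death_year"].fillna(df["last_alive_year"])
            df["attained_age"] = df["end_year"] - df["birth_year"]
            if self.sibships is not None:
                df["sibship_id"] = [self.sibship_of(p) for p in df["person_id"]]
            self._frame = df
        return self._frame

    def replace(self, **kwargs) -> "PedigreeSample":
        out = PedigreeSample(
            kwargs.get("individuals", self.individuals),
            kwargs.get("sibships", self.sibships),
            kwargs.get("externals", self.externals),
            kwargs.get("provenance", self.provenance),
        )
        out.truth = self.truth
        return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _delimiter(dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")


def _parse_year(value: str, row: int, column: str) -> int | None:
    if value == "":
        return None
    try:
        return int(value)
    except ValueError:
        raise PedigreeDataError(
            f"row {row}: unparsable {column} value {value!r}"
        ) from None


def read_pedigree(path: str | Path, dialect: str = "csv") -> PedigreeSample:
    """Read a pedigree file into a validated :class:`PedigreeSample`.

    Empty fields denote absent values.  Rows violating relational invariants
    (death before birth, unknown sex code) are rejected and reported through
    ``sample.diagnostics`` and the log; structural problems (missing columns,
    duplicate ids, unparsable years) raise.
    """
    path = Path(path)
    delim = _delimiter(dialect)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise PedigreeFormatError(f"{path}: empty file")
        missing = set(PEDIGREE_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise PedigreeFormatError(
                f"{path}: missing required column(s) {sorted(missing)}"
            )
        individuals: dict[str, Individual] = {}
        diagnostics: list[RowDiagnostic] = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            pid = row["person_id"].strip()
            if not pid:
                raise PedigreeDataError(f"row {i}: empty person_id")
            if pid in individuals:
                raise PedigreeDataError(f"row {i}: duplicate person_id {pid!r}")
            birth = _parse_year(row["birth_year"], i, "birth_year")
            if birth is None:
                raise PedigreeDataError(f"row {i}: missing birth_year")
            adopted_raw = row["adopted"].strip().lower()
            if adopted_raw in _TRUE:
                adopted = True
            elif adopted_raw in _FALSE:
                adopted = False
            else:
                raise PedigreeDataError(
                    f"row {i}: unparsable adopted flag {row['adopted']!r}"
                )
            ind = Individual(
                person_id=pid,
                sex=row["sex"].strip(),
                birth_year=birth,
                death_year=_parse_year(row["death_year"], i, "death_year"),
                last_alive_year=_parse_year(row["last_alive_year"], i, "last_alive_year"),
                mother_id=row["mother_id"].strip() or None,
                father_id=row["father_id"].strip() or None,
                adopted=adopted,
            )
            try:
                ind.validate()
            except PedigreeDataError as exc:
                diagnostics.append(RowDiagnostic(row=i, person_id=pid, rule=str(exc)))
                log.warning("rejected row %d (%s): %s", i, pid, exc)
                continue
            individuals[pid] = ind
    return PedigreeSample(
        individuals, provenance=str(path), diagnostics=diagnostics
    )


def write_pedigree(sample: PedigreeSample, path: str | Path, dialect: str = "csv") -> None:
    """Write members in the canonical column schema (absent values as '')."""
    delim = _delimiter(dialect)
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(PEDIGREE_COLUMNS)
        for ind in sample.individuals.values():
            writer.writerow(
                [
                    ind.person_id,
                    ind.sex,
                    ind.birth_year,
                    "" if ind.death_year is None else ind.death_year,
                    "" if ind.last_alive_year is None else ind.last_alive_year,
                    ind.mother_id or "",
                    ind.father_id or "",
                    "1" if ind.adopted else "0",
                ]
            )


# ---------------------------------------------------------------------------
# sibship derivation and filters
# ---------------------------------------------------------------------------

def derive_sibships(sample: PedigreeSample, key: str = "full") -> PedigreeSample:
    """Partition the members into sibships.

    ``key='full'`` groups by the ordered (mother_id, father_id) pair, so
    half-siblings fall in different sibships; anyone missing a parent id
    becomes a singleton (an unknown parent cannot confirm full sibship).
    ``key='mother'`` groups by mother_id alone.
    """
    if key not in ("full", "mother"):
        raise ValueError("key must be 'full' or 'mother'")
    grouped: dict[tuple, list[str]] = {}
    singletons: list[str] = []
    for ind in sample.individuals.values():
        if key == "full":
            k = (ind.mother_id, ind.father_id)
            known = ind.mother_id is not None and ind.father_id is not None
        else:
            k = (ind.mother_id,)
            known = ind.mother_id is not None
        if known:
            grouped.setdefault(k, []).append(ind.person_id)
        else:
            singletons.append(ind.person_id)
    sibships: dict[str, Sibship] = {}
    for k in sorted(grouped):
        sid = "fam:" + "+".join(k)
        mother = k[0]
        father = k[1] if key == "full" else None
        sibships[sid] = Sibship(sid, mother, father, sorted(grouped[k]))
    for pid in sorted(singletons):
        sid = f"solo:{pid}"
        ind = sample.individuals[pid]
        sibships[sid] = Sibship(sid, ind.mother_id, ind.father_id, [pid])
    return sample.replace(sibships=sibships)


def _parent_ok(sample: PedigreeSample, parent_id: str | None) -> bool:
    rec = sample.parent_record(parent_id)
    return rec is not None and rec.has_vital_info


def apply_inclusion_filters(
    sample: PedigreeSample, max_birth_year: int = 1910
) -> PedigreeSample:
    """Retain whole sibships satisfying the three inclusion criteria.

    (1) every member born in ``max_birth_year`` or earlier; (2) every member
    has a year of death or a last-known-alive year; (3) every member's mother
    and father are resolvable with birth and death (or last-alive) years.
    Sibships are kept or dropped atomically; dropped individuals move to the
    externals registry so re-application is a no-op.
    """
    if sample.sibships is None:
        raise ValueError("sibships not derived; call derive_sibships first")
    drops = {"birth_year_cap": 0, "missing_vital_years": 0, "parent_information": 0}
    kept: dict[str, Sibship] = {}
    kept_inds: dict[str, Individual] = {}
    dropped_inds: dict[str, Individual] = {}
    for sid, sib in sample.sibships.items():
        members = [sample.individuals[p] for p in sib.member_ids]
        ok1 = all(m.birth_year <= max_birth_year for m in members)
        ok2 = all(m.has_vital_info for m in members)
        ok3 = all(
            _parent_ok(sample, m.mother_id) and _parent_ok(sample, m.father_id)
            for m in members
        )
        if not ok1:
            drops["birth_year_cap"] += 1
        if not ok2:
            drops["missing_vital_years"] += 1
        if not ok3:
            drops["parent_information"] += 1
        if ok1 and ok2 and ok3:
            kept[sid] = sib
            for m in members:
                kept_inds[m.person_id] = m
        else:
            for m in members:
                dropped_inds[m.person_id] = m
    log.info(
        "inclusion filters: kept %d/%d sibships (dropped per criterion: %s)",
        len(kept),
        len(sample.sibships),
        drops,
    )
    externals = dict(sample.externals)
    externals.update(dropped_inds)
    return sample.replace(individuals=kept_inds, sibships=kept, externals=externals)


def apply_score_eligibility(sample: PedigreeSample, min_age: int = 40) -> PedigreeSample:
    """Drop adoptees and anyone whose attained age is below ``min_age``.

    'Died before ``min_age``' is strict: death at attained age exactly
    ``min_age`` stays eligible.  Sibships shrink (possibly to empty, in which
    case they are removed); removed individuals move to externals.
    """
    if sample.sibships is None:
        raise ValueError("sibships not derived; call derive_sibships first")
    kept: dict[str, Sibship] = {}
    kept_inds: dict[str, Individual] = {}
    dropped_inds: dict[str, Individual] = {}
    n_adopted = n_young = 0
    for sid, sib in sample.sibships.items():
        retained = []
        for pid in sib.member_ids:
            ind = sample.individuals[pid]
            age = ind.attained_age
            if ind.adopted:
                n_adopted += 1
                dropped_inds[pid] = ind
            elif age is None or age < min_age:
                n_young += 1
                dropped_inds[pid] = ind
            else:
                retained.append(pid)
                kept_inds[pid] = ind
        if retained:
            kept[sid] = replace(sib, member_ids=retained)
    log.info(
        "score eligibility: removed %d adopted and %d below age %d; "
        "%d sibships remain",
        n_adopted,
        n_young,
        min_age,
        len(kept),
    )
    externals = dict(sample.externals)
    externals.update(dropped_inds)
    return sample.replace(individuals=kept_inds, sibships=kept, externals=externals)
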