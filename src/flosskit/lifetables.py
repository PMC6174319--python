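"""Sex- and birth-cohort-specific survival tables conditional on age 40.

Tables are built with the product-limit estimator, left-truncated at the
base age so only people who attained it enter the risk set; people with only
a last-known-alive year are right-censored at that age.  Survival is stored
on an integer age grid starting at the base age with S(base_age)=1; queries
at non-integer ages interpolate log S linearly, and ages beyond the grid are
carried forward flat.

An external SSA-style table (columns ``age,survival`` or ``age,lx``) can be
read for comparison curves; ``lx`` inputs are normalized to the base-age row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    CohortRangeError,
    ConditioningError,
    EmptyStratumError,
    LifeTableFormatError,
)
from .pedigree import SEXES, PedigreeSample
from .survival import km_from_arrays

log = logging.getLogger(__name__)

_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class CohortBand:
    """A birth-year band; ``start_year=None`` means an open lower edge."""

    label: str
    start_year: int | None
    end_year: int

    def contains(self, year: int) -> bool:
        lo_ok = self.start_year is None or year >= self.start_year
        return lo_ok and year <= self.end_year


def default_bands(
    open_before: int = 1850, end_year: int = 1910, width: int = 10
) -> list[CohortBand]:
    """Decade bands with a pooled open band below ``open_before``.

    The terminal band absorbs the remainder up to ``end_year`` (so with the
    defaults it spans 1900-1910 and 1910 does not form a one-year cohort).
    """
    bands = [CohortBand(f"pre-{open_before}", None, open_before - 1)]
    start = open_before
    while start + width <= end_year:
        stop = start + width - 1
        if start + 2 * width > end_year:
            stop = end_year  # terminal band absorbs the remainder
        bands.append(CohortBand(f"{start}-{stop}", start, stop))
        start = stop + 1
    return bands


def assign_cohort(birth_year: int, bands: Iterable[CohortBand]) -> CohortBand:
    """Return the unique band containing ``birth_year``."""
    for band in bands:
        if band.contains(birth_year):
            return band
    raise CohortRangeError(f"birth year {birth_year} outside all cohort bands")


class CohortLifeTable:
    """Survival conditional on the base age, on an integer age grid."""

    def __init__(
        self,
        sex: str,
        band: CohortBand,
        base_age: int,
        ages: np.ndarray,
        survival: np.ndarray,
        n_risk: np.ndarray | None = None,
        n_event: np.ndarray | None = None,
    ) -> None:
        self.sex = sex
        self.band = band
        self.base_age = int(base_age)
        self.ages = np.asarray(ages, dtype=int)
        self.survival = np.asarray(survival, dtype=float)
        self.n_risk = None if n_risk is None else np.asarray(n_risk, dtype=float)
        self.n_event = None if n_event is None else np.asarray(n_event, dtype=float)
        self._validate()

    def _validate(self) -> None:
        if self.ages.size == 0:
            raise LifeTableFormatError("empty age grid")
        if self.ages[0] != self.base_age:
            raise LifeTableFormatError(
                f"grid must start at base_age {self.base_age}, got {self.ages[0]}"
            )
        if self.ages.size > 1 and np.any(np.diff(self.ages) <= 0):
            raise LifeTableFormatError("ages must be strictly increasing")
        if abs(self.survival[0] - 1.0) > 1e-9:
            raise LifeTableFormatError("S(base_age) must be 1")
        if np.any(np.diff(self.survival) > _ZERO_TOL):
            raise LifeTableFormatError("survival must be non-increasing")
        if self.survival.min() < -_ZERO_TOL or self.survival.max() > 1 + _ZERO_TOL:
            raise LifeTableFormatError("survival must lie in [0, 1]")

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    @property
    def min_positive_survival(self) -> float:
        """Smallest strictly positive tabulated value (score truncation)."""
        pos = self.survival[self.survival > 0]
        return float(pos.min())

    def survival_at(self, age) -> np.ndarray | float:
        """S(age | base_age) with log-linear interpolation between grid ages.

        Ages below the base age return 1, ages beyond the grid return the
        last tabulated value (flat carry-forward); values that interpolate
        below 1e-12 are reported as exactly 0.
        """
        x = np.asarray(age, dtype=float)
        logs = np.log(np.clip(self.survival, 1e-300, 1.0))
        out = np.exp(np.interp(x, self.ages, logs))
        out = np.where(out < _ZERO_TOL, 0.0, out)
        return float(out) if np.isscalar(age) or x.ndim == 0 else out

    def neg_log_survival_at(self, age) -> np.ndarray | float:
        """u = -log S(age), truncated at the last positive tabulated value."""
        s = np.asarray(self.survival_at(age), dtype=float)
        s = np.clip(s, self.min_positive_survival, 1.0)
        out = -np.log(s)
        return float(out) if np.isscalar(age) else out

    @classmethod
    def from_records(
        cls,
        sex: str,
        band: CohortBand,
        entry_ages,
        exit_ages,
        events,
        base_age: int = 40,
    ) -> "CohortLifeTable":
        """Product-limit table from (possibly continuous) age records.

        Entries are clipped to the base age; records not surviving past it
        are excluded (a death at exactly the base age is the boundary and
        contributes nothing, consistent with S(base_age)=1).
        """
        entry = np.maximum(np.asarray(entry_ages, dtype=float), float(base_age))
        exit_ = np.asarray(exit_ages, dtype=float)
        event = np.asarray(events, dtype=bool)
        keep = exit_ > entry
        if not np.any(exit_ >= base_age):
            raise EmptyStratumError(
                f"no individuals attain base age {base_age} in stratum "
                f"{sex}/{band.label}"
            )
        if not np.any(keep):
            # everyone censored or dead exactly at the base age: degenerate grid
            return cls(sex, band, base_age, np.array([base_age]), np.array([1.0]))
        curve = km_from_arrays(entry[keep], exit_[keep], event[keep])
        top = int(np.floor(exit_[keep].max()))
        grid = np.arange(base_age, max(top, base_age) + 1)
        surv = np.asarray(curve.evaluate(grid.astype(float)), dtype=float)
        surv[0] = 1.0
        return cls(sex, band, base_age, grid, surv)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "survival": self.survival})

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"CohortLifeTable(sex={self.sex!r}, band={self.band.label!r}, "
            f"base_age={self.base_age}, ages={self.ages[0]}..{self.ages[-1]})"
        )


def conditional_survival(
    table: CohortLifeTable, t, condition_age: int | None = None
) -> np.ndarray | float:
    """S(t)/S(condition_age) for t >= condition_age (default the base age)."""
    if condition_age is None:
        condition_age = table.base_age
    if condition_age < table.base_age:
        raise ValueError("condition_age must be >= base_age")
    s0 = table.survival_at(condition_age)
    if s0 <= 0:
        raise ConditioningError(
            f"survival is 0 at conditioning age {condition_age}"
        )
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < condition_age):
        raise ValueError("t must be >= condition_age")
    return table.survival_at(t) / s0


def build_cohort_life_table(
    sample: PedigreeSample,
    sex: str,
    band: CohortBand,
    base_age: int = 40,
    method: str = "product-limit",
) -> CohortLifeTable:
    """Build one stratum's table from a filtered pedigree sample.

    ``method='product-limit'`` treats last-alive-only individuals as
    right-censored; ``method='empirical'`` uses known deaths only (simple
    death-count survival), provided for sensitivity checks.
    """
    df = sample.frame()
    mask = (
        (df["sex"] == sex)
        & df["birth_year"].apply(band.contains)
        & df["attained_age"].notna()
    )
    sub = df.loc[mask]
    if sub.empty:
        raise EmptyStratumError(f"empty stratum {sex}/{band.label}")
    if method == "product-limit":
        return CohortLifeTable.from_records(
            sex,
            band,
            np.full(len(sub), float(base_age)),
            sub["attained_age"].to_numpy(dtype=float),
            sub["death_year"].notna().to_numpy(),
            base_age=base_age,
        )
    if method == "empirical":
        deaths = sub.loc[sub["death_year"].notna(), "attained_age"].to_numpy(float)
        deaths = deaths[deaths >= base_age]
        if deaths.size == 0:
            raise EmptyStratumError(
                f"no deaths past base age in stratum {sex}/{band.label}"
            )
        grid = np.arange(base_age, int(deaths.max()) + 1)
        denom = (deaths > base_age).sum()
        if denom == 0:
            return CohortLifeTable(
                sex, band, base_age, np.array([base_age]), np.array([1.0])
            )
        surv = np.array([(deaths > t).sum() / denom for t in grid], dtype=float)
        surv[0] = 1.0
        return CohortLifeTable(sex, band, base_age, grid, surv)
    raise ValueError("method must be 'product-limit' or 'empirical'")


class LifeTableSet:
    """Tables keyed by (sex, band label), with birth-year lookup."""

    def __init__(
        self,
        tables: Mapping[tuple[str, str], CohortLifeTable],
        bands: list[CohortBand],
    ) -> None:
        self.tables = dict(tables)
        self.bands = list(bands)
        if not self.tables:
            raise EmptyStratumError("no life tables in set")
        base_ages = {t.base_age for t in self.tables.values()}
        if len(base_ages) != 1:
            raise ValueError("tables in a set must share base_age")
        self.base_age = base_ages.pop()

    def lookup(self, sex: str, birth_year: int) -> CohortLifeTable:
        band = assign_cohort(birth_year, self.bands)
        try:
            return self.tables[(sex, band.label)]
        except KeyError:
            raise EmptyStratumError(
                f"no life table for stratum {sex}/{band.label}"
            ) from None

    def items(self):
        return self.tables.items()


def build_life_tables(
    sample: PedigreeSample,
    bands: list[CohortBand] | None = None,
    base_age: int = 40,
    method: str = "product-limit",
) -> LifeTableSet:
    """Build all sex x band tables present in the sample (empty strata skipped)."""
    if bands is None:
        bands = default_bands()
    tables: dict[tuple[str, str], CohortLifeTable] = {}
    for sex in SEXES:
        for band in bands:
            try:
                tables[(sex, band.label)] = build_cohort_life_table(
                    sample, sex, band, base_age=base_age, method=method
                )
            except EmptyStratumError:
                log.warning("skipping empty stratum %s/%s", sex, band.label)
    return LifeTableSet(tables, bands)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_life_table(table: CohortLifeTable, path: str | Path) -> None:
    """Write as delimited text with a '#' metadata header line."""
    band = table.band
    start = "" if band.start_year is None else band.start_year
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(
            f"# sex={table.sex} band={band.label} band_start={start} "
            f"band_end={band.end_year} base_age={table.base_age}\n"
        )
        fh.write("age,survival\n")
        for a, s in zip(table.ages, table.survival):
            fh.write(f"{int(a)},{float(s)!r}\n")


def read_life_table(path: str | Path, dialect: str = "csv") -> CohortLifeTable:
    """Read an ``age,survival`` or ``age,lx`` table; normalize lx to base age.

    Metadata may be supplied on a leading ``#`` comment line as key=value
    pairs (sex, band, band_start, band_end, base_age); absent metadata
    defaults to an all-years band and a base age equal to the first grid age.
    """
    path = Path(path)
    delim = "," if dialect == "csv" else "\t"
    meta: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
    df = pd.read_csv(path, sep=delim, comment="#", float_precision="round_trip")
    if "age" not in df.columns:
        raise LifeTableFormatError(f"{path}: missing 'age' column")
    if "survival" in df.columns:
        values = df["survival"].to_numpy(dtype=float)
    elif "lx" in df.columns:
        values = df["lx"].to_numpy(dtype=float)
    else:
        raise LifeTableFormatError(f"{path}: need a 'survival' or 'lx' column")
    ages = df["age"].to_numpy(dtype=int)
    base_age = int(meta["base_age"]) if "base_age" in meta else int(ages[0])
    at_base = np.flatnonzero(ages == base_age)
    if at_base.size == 0:
        raise LifeTableFormatError(f"{path}: no row at base_age {base_age}")
    norm = values[at_base[0]]
    if norm <= 0:
        raise LifeTableFormatError(f"{path}: value at base_age is not positive")
    keep = ages >= base_age
    sex = meta.get("sex", "")
    start = meta.get("band_start", "")
    band = CohortBand(
        meta.get("band", "all"),
        int(start) if start else None,
        int(meta["band_end"]) if "band_end" in meta else 9999,
    )
    try:
        return CohortLifeTable(sex, band, base_age, ages[keep], values[keep] / norm)
    except LifeTableFormatError as exc:
        raise LifeTableFormatError(f"{path}: {exc}") from None


def write_life_table_set(tables: LifeTableSet, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (sex, label), table in sorted(tables.items()):
        write_life_table(table, out / f"lifetable_{sex}_{label}.csv")
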