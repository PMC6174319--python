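"""The Family Longevity Selection Score (FLoSS) and its summaries.

Each score-eligible sibling contributes an exceedance u = -log S(attained
age | base age), where S is the sex- and birth-cohort-specific survival
conditional on the base age (default 40).  When lifespans are drawn from the
scoring table itself, u is unit-exponential, so the exceedance sum over k
deceased members has a Gamma(k, 1) null.  Each scored member's contribution
is centered at that null mean through a per-member size penalty (default
1.0), and a living member receives an alive bonus (default 1.0, the
conditional expectation of the eventual exceedance beyond the attained age
under the null), so the score rewards very old living family members:

    FLoSS = sum_i (u_i - size_penalty + alive_bonus * 1{alive_i}).

With the defaults a deceased member contributes u - 1 (null mean 0) and a
living member contributes u, so FLoSS is centered at zero for every sibship
size, is negative for families with unexceptional survival, and a raw
threshold of 7 sits roughly 2.5 null standard deviations out for typical
sibship sizes — a rare upper tail.  Setting ``size_penalty=0`` recovers a
plain non-negative exceedance sum.

Scores for record-age individuals whose tabulated survival has reached 0 are
truncated at the last strictly positive tabulated value, keeping them finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import (
    DegenerateSummaryError,
    EligibilityError,
    EmptySibshipError,
    TableMismatchError,
)
from .lifetables import CohortLifeTable, LifeTableSet, assign_cohort
from .pedigree import Individual, PedigreeSample, Sibship

log = logging.getLogger(__name__)

DEFAULT_ALIVE_BONUS = 1.0
DEFAULT_SIZE_PENALTY = 1.0


@dataclass
class IndividualScore:
    """One member's contribution: exceedance, bonus, and centered total.

    ``neg_log_survival`` is the raw exceedance u; ``total`` is the centered
    contribution u - size_penalty + bonus entering the sibship sum.
    """

    person_id: str
    attained_age: float
    alive_at_reference: bool
    neg_log_survival: float
    bonus: float
    total: float


@dataclass
class SibshipScore:
    sibship_id: str
    floss: float
    n_members_scored: int
    n_alive: int
    member_scores: list[IndividualScore] = field(default_factory=list)


@dataclass
class FlossSummary:
    """Mean and (sample) standard deviation of sibship FLoSS values."""

    mean: float
    sd: float
    n_sibships: int


def _status_at(
    ind: Individual, reference_year: int | None
) -> tuple[float, bool]:
    """(attained age, alive) either final or as of a reference year.

    As of a reference year: a person whose death (or last-alive) year falls
    after the year is treated as alive then, at age year - birth_year, even
    if they later died.  A person censored at or before the year contributes
    their last-alive age with unknown (hence not-alive) status.
    """
    if reference_year is None:
        age = ind.attained_age
        if age is None:
            raise EligibilityError(f"{ind.person_id}: no vital information")
        return float(age), ind.death_year is None
    if ind.death_year is not None and ind.death_year <= reference_year:
        return float(ind.death_year - ind.birth_year), False
    end = ind.end_year
    if end is None:
        raise EligibilityError(f"{ind.person_id}: no vital information")
    if end > reference_year:
        return float(reference_year - ind.birth_year), True
    return float(end - ind.birth_year), False


def individual_score(
    ind: Individual,
    table: CohortLifeTable,
    reference_year: int | None = None,
    alive_bonus: float = DEFAULT_ALIVE_BONUS,
    size_penalty: float = DEFAULT_SIZE_PENALTY,
) -> IndividualScore:
    """Score one person against their sex/cohort life table."""
    if table.sex and ind.sex != table.sex:
        raise TableMismatchError(
            f"{ind.person_id}: sex {ind.sex} scored against {table.sex} table"
        )
    if not table.band.contains(ind.birth_year):
        raise TableMismatchError(
            f"{ind.person_id}: birth year {ind.birth_year} outside table band "
            f"{table.band.label}"
        )
    attained, alive = _status_at(ind, reference_year)
    if attained < table.base_age:
        raise EligibilityError(
            f"{ind.person_id}: attained age {attained} below base age "
            f"{table.base_age}"
        )
    u = float(table.neg_log_survival_at(attained))
    bonus = alive_bonus if alive else 0.0
    return IndividualScore(
        person_id=ind.person_id,
        attained_age=attained,
        alive_at_reference=alive,
        neg_log_survival=u,
        bonus=bonus,
        total=u - size_penalty + bonus,
    )


def sibship_floss(
    sibship: Sibship,
    sample: PedigreeSample,
    tables: LifeTableSet,
    reference_year: int | None = None,
    alive_bonus: float = DEFAULT_ALIVE_BONUS,
    size_penalty: float = DEFAULT_SIZE_PENALTY,
) -> SibshipScore:
    """FLoSS for one sibship: the sum of eligible member contributions.

    Members ineligible as of the reference year (attained age below the base
    age at that year) are excluded from the sum.
    """
    member_scores: list[IndividualScore] = []
    for pid in sibship.member_ids:
        ind = sample[pid]
        table = tables.lookup(ind.sex, ind.birth_year)
        try:
            member_scores.append(
                individual_score(ind, table, reference_year, alive_bonus, size_penalty)
            )
        except EligibilityError:
            continue
    if not member_scores:
        raise EmptySibshipError(f"{sibship.sibship_id}: no scoreable member")
    return SibshipScore(
        sibship_id=sibship.sibship_id,
        floss=float(sum(s.total for s in member_scores)),
        n_members_scored=len(member_scores),
        n_alive=sum(s.alive_at_reference for s in member_scores),
        member_scores=member_scores,
    )


def score_sample(
    sample: PedigreeSample,
    tables: LifeTableSet,
    reference_year: int | None = None,
    alive_bonus: float = DEFAULT_ALIVE_BONUS,
    size_penalty: float = DEFAULT_SIZE_PENALTY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized scoring of a whole sample.

    Returns ``(members, sibships)``: a per-member frame (person_id,
    sibship_id, attained_age, alive, neg_log_survival, total) over eligible
    members, and a per-sibship frame (sibship_id, floss, n_members_scored,
    n_alive) sorted by sibship id.  Sibships with no eligible member as of
    the reference year are omitted (their count is logged).
    """
    df = sample.frame().copy()
    base_age = tables.base_age
    birth = df["birth_year"].to_numpy(dtype=float)
    death = df["death_year"].to_numpy(dtype=float)
    end = df["end_year"].to_numpy(dtype=float)
    if reference_year is None:
        attained = end - birth
        alive = np.isnan(death)
    else:
        dead_by = ~np.isnan(death) & (death <= reference_year)
        alive = ~dead_by & (end > reference_year)
        attained = np.where(
            dead_by, death - birth, np.where(alive, reference_year - birth, end - birth)
        )
    eligible = ~np.isnan(attained) & (attained >= base_age)

    u = np.full(len(df), np.nan)
    sexes = df["sex"].to_numpy()
    band_labels = np.array(
        [assign_cohort(int(b), tables.bands).label for b in birth], dtype=object
    )
    for (sex, label), table in tables.items():
        mask = eligible & (sexes == sex) & (band_labels == label)
        if mask.any():
            u[mask] = table.neg_log_survival_at(attained[mask])
    unmatched = eligible & np.isnan(u)
    if unmatched.any():
        raise TableMismatchError(
            f"{int(unmatched.sum())} eligible member(s) have no matching life table"
        )
    total = u - size_penalty + alive_bonus * alive

    members = pd.DataFrame(
        {
            "person_id": df["person_id"],
            "sibship_id": df["sibship_id"],
            "sex": df["sex"],
            "birth_year": df["birth_year"],
            "attained_age": attained,
            "alive": alive,
            "neg_log_survival": u,
            "total": total,
        }
    ).loc[eligible]
    sibs = (
        members.groupby("sibship_id", sort=True)
        .agg(
            floss=("total", "sum"),
            n_members_scored=("total", "size"),
            n_alive=("alive", "sum"),
        )
        .reset_index()
    )
    n_skipped = len(sample.sibships) - len(sibs)
    if n_skipped:
        log.info(
            "score_sample: %d sibship(s) had no eligible member and were skipped",
            n_skipped,
        )
    return members.reset_index(drop=True), sibs


def summarize_floss(scores) -> FlossSummary:
    """Sample mean and standard deviation of sibship FLoSS values.

    Accepts an iterable of :class:`SibshipScore`, a sibship frame from
    :func:`score_sample`, or a plain sequence of numbers.
    """
    values = _floss_values(scores)
    if values.size < 2:
        raise DegenerateSummaryError("need at least 2 sibships to summarize")
    sd = float(np.std(values, ddof=1))
    if sd <= 0:
        raise DegenerateSummaryError("FLoSS values have zero spread")
    return FlossSummary(mean=float(np.mean(values)), sd=sd, n_sibships=values.size)


def standardize_floss(score: float, summary: FlossSummary) -> float:
    """S-FLoSS = (FLoSS - M) / S."""
    if summary.sd <= 0:
        raise DegenerateSummaryError("standard deviation must be positive")
    return (score - summary.mean) / summary.sd


def select_sibships(scores, threshold: float, direction: str = "ge") -> list[str]:
    """Sibship ids whose FLoSS satisfies the threshold (boundary inclusive)."""
    if direction not in ("ge", "le"):
        raise ValueError("direction must be 'ge' or 'le'")
    ids, values = _floss_items(scores)
    values = np.asarray(values, dtype=float)
    mask = values >= threshold if direction == "ge" else values <= threshold
    return sorted(np.asarray(ids, dtype=object)[mask])


def write_scores(sibs: pd.DataFrame, path: str | Path) -> None:
    sibs.to_csv(path, index=False)


def _floss_items(scores) -> tuple[list, list]:
    if isinstance(scores, pd.DataFrame):
        return list(scores["sibship_id"]), list(scores["floss"])
    scores = list(scores)
    if scores and isinstance(scores[0], SibshipScore):
        return [s.sibship_id for s in scores], [s.floss for s in scores]
    raise TypeError("expected a sibship frame or SibshipScore objects")


def _floss_values(scores) -> np.ndarray:
    if isinstance(scores, pd.DataFrame):
        return scores["floss"].to_numpy(dtype=float)
    scores = list(scores)
    if scores and isinstance(scores[0], SibshipScore):
        return np.array([s.floss for s in scores], dtype=float)
    return np.asarray(scores, dtype=float)
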