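"""Orchestration of the three FLoSS validation analyses.

1. Whole-sample scoring: build conditional cohort life tables from the
   filtered sample, score every sibship, summarize and standardize the
   score distribution, and select high (FLoSS >= 7) and low (FLoSS <= -4.5)
   tails; survival of the born-after-1900 tails is compared conditional on
   age 80.
2. Cross-sectional study year (default 1980): recompute age and vital status
   at the study year, score sibships as of that year, split the living 80+
   population into 'exceptional' (sibship FLoSS >= threshold) and 'ordinary'
   groups, and compare their subsequent survival with a left-truncated
   Kaplan-Meier estimate and log-rank test, entry at the age in the study
   year.
3. Offspring comparison: offspring born after 1900 are 'exceptional' when at
   least one parent belongs to a sibship with FLoSS >= threshold, 'ordinary'
   when both parents' sibships score below it; survival past age 80 is
   compared the same way.

All group constructions partition the eligible population; the report
records counts, test results, and restricted-mean summaries per sex and
pooled.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import floss as floss_mod
from .errors import StudyConfigError
from .lifetables import build_life_tables, default_bands, write_life_table_set
from .pedigree import (
    SEXES,
    PedigreeSample,
    apply_inclusion_filters,
    apply_score_eligibility,
    derive_sibships,
    read_pedigree,
    write_pedigree,
)
from .simulate import SimParams, simulate_pedigrees
from .survival import (
    LogRankResult,
    SurvivalCurve,
    condition_curve,
    km_from_arrays,
    logrank_from_arrays,
    rmst,
)

log = logging.getLogger(__name__)

EXCEPTIONAL = "exceptional"
ORDINARY = "ordinary"
EXCLUDED = "excluded"


@dataclass
class StudyConfig:
    """Tunable parameters of the full study run."""

    study_year: int = 1980
    age_threshold: int = 80
    floss_threshold: float = 7.0
    anti_threshold: float = -4.5
    offspring_min_birth_year: int = 1900
    base_age: int = 40
    alive_bonus: float = 1.0
    size_penalty: float = 1.0
    max_birth_year: int = 1910
    rmst_horizon: int = 95
    seed: int = 0
    sibship_key: str = "full"
    group_score_mode: str = "complete"
    table_method: str = "product-limit"
    pedigree_path: str | None = None
    plot: bool = False
    sim: SimParams = field(default_factory=SimParams)

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimParams(**self.sim)
        self.validate()

    def validate(self) -> None:
        if self.age_threshold <= self.base_age:
            raise StudyConfigError("age_threshold must exceed base_age")
        for name in ("floss_threshold", "anti_threshold"):
            if not np.isfinite(getattr(self, name)):
                raise StudyConfigError(f"{name} must be finite")
        if self.rmst_horizon <= self.age_threshold:
            raise StudyConfigError("rmst_horizon must exceed age_threshold")
        if self.group_score_mode not in ("complete", "as-of-year"):
            raise StudyConfigError(
                "group_score_mode must be 'complete' or 'as-of-year'"
            )

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with Path(path).open(encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


@dataclass
class GroupAssignment:
    person_id: str
    group: str
    age_at_study_year: int | None
    alive_at_study_year: bool


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def prepare_sample(config: StudyConfig) -> PedigreeSample:
    """Load or simulate the pedigree, derive sibships, apply both filters."""
    if config.pedigree_path:
        sample = read_pedigree(config.pedigree_path)
    else:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        sample = simulate_pedigrees(sim)
    sample = derive_sibships(sample, key=config.sibship_key)
    sample = apply_inclusion_filters(sample, max_birth_year=config.max_birth_year)
    sample = apply_score_eligibility(sample, min_age=config.base_age)
    return sample


def cross_section_status(sample: PedigreeSample, year: int) -> pd.DataFrame:
    """Per-person vital status and age at a cross-sectional year.

    A person is alive at the year when their death (or last-known-alive)
    year falls strictly after it; age is year - birth_year.  People born
    after the year are excluded.
    """
    df = sample.frame()
    keep = df["birth_year"] <= year
    out = df.loc[keep, ["person_id", "sex", "birth_year", "end_year"]].copy()
    out["alive"] = out["end_year"] > year
    out["age"] = year - out["birth_year"]
    return out[["person_id", "sex", "alive", "age"]].reset_index(drop=True)


def build_groups_at_year(
    sample: PedigreeSample, sibship_scores: pd.DataFrame, config: StudyConfig
) -> pd.DataFrame:
    """Partition the living age-eligible population at the study year.

    Members of sibships whose as-of-year FLoSS meets the threshold form the
    exceptional group; every other living person at or above the age
    threshold is ordinary.  Returns one row per living age-eligible person.
    """
    year = config.study_year
    status = cross_section_status(sample, year)
    eligible = status.loc[status["alive"] & (status["age"] >= config.age_threshold)]
    if eligible.empty:
        raise StudyConfigError(
            f"no one alive and aged >= {config.age_threshold} in {year}"
        )
    floss_by_sib = dict(
        zip(sibship_scores["sibship_id"], sibship_scores["floss"])
    )
    rows = eligible.copy()
    rows["sibship_id"] = [sample.sibship_of(p) for p in rows["person_id"]]
    rows["floss"] = rows["sibship_id"].map(floss_by_sib)
    rows["group"] = np.where(
        rows["floss"].to_numpy(dtype=float) >= config.floss_threshold,
        EXCEPTIONAL,
        ORDINARY,
    )
    rows = rows.rename(columns={"age": "age_at_study_year"})
    # partition sanity: exceptional and ordinary are disjoint and exhaustive
    assert (rows["group"].isin([EXCEPTIONAL, ORDINARY])).all()
    return rows[
        ["person_id", "sex", "sibship_id", "floss", "group", "age_at_study_year"]
    ].reset_index(drop=True)


def offspring_groups(
    sample: PedigreeSample, sibship_scores: pd.DataFrame, config: StudyConfig
) -> pd.DataFrame:
    """Label offspring by their parents' sibship FLoSS.

    Offspring born after ``offspring_min_birth_year`` are 'exceptional' when
    either parent belongs to a sibship with FLoSS >= threshold, 'ordinary'
    when both parents' sibships score below it, and 'excluded' when a parent
    is unscored (not in the scored sample).
    """
    df = sample.frame()
    floss_by_sib = dict(zip(sibship_scores["sibship_id"], sibship_scores["floss"]))

    def parent_floss(pid: str | None) -> float | None:
        if pid is None or pid not in sample.individuals:
            return None
        return floss_by_sib.get(sample.sibship_of(pid))

    rows = df.loc[df["birth_year"] > config.offspring_min_birth_year].copy()
    groups = []
    for mid, fid in zip(rows["mother_id"], rows["father_id"]):
        fm, ff = parent_floss(mid), parent_floss(fid)
        if fm is None or ff is None:
            groups.append(EXCLUDED)
        elif max(fm, ff) >= config.floss_threshold:
            groups.append(EXCEPTIONAL)
        else:
            groups.append(ORDINARY)
    rows["group"] = groups
    return rows[["person_id", "sex", "birth_year", "group"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# group survival comparison
# ---------------------------------------------------------------------------

def _follow_up_arrays(sample: PedigreeSample, person_ids) -> tuple[np.ndarray, np.ndarray]:
    """(exit age, death observed) from final follow-up information."""
    exits = np.empty(len(person_ids), dtype=float)
    events = np.empty(len(person_ids), dtype=bool)
    for i, pid in enumerate(person_ids):
        ind = sample[pid]
        exits[i] = ind.attained_age
        events[i] = ind.is_deceased
    return exits, events


def _curve_stats(
    entry: np.ndarray,
    exit_: np.ndarray,
    event: np.ndarray,
    label: str,
    condition_age: float,
    horizon: float,
) -> dict:
    curve = km_from_arrays(entry, exit_, event, label)
    # every record enters at or after condition_age, so the estimate is 1 on
    # [condition_age, first entry) and conditioning there is well defined
    curve.start_age = min(curve.start_age, float(condition_age))
    cond = condition_curve(curve, condition_age)
    return {
        "n": int(entry.size),
        "n_events": int(event.sum()),
        "rmst": rmst(cond, condition_age, horizon),
        "curve": cond,
    }


def compare_groups(
    groups: pd.DataFrame,
    sample: PedigreeSample,
    condition_age: float,
    horizon: float,
    entry_col: str | None = None,
) -> dict:
    """Exceptional-vs-ordinary survival comparison past ``condition_age``.

    Records enter at their study-year age when ``entry_col`` is given
    (cross-sectional design) or at ``condition_age`` otherwise (complete
    follow-up conditioned on surviving past it); in both cases only records
    with exit after the conditioning age contribute.  Returns per-sex and
    pooled log-rank results, RMST(condition_age -> horizon) per group, and
    the conditional curves.
    """
    out: dict = {}
    for subset_label in list(SEXES) + ["pooled"]:
        sub = groups if subset_label == "pooled" else groups[groups["sex"] == subset_label]
        parts = {}
        arrays = {}
        for grp in (EXCEPTIONAL, ORDINARY):
            rows = sub[sub["group"] == grp]
            exits, events = _follow_up_arrays(sample, list(rows["person_id"]))
            if entry_col is not None:
                entry = rows[entry_col].to_numpy(dtype=float)
            else:
                entry = np.full(exits.size, float(condition_age))
            entry = np.maximum(entry, float(condition_age))
            keep = exits > entry
            entry, exits, events = entry[keep], exits[keep], events[keep]
            if entry.size == 0:
                parts = None
                break
            arrays[grp] = (entry, exits, events)
            parts[grp] = _curve_stats(
                entry, exits, events, grp, condition_age, horizon
            )
        if parts is None:
            out[subset_label] = None
            continue
        lr = logrank_from_arrays(*arrays[EXCEPTIONAL], *arrays[ORDINARY])
        out[subset_label] = {
            "groups": parts,
            "logrank": lr,
            "rmst_gap": parts[EXCEPTIONAL]["rmst"] - parts[ORDINARY]["rmst"],
        }
    return out


def _comparison_summary(comp: dict) -> dict:
    summary = {}
    for key, res in comp.items():
        if res is None:
            summary[key] = None
            continue
        summary[key] = {
            "n_exceptional": res["groups"][EXCEPTIONAL]["n"],
            "n_ordinary": res["groups"][ORDINARY]["n"],
            "events_exceptional": res["groups"][EXCEPTIONAL]["n_events"],
            "events_ordinary": res["groups"][ORDINARY]["n_events"],
            "rmst_exceptional": res["groups"][EXCEPTIONAL]["rmst"],
            "rmst_ordinary": res["groups"][ORDINARY]["rmst"],
            "rmst_gap": res["rmst_gap"],
            "logrank_statistic": res["logrank"].statistic,
            "logrank_p": res["logrank"].p_value,
        }
    return summary


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full pipeline; optionally write the report tree to ``out_dir``.

    Deterministic given ``config.seed``: rerunning with the same
    configuration reproduces every output byte for byte.
    """
    bands = default_bands(end_year=config.max_birth_year)
    raw = (
        read_pedigree(config.pedigree_path)
        if config.pedigree_path
        else simulate_pedigrees(dataclasses.replace(config.sim, seed=config.seed))
    )
    n_raw = len(raw)
    sample = derive_sibships(raw, key=config.sibship_key)
    included = apply_inclusion_filters(sample, max_birth_year=config.max_birth_year)
    n_included = len(included)
    eligible = apply_score_eligibility(included, min_age=config.base_age)

    tables = build_life_tables(
        eligible, bands, base_age=config.base_age, method=config.table_method
    )

    # --- whole-sample scoring and tail selection ---------------------------
    members, sibs = floss_mod.score_sample(
        eligible,
        tables,
        reference_year=None,
        alive_bonus=config.alive_bonus,
        size_penalty=config.size_penalty,
    )
    summary = floss_mod.summarize_floss(sibs)
    selected_high = floss_mod.select_sibships(sibs, config.floss_threshold, "ge")
    selected_low = floss_mod.select_sibships(sibs, config.anti_threshold, "le")
    sibs = sibs.assign(
        s_floss=[floss_mod.standardize_floss(v, summary) for v in sibs["floss"]]
    )

    post1900 = members.loc[members["birth_year"] > config.offspring_min_birth_year]
    share_high = float(
        post1900["sibship_id"].isin(selected_high).mean()
    ) if len(post1900) else float("nan")
    share_low = float(
        post1900["sibship_id"].isin(selected_low).mean()
    ) if len(post1900) else float("nan")

    # --- study-year comparison ---------------------------------------------
    # group membership follows the whole-sample (complete-lifespan) FLoSS by
    # default; 'as-of-year' rescores every sibship with information available
    # at the study year instead
    if config.group_score_mode == "as-of-year":
        _, group_scores = floss_mod.score_sample(
            eligible,
            tables,
            reference_year=config.study_year,
            alive_bonus=config.alive_bonus,
            size_penalty=config.size_penalty,
        )
    else:
        group_scores = sibs
    groups_year = build_groups_at_year(eligible, group_scores, config)
    comp_year = compare_groups(
        groups_year,
        eligible,
        condition_age=float(config.age_threshold),
        horizon=float(config.rmst_horizon),
        entry_col="age_at_study_year",
    )

    # --- offspring comparison ----------------------------------------------
    groups_off = offspring_groups(eligible, sibs, config)
    comp_off = compare_groups(
        groups_off,
        eligible,
        condition_age=float(config.age_threshold),
        horizon=float(config.rmst_horizon),
    )

    year_summary = _comparison_summary(comp_year)
    off_summary = _comparison_summary(comp_off)
    n80 = len(groups_year)
    report = {
        "config": _jsonable(config.to_dict()),
        "sample": {
            "n_raw": n_raw,
            "n_after_inclusion": n_included,
            "n_score_eligible": len(eligible),
            "n_sibships_scored": int(len(sibs)),
        },
        "floss": {
            "mean": summary.mean,
            "sd": summary.sd,
            "n_sibships": summary.n_sibships,
            "n_selected_high": len(selected_high),
            "n_selected_low": len(selected_low),
            "share_members_high_post1900": share_high,
            "share_members_low_post1900": share_low,
        },
        "study_year": {
            "year": config.study_year,
            "n_alive_age_eligible": n80,
            "n_exceptional": int((groups_year["group"] == EXCEPTIONAL).sum()),
            "n_ordinary": int((groups_year["group"] == ORDINARY).sum()),
            "comparison": year_summary,
        },
        "offspring": {
            "n_exceptional": int((groups_off["group"] == EXCEPTIONAL).sum()),
            "n_ordinary": int((groups_off["group"] == ORDINARY).sum()),
            "n_excluded": int((groups_off["group"] == EXCLUDED).sum()),
            "comparison": off_summary,
        },
        "attenuation": {
            "index_rmst_gap_pooled": year_summary["pooled"]["rmst_gap"]
            if year_summary.get("pooled")
            else None,
            "offspring_rmst_gap_pooled": off_summary["pooled"]["rmst_gap"]
            if off_summary.get("pooled")
            else None,
        },
    }
    assert (
        report["study_year"]["n_exceptional"] + report["study_year"]["n_ordinary"]
        == n80
    ), "study-year groups must partition the living age-eligible population"

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_life_table_set(tables, out / "lifetables")
        sibs.to_csv(out / "sibship_scores.csv", index=False)
        members.to_csv(out / "member_scores.csv", index=False)
        groups_year.to_csv(out / "groups_study_year.csv", index=False)
        groups_off.to_csv(out / "groups_offspring.csv", index=False)
        _write_curves(out / "curves", "study_year", comp_year)
        _write_curves(out / "curves", "offspring", comp_off)
        with (out / "report.json").open("w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        if config.plot:
            from .plotting import plot_comparison

            plot_comparison(comp_year, out / "fig_study_year.png",
                            title=f"Survival from age {config.age_threshold}, "
                                  f"study year {config.study_year}")
            plot_comparison(comp_off, out / "fig_offspring.png",
                            title=f"Offspring survival from age {config.age_threshold}")
    return report


def _write_curves(curve_dir: Path, analysis: str, comp: dict) -> None:
    curve_dir.mkdir(parents=True, exist_ok=True)
    for subset, res in comp.items():
        if res is None:
            continue
        for grp, stats in res["groups"].items():
            stats["curve"].to_frame().to_csv(
                curve_dir / f"{analysis}_{subset}_{grp}.csv", index=False
            )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
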