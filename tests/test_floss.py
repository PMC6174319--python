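"""FLoSS scoring: member contributions, sibship sums, summaries, selection."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from flosskit import (
    CohortBand,
    CohortLifeTable,
    DegenerateSummaryError,
    EligibilityError,
    EmptySibshipError,
    FlossSummary,
    LifeTableSet,
    PedigreeSample,
    Sibship,
    SibshipScore,
    TableMismatchError,
    derive_sibships,
    gompertz_life_table,
    individual_score,
    score_sample,
    select_sibships,
    sibship_floss,
    simulate_null_from_table,
    standardize_floss,
    summarize_floss,
)

from conftest import make_individual

BAND = CohortBand("1850-1859", 1850, 1859)


def table_with(survival_by_age: dict[int, float], sex="F") -> CohortLifeTable:
    ages = np.arange(40, max(survival_by_age) + 1)
    surv = np.ones(ages.size)
    s = 1.0
    for i, a in enumerate(ages):
        s = survival_by_age.get(int(a), s)
        surv[i] = s
    return CohortLifeTable(sex, BAND, 40, ages, surv)


# ---------------------------------------------------------------------------
# individual scores
# ---------------------------------------------------------------------------

def test_deceased_at_base_age_scores_minus_penalty():
    table = table_with({80: 0.5})
    ind = make_individual("a", "F", 1855, 1895)  # died at exactly 40, S=1
    score = individual_score(ind, table)
    assert score.neg_log_survival == pytest.approx(0.0)
    assert score.total == pytest.approx(-1.0)  # u - size_penalty
    assert individual_score(ind, table, size_penalty=0.0).total == pytest.approx(0.0)


def test_deceased_exceedance_is_neg_log_survival():
    table = table_with({70: 0.1})
    ind = make_individual("a", "F", 1855, 1925)  # died at 70, S=0.1
    score = individual_score(ind, table)
    assert score.neg_log_survival == pytest.approx(-math.log(0.1), abs=1e-4)
    assert score.total == pytest.approx(2.302585 - 1.0, abs=1e-4)
    assert not score.alive_at_reference and score.bonus == 0.0


def test_living_member_receives_alive_bonus():
    table = table_with({70: 0.1})
    ind = make_individual("a", "F", 1855, None, last_alive=1925)  # alive at 70
    score = individual_score(ind, table)
    assert score.bonus == 1.0
    assert score.total == pytest.approx(2.302585, abs=1e-4)  # u - 1 + 1
    uncentered = individual_score(ind, table, size_penalty=0.0)
    assert uncentered.total == pytest.approx(3.302585, abs=1e-4)  # u + 1


def test_score_truncated_where_survival_reaches_zero():
    table = table_with({70: 0.01, 75: 0.0})
    ind = make_individual("a", "F", 1855, 1965)  # died at 110, beyond support
    score = individual_score(ind, table)
    assert score.neg_log_survival == pytest.approx(-math.log(0.01), abs=1e-9)
    assert np.isfinite(score.total)


def test_score_monotone_in_attained_age():
    table = gompertz_life_table(1e-4, np.log(2) / 8, sex="F", band=BAND)
    totals = [
        individual_score(make_individual("a", "F", 1855, 1855 + age), table).total
        for age in range(40, 110, 5)
    ]
    assert all(b >= a - 1e-12 for a, b in zip(totals, totals[1:]))


def test_table_mismatch_and_eligibility_errors():
    table = table_with({70: 0.1})
    with pytest.raises(TableMismatchError):
        individual_score(make_individual("a", "M", 1855, 1925), table)
    with pytest.raises(TableMismatchError):
        individual_score(make_individual("a", "F", 1870, 1940), table)
    with pytest.raises(EligibilityError):
        individual_score(make_individual("a", "F", 1855, 1890), table)  # age 35


def test_reference_year_recomputes_age_and_vital_status():
    table = table_with({60: 0.5, 70: 0.1})
    # died in 1930 at 75, but alive at the 1915 reference aged 60
    ind = make_individual("a", "F", 1855, 1930)
    score = individual_score(ind, table, reference_year=1915)
    assert score.alive_at_reference
    assert score.attained_age == 60
    assert score.total == pytest.approx(-math.log(0.5), abs=1e-9)  # u - 1 + 1
    # censored before the reference year: exceedance at last-alive age, no bonus
    cens = make_individual("b", "F", 1855, None, last_alive=1915)
    s2 = individual_score(cens, table, reference_year=1925)
    assert not s2.alive_at_reference
    assert s2.attained_age == 60
    assert s2.total == pytest.approx(-math.log(0.5) - 1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# sibship scores
# ---------------------------------------------------------------------------

def _mini_family(s_by_age, statuses):
    """Sibship of len(statuses) members with chosen death/alive ages."""
    inds = [
        make_individual("PF", "M", 1830, 1900),
        make_individual("PM", "F", 1832, 1905),
    ]
    for i, (age, died) in enumerate(statuses):
        inds.append(
            make_individual(
                f"k{i}",
                "F",
                1855,
                1855 + age if died else None,
                last_alive=None if died else 1855 + age,
                mother_id="PM",
                father_id="PF",
            )
        )
    sample = derive_sibships(PedigreeSample(inds))
    tables = LifeTableSet({("F", BAND.label): table_with(s_by_age)}, [BAND])
    sid = sample.sibship_of("k0")
    return sample.sibships[sid], sample, tables


def test_sibship_floss_sums_member_exceedances():
    """Deceased members with S = 0.05, 0.0735, 0.5: the exceedance sum is
    2.9957 + 2.6104 + 0.6931 = 6.2992, and FLoSS subtracts one per member."""
    s_by_age = {61: 0.5, 75: 0.0735, 80: 0.05}
    sib, sample, tables = _mini_family(
        s_by_age, [(80, True), (75, True), (61, True)]
    )
    score = sibship_floss(sib, sample, tables)
    exceedance = sum(m.neg_log_survival for m in score.member_scores)
    assert exceedance == pytest.approx(
        -np.log(0.05) - np.log(0.0735) - np.log(0.5), abs=1e-6
    )
    assert score.floss == pytest.approx(exceedance - 3.0, abs=1e-9)
    assert score.n_members_scored == 3 and score.n_alive == 0


def test_sibship_floss_invariant_to_member_order():
    s_by_age = {61: 0.5, 75: 0.2, 80: 0.05}
    sib, sample, tables = _mini_family(
        s_by_age, [(80, True), (75, False), (61, True)]
    )
    forward = sibship_floss(sib, sample, tables)
    sib.member_ids.reverse()
    backward = sibship_floss(sib, sample, tables)
    assert forward.floss == pytest.approx(backward.floss)
    assert forward.n_alive == backward.n_alive == 1


def test_sibship_with_no_scoreable_member_errors():
    sib, sample, tables = _mini_family({80: 0.5}, [(30, True)])
    with pytest.raises(EmptySibshipError):
        sibship_floss(sib, sample, tables)


def test_bulk_scoring_matches_per_sibship_scoring(eligible_sample):
    from flosskit import build_life_tables

    tables = build_life_tables(eligible_sample)
    members, sibs = score_sample(eligible_sample, tables)
    by_id = dict(zip(sibs["sibship_id"], sibs["floss"]))
    rng = np.random.default_rng(0)
    ids = rng.choice(sibs["sibship_id"], size=25, replace=False)
    for sid in ids:
        direct = sibship_floss(eligible_sample.sibships[sid], eligible_sample, tables)
        assert direct.floss == pytest.approx(by_id[sid], abs=1e-9)


# ---------------------------------------------------------------------------
# summaries, standardization, selection
# ---------------------------------------------------------------------------

def _scores(values):
    return [SibshipScore(f"s{i}", v, 1, 0) for i, v in enumerate(values)]


def test_summarize_mean_and_sample_sd():
    summary = summarize_floss(_scores([1.0, 3.0]))
    assert summary.mean == pytest.approx(2.0)
    assert summary.sd == pytest.approx(math.sqrt(2), abs=1e-6)
    assert summary.n_sibships == 2


def test_summarize_degenerate_inputs():
    with pytest.raises(DegenerateSummaryError):
        summarize_floss(_scores([1.0]))
    with pytest.raises(DegenerateSummaryError):
        summarize_floss(_scores([0.0, 0.0, 0.0]))


def test_standardize_floss_matches_reported_arithmetic():
    """With the reported distribution M = -0.234, S = 2.9 the selection
    threshold 7 standardizes to 2.4945."""
    summary = FlossSummary(mean=-0.234, sd=2.9, n_sibships=57192)
    assert standardize_floss(7.0, summary) == pytest.approx(2.4945, abs=1e-4)
    assert standardize_floss(summary.mean, summary) == 0.0
    assert standardize_floss(summary.mean + summary.sd, summary) == pytest.approx(1.0)


def test_select_sibships_boundary_inclusive_both_directions():
    scores = _scores([6.9, 7.0, 7.1])
    assert select_sibships(scores, 7.0, "ge") == ["s1", "s2"]
    low = _scores([-5.0, 0.0])
    assert select_sibships(low, -4.5, "le") == ["s0"]
    assert select_sibships(scores, -100.0, "ge") == ["s0", "s1", "s2"]
    df = pd.DataFrame({"sibship_id": ["a", "b"], "floss": [7.0, 1.0]})
    assert select_sibships(df, 7.0, "ge") == ["a"]


# ---------------------------------------------------------------------------
# null calibration (table-sampled lifespans)
# ---------------------------------------------------------------------------

def test_null_exceedance_is_unit_exponential():
    """Lifespans drawn from the scoring table itself make u = -log S(T)
    unit-exponential: mean 1, and memorylessness gives the +1 alive bonus."""
    table = gompertz_life_table(1e-4, np.log(2) / 8, sex="F", band=BAND)
    draws = simulate_null_from_table(table, 20_000, seed=2)
    u = table.neg_log_survival_at(draws)
    assert np.mean(u) == pytest.approx(1.0, abs=0.03)
    # E[u(T) | T > a] = u(a) + 1 for any conditioning age a
    for a in (60.0, 80.0):
        tail = u[draws > a]
        assert tail.mean() == pytest.approx(
            float(table.neg_log_survival_at(a)) + 1.0, abs=4 * tail.std() / len(tail) ** 0.5
        )


def test_selection_enriches_low_frailty_families(eligible_sample, sim_sample):
    """Sibships passing the threshold carry below-average simulated frailty
    (lower hazard), the property the selection score exists to deliver."""
    from flosskit import build_life_tables

    tables = build_life_tables(eligible_sample)
    _, sibs = score_sample(eligible_sample, tables)
    # enrich threshold: upper 5% of this small sample
    thr = float(np.quantile(sibs["floss"], 0.95))
    chosen = set(select_sibships(sibs, thr, "ge"))
    truth = dict(zip(sim_sample.truth["person_id"], sim_sample.truth["frailty"]))
    sel, rest = [], []
    for sid, sib in eligible_sample.sibships.items():
        bucket = sel if sid in chosen else rest
        bucket.extend(truth[p] for p in sib.member_ids)
    assert np.mean(sel) < np.mean(rest)
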