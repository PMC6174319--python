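"""Shared fixtures: small hand-built pedigrees and a simulated sample."""

from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from flosskit import (
    Individual,
    PedigreeSample,
    SimParams,
    apply_inclusion_filters,
    apply_score_eligibility,
    derive_sibships,
    simulate_pedigrees,
)


def make_individual(pid, sex="F", birth=1860, death=1930, last_alive=None, **kw):
    return Individual(
        person_id=pid,
        sex=sex,
        birth_year=birth,
        death_year=death,
        last_alive_year=last_alive,
        **kw,
    )


@pytest.fixture
def toy_sample() -> PedigreeSample:
    """Two full sibships (with recorded parents) plus one singleton.

    Parents P* carry vital years so the inclusion filters keep the sibships.
    """
    parents = [
        make_individual("P1", "M", 1830, 1900),
        make_individual("P2", "F", 1835, 1905),
        make_individual("P3", "M", 1832, 1890),
        make_individual("P4", "F", 1838, 1910),
    ]
    kids = [
        make_individual("K1", "F", 1860, 1935, mother_id="P2", father_id="P1"),
        make_individual("K2", "M", 1862, 1940, mother_id="P2", father_id="P1"),
        make_individual("K3", "F", 1864, None, last_alive=1950,
                        mother_id="P2", father_id="P1"),
        make_individual("K4", "M", 1866, 1938, mother_id="P4", father_id="P3"),
        make_individual("K5", "F", 1868, 1960, mother_id="P4", father_id="P3"),
        make_individual("S1", "M", 1870, 1945),
    ]
    return derive_sibships(PedigreeSample(parents + kids, provenance="toy"))


@pytest.fixture(scope="session")
def sim_sample() -> PedigreeSample:
    """A small deterministic simulated pedigree (raw, unfiltered)."""
    return simulate_pedigrees(SimParams(n_families=400, seed=11))


@pytest.fixture(scope="session")
def eligible_sample(sim_sample) -> PedigreeSample:
    """The simulated pedigree after sibship derivation and both filters."""
    s = derive_sibships(sim_sample)
    s = apply_inclusion_filters(s, max_birth_year=1910)
    return apply_score_eligibility(s, min_age=40)
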