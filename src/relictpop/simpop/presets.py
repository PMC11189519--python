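"""Built-in desk-scaled demographic scenarios.

Every preset keeps Ne <= 500 and inflates mu and r so that 4*Ne*mu and
4*Ne*r match the larger populations they stand in for; event times are
scaled by the same factor as Ne, preserving their ratios (e.g. the relict
island's crash/re-expansion times keep their 10:3 ratio).
"""

from __future__ import annotations

from relictpop.simpop.demography import DemographyModel, PopulationSpec, default_layout

__all__ = ["preset_scenario", "PRESET_NAMES"]

PRESET_NAMES = (
    "neutral_equilibrium",
    "two_deme_island",
    "domestication_series",
    "island_relict",
    "full_cohort",
)


def preset_scenario(name: str, **overrides) -> DemographyModel:
    """Return a named built-in :class:`DemographyModel`.

    Overrides (``mu``, ``recomb_rate``, ``selfing_rate``, and preset-specific
    knobs such as ``nm`` or ``n_demes``) are applied where meaningful.
    """
    builders = {
        "neutral_equilibrium": _neutral_equilibrium,
        "two_deme_island": _two_deme_island,
        "domestication_series": _domestication_series,
        "island_relict": _island_relict,
        "full_cohort": _full_cohort,
    }
    if name not in builders:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    return builders[name](**overrides)


def _neutral_equilibrium(ne: int = 100, mu: float = 2.5e-5, recomb_rate: float = 2.5e-5,
                         selfing_rate: float = 0.0) -> DemographyModel:
    """Single panmictic population at mutation-drift equilibrium."""
    return DemographyModel(
        populations=[PopulationSpec("wild", [(None, ne)], selfing_rate=selfing_rate)],
        mu=mu,
        recomb_rate=recomb_rate,
    )


def _two_deme_island(nm: float = 1.0, ne: int = 50, n_demes: int = 8,
                     mu: float = 5e-5, recomb_rate: float = 5e-5) -> DemographyModel:
    """Island model for the Fst check: two focal demes embedded in a ring of
    ``n_demes`` equal islands exchanging ``nm`` migrant individuals per deme
    per generation.

    Sampling two demes out of many makes the classic infinite-island
    expectation Fst ~ 1/(1 + 4*N*m) hold to good approximation; with
    exactly two demes in the whole world the equilibrium would instead be
    1/(1 + 8*N*m).
    """
    m_total = nm / ne
    pops = [PopulationSpec(f"deme{i}", [(None, ne)]) for i in range(n_demes)]
    migration = {}
    rate = m_total / (n_demes - 1)
    for i in range(n_demes):
        for j in range(n_demes):
            if i != j:
                migration[(f"deme{i}", f"deme{j}")] = rate
    return DemographyModel(populations=pops, migration=migration, mu=mu,
                           recomb_rate=recomb_rate)


def _domestication_series(mu: float = 2.5e-5, recomb_rate: float = 2.5e-5) -> DemographyModel:
    """Wild source population with two serially bottlenecked landraces and a
    twice-bottlenecked cultivar; expected diversity ordering
    wild > landraces > cultivar."""
    return DemographyModel(
        populations=[
            PopulationSpec("wild", [(None, 100)]),
            PopulationSpec("LR1", [(None, 25)], source="wild", split_time=50),
            PopulationSpec("LR2", [(None, 25)], source="wild", split_time=50),
            PopulationSpec("cultivar", [(None, 8)], source="LR1", split_time=25),
        ],
        mu=mu,
        recomb_rate=recomb_rate,
    )


def _island_relict(mu: float = 1.25e-5, recomb_rate: float = 1.25e-5,
                   selfing_rate: float = 0.0) -> DemographyModel:
    """Isolated island deme: long-term size 200, ancient crash to 8,
    re-expansion to 200, and a recent decline to 50.

    Crash and re-expansion times (80 and 24 generations ago) keep the 10:3
    ratio of the 10,000/3,000-generation history they are scaled from.
    Expected signatures: negative genome-average Tajima's D and a
    singleton-enriched folded SFS.
    """
    return DemographyModel(
        populations=[
            PopulationSpec(
                "MK",
                [(None, 200), (80, 8), (24, 200), (8, 50)],
                selfing_rate=selfing_rate,
            )
        ],
        mu=mu,
        recomb_rate=recomb_rate,
    )


def _full_cohort(mu: float = 2.5e-5, recomb_rate: float = 2.5e-5,
                 selfing_rate: float = 0.4) -> DemographyModel:
    """Six-group cohort emulation: wild source, deep-split outgroup, an
    isolated island deme ("MK") that diverges unseen by the wild sample,
    two landraces, and a cultivar; partial selfing everywhere in the
    ingroup induces positive F_IS."""
    return DemographyModel(
        populations=[
            PopulationSpec("wild", [(None, 100)], selfing_rate=selfing_rate),
            PopulationSpec("outgroup", [(None, 50)], source="wild", split_time=600),
            PopulationSpec("MK", [(None, 30)], selfing_rate=selfing_rate,
                           source="wild", split_time=200),
            PopulationSpec("LR1", [(None, 25)], selfing_rate=selfing_rate,
                           source="wild", split_time=50),
            PopulationSpec("LR2", [(None, 25)], selfing_rate=selfing_rate,
                           source="wild", split_time=50),
            PopulationSpec("cultivar", [(None, 12)], selfing_rate=selfing_rate,
                           source="LR1", split_time=25),
        ],
        mu=mu,
        recomb_rate=recomb_rate,
        layout=default_layout(),
    )


#: default per-population diploid sample sizes for the full cohort
FULL_COHORT_SAMPLES = {
    "MK": 25,
    "wild": 10,
    "LR1": 10,
    "LR2": 10,
    "cultivar": 10,
    "outgroup": 2,
}
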