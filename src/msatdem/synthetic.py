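"""Synthetic fixture datasets with known ground truth.

Generates genotype datasets with the statistical structure of the Canary
Islands blue tit study system — a diverse mainland source, serially
bottlenecked island populations with pronounced fixation and private
alleles, Z-linked loci, and locus-specific amplification failure — so
every pipeline stage is testable without any external data.

The fixture demography is an invented mainland-source / island-bottleneck
scenario (documented in the package's methods note); drift intensities
are chosen so pairwise F_ST spans roughly 0.02–0.6.  No fixture value is
claimed to reproduce any empirical statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .coalsim import MutationModel, SampleConfig, simulate_dataset
from .demography import (
    MERGE,
    DemographicEvent,
    ParameterDraw,
    PriorSpec,
    Scenario,
)
from .genepop import AUTOSOMAL, Dataset, LocusDef, Z_LINKED

#: populations in study order with (sample size, fraction-male rounding up)
PAPER_SAMPLE_SIZES: dict[str, int] = {
    "Sweden": 20,
    "Spain": 22,
    "ElHierro": 13,
    "LaPalma": 24,
    "LaGomera": 21,
    "Tenerife": 25,
    "GranCanaria": 22,
    "Fuerteventura": 20,
    "Lanzarote": 17,
    "NorthAfrica": 22,
}

AFROCANARIAN = [
    "ElHierro",
    "LaPalma",
    "LaGomera",
    "Tenerife",
    "GranCanaria",
    "Fuerteventura",
    "Lanzarote",
    "NorthAfrica",
]


def paper_shape_loci() -> list[LocusDef]:
    """21 microsatellite loci: 4 Z-linked, three multi-locus linkage groups
    plus unlinked loci, with map positions such that 10 cM thinning of the
    19 working loci keeps 14."""
    return [
        # linkage group LG1b
        LocusDef("Cdi31-ZFM", AUTOSOMAL, "LG1b", 0.0),
        LocusDef("CcaTgu28", AUTOSOMAL, "LG1b", 5.0),
        LocusDef("Tgu5", AUTOSOMAL, "LG1b", 9.0),
        LocusDef("CcaTgu19", AUTOSOMAL, "LG1b", 14.0),
        # linkage group LG2
        LocusDef("Ase18", AUTOSOMAL, "LG2", 0.0),
        LocusDef("PK11", AUTOSOMAL, "LG2", 4.0),
        LocusDef("PK12", AUTOSOMAL, "LG2", 8.0),
        LocusDef("CcaTgu21", AUTOSOMAL, "LG2", 12.0),
        LocusDef("Mcyu4", AUTOSOMAL, "LG2", 20.0),
        # Z chromosome
        LocusDef("Ase46-ZFM", Z_LINKED, "LGZ", 0.0),
        LocusDef("CcaTgu31", Z_LINKED, "LGZ", 12.0),
        LocusDef("TGZ-040", Z_LINKED, "LGZ", 24.0),
        LocusDef("Phtr3", Z_LINKED, "LGZ", 37.0),
        # unlinked
        LocusDef("Pdou5", AUTOSOMAL),
        LocusDef("ApCo46-ZEST", AUTOSOMAL),
        LocusDef("LS2", AUTOSOMAL),
        LocusDef("PmaTGAn42", AUTOSOMAL),
        LocusDef("TG02-088", AUTOSOMAL),
        LocusDef("Titgata02", AUTOSOMAL),
        LocusDef("Tgu9", AUTOSOMAL),
        LocusDef("Pca8", AUTOSOMAL),
    ]


def fixture_scenario() -> tuple[Scenario, ParameterDraw]:
    """The invented drift-heavy island scenario used by the fixtures.

    A large, diverse European/North African background with island
    populations of small effective size that split a few hundred to a few
    thousand generations ago; drift intensity t/2N per island spans
    ~0.05 to ~1, giving fixation, private alleles and strong pairwise
    differentiation.
    """
    sizes = {
        "Sweden": 10_000.0,
        "Spain": 10_000.0,
        "ElHierro": 500.0,
        "LaPalma": 1_000.0,
        "LaGomera": 800.0,
        "Tenerife": 2_500.0,
        "GranCanaria": 1_200.0,
        "Fuerteventura": 900.0,
        "Lanzarote": 500.0,
        "NorthAfrica": 8_000.0,
    }
    times = {
        "t_eur": 800.0,         # Spain/Sweden
        "t_hierro": 1_000.0,    # ElHierro from LaPalma branch
        "t_west": 2_000.0,      # LaPalma branch joins central ancestor
        "t_central": 1_500.0,   # LaGomera, GranCanaria from Tenerife branch
        "t_lanz": 700.0,        # Lanzarote from Fuerteventura
        "t_east": 1_200.0,      # Fuerteventura joins North Africa
        "t_canary": 3_000.0,    # archipelago ancestor joins North Africa
        "t_root": 19_000.0,     # Afrocanarian clade joins Europe
    }
    events = [
        DemographicEvent(MERGE, "t_lanz", derived="Lanzarote", ancestor="Fuerteventura"),
        DemographicEvent(MERGE, "t_hierro", derived="ElHierro", ancestor="LaPalma"),
        DemographicEvent(MERGE, "t_east", derived="Fuerteventura", ancestor="NorthAfrica"),
        DemographicEvent(MERGE, "t_central", derived="LaGomera", ancestor="Tenerife"),
        DemographicEvent(MERGE, "t_central", derived="GranCanaria", ancestor="Tenerife"),
        DemographicEvent(MERGE, "t_west", derived="LaPalma", ancestor="Tenerife"),
        DemographicEvent(MERGE, "t_eur", derived="Spain", ancestor="Sweden"),
        DemographicEvent(MERGE, "t_canary", derived="Tenerife", ancestor="NorthAfrica"),
        DemographicEvent(MERGE, "t_root", derived="NorthAfrica", ancestor="Sweden"),
    ]
    # every symbol priced by a degenerate-width-avoiding prior around its value
    priors = [
        PriorSpec(f"N_{p}", v * 0.999, v * 1.001) for p, v in sizes.items()
    ] + [PriorSpec(sym, v * 0.999, v * 1.001) for sym, v in times.items()]
    scenario = Scenario(
        id="fixture-islands",
        populations={p: f"N_{p}" for p in sizes},
        events=events,
        priors=priors,
        note="invented fixture demography (mainland source, island bottlenecks)",
    )
    values = {f"N_{p}": v for p, v in sizes.items()} | dict(times)
    return scenario, ParameterDraw(values, scenario.id)


@dataclass
class FixtureSpec:
    """Ground truth and generation plan for a synthetic fixture."""

    sample_sizes: dict[str, int]
    loci: list[LocusDef]
    scenario: Scenario
    draw: ParameterDraw
    mutation: MutationModel
    failure_plan: dict[str, list[str]]
    seed: int


def _sample_config(sample_sizes: Mapping[str, int]) -> SampleConfig:
    # males rounded up: Z-linked statistics need diploid males
    return SampleConfig(
        {p: ((n + 1) // 2, n // 2) for p, n in sample_sizes.items()}
    )


def inject_amplification_failure(
    d: Dataset, plan: Mapping[str, Sequence[str]]
) -> Dataset:
    """Set all calls at each named locus to missing within the named
    populations; every other cell is untouched."""
    out = d.copy()
    for locus_name, pops in plan.items():
        j = out.locus_index(locus_name)
        for pop in pops:
            mask = out.population_mask(pop)
            if not mask.any():
                raise KeyError(f"population {pop!r} not in dataset")
            out.alleles[mask, j, :] = 0
    return out


def known_truth_dataset(
    scenario: Scenario,
    draw: ParameterDraw,
    config: SampleConfig,
    seed: int,
    loci: Sequence[LocusDef] | None = None,
    mut: MutationModel | None = None,
) -> tuple[Dataset, dict]:
    """Simulate a dataset and return it with its full generating truth."""
    if loci is None:
        loci = [LocusDef(f"L{i + 1:02d}") for i in range(10)]
    if mut is None:
        mut = MutationModel(mean_rate=5e-4, range_bound=40)
    data = simulate_dataset(scenario, draw, config, loci, mut, seed)
    truth = {
        "scenario": scenario.id,
        "parameters": dict(draw.values),
        "mutation_rate": mut.mean_rate,
        "seed": seed,
    }
    return data, truth


def paper_shape_fixture(seed: int) -> tuple[Dataset, FixtureSpec]:
    """A 206-individual, 10-population, 21-locus fixture.

    Sample sizes follow the study layout; genotypes are simulated under
    the drift-heavy island scenario; loci ``Tgu9`` (all Afrocanarian
    populations) and ``Pca8`` (La Palma) are masked to mimic
    amplification failure, so the failed-locus filter retains 19 loci.
    """
    scenario, draw = fixture_scenario()
    loci = paper_shape_loci()
    mut = MutationModel(mean_rate=1e-4, model="smm", range_bound=40)
    config = _sample_config(PAPER_SAMPLE_SIZES)
    data = simulate_dataset(scenario, draw, config, loci, mut, seed)
    plan = {"Tgu9": list(AFROCANARIAN), "Pca8": ["LaPalma"]}
    data = inject_amplification_failure(data, plan)
    spec = FixtureSpec(
        sample_sizes=dict(PAPER_SAMPLE_SIZES),
        loci=loci,
        scenario=scenario,
        draw=draw,
        mutation=mut,
        failure_plan={k: list(v) for k, v in plan.items()},
        seed=seed,
    )
    return data, spec
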