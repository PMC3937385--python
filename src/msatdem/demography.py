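"""Declarative demographic scenarios with priors, for coalescent simulation.

A :class:`Scenario` is a backward-time model: named populations, each
with an effective-size parameter, and a time-ordered list of events
(population merges, pulse admixture, size changes) whose times and
rates are symbols priced by uniform or log-uniform priors.  Time runs
backward in generations with 0 = present; all events are instantaneous.

A library of scenario sets for the Canary Islands blue tit system is
provided: a 3-population test of the split order between Europe, the
Canary archipelago and North Africa; per-island-group tests (western,
central, eastern+Morocco); and a final 9-population set combining
simultaneous within-group splits with alternative branch orders.
Members whose topology is not fully pinned down by the published
description carry ``note="topology partially inferred"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import yaml

MERGE = "merge"
ADMIXTURE = "admixture"
SIZE_CHANGE = "size_change"


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class PriorSpec:
    """A uniform or log-uniform prior for one scalar parameter.

    ``greater_than`` optionally names another parameter that this one must
    exceed in every accepted draw (e.g. a deeper split time).
    """

    name: str
    low: float
    high: float
    distribution: str = "uniform"
    greater_than: str | None = None

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ScenarioError(f"prior {self.name}: low must be < high")
        if self.distribution not in ("uniform", "log_uniform"):
            raise ScenarioError(f"prior {self.name}: unknown distribution")


@dataclass(frozen=True)
class DemographicEvent:
    """One instantaneous backward-time event.

    * ``merge``: lineages of ``derived`` move into ``ancestor`` at ``time``;
    * ``admixture``: each lineage of ``target`` reassigns to ``source1``
      with probability ``rate`` else ``source2``;
    * ``size_change``: ``population`` takes size ``new_size`` backward of
      ``time``.

    Times, rates and sizes may be parameter symbols (str) or literals.
    """

    kind: str
    time: str | float
    derived: str | None = None
    ancestor: str | None = None
    target: str | None = None
    source1: str | None = None
    source2: str | None = None
    rate: str | float | None = None
    population: str | None = None
    new_size: str | float | None = None


@dataclass
class Scenario:
    id: str
    populations: dict[str, str | float]  # name -> size symbol or literal
    events: list[DemographicEvent]
    priors: list[PriorSpec]
    note: str = ""

    def prior(self, name: str) -> PriorSpec:
        for p in self.priors:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def symbols(self) -> list[str]:
        return [p.name for p in self.priors]


@dataclass(frozen=True)
class ParameterDraw:
    values: dict[str, float]
    scenario_id: str
    seed: int | None = None

    def resolve(self, x: str | float) -> float:
        if isinstance(x, str):
            return self.values[x]
        return float(x)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _used_symbols(s: Scenario) -> set[str]:
    used: set[str] = set()
    for v in s.populations.values():
        if isinstance(v, str):
            used.add(v)
    for e in s.events:
        for v in (e.time, e.rate, e.new_size):
            if isinstance(v, str):
                used.add(v)
    return used


def validate_scenario(s: Scenario) -> list[str]:
    """Structural checks; empty list means the scenario is valid.

    Checks that every symbol is priced by exactly one prior, that the
    constraint graph is acyclic, that event actors exist, that admixture
    literal rates are in [0, 1], and that the merges leave a single root.
    """
    violations: list[str] = []
    names = [p.name for p in s.priors]
    if len(set(names)) != len(names):
        violations.append("duplicate prior symbols")
    priced = set(names)
    for sym in sorted(_used_symbols(s) - priced):
        violations.append(f"unpriced parameter {sym!r}")

    # constraint cycle check
    edges = {p.name: p.greater_than for p in s.priors if p.greater_than}
    for start in edges:
        seen = set()
        node: str | None = start
        while node in edges:
            if node in seen:
                violations.append(f"constraint cycle through {start!r}")
                break
            seen.add(node)
            node = edges[node]

    pops = set(s.populations)
    alive = set(pops)
    for e in s.events:
        if e.kind == MERGE:
            if e.derived not in pops or e.ancestor not in pops:
                violations.append(f"merge names unknown population ({e.derived}->{e.ancestor})")
                continue
            if e.derived not in alive:
                violations.append(f"merge of already-merged population {e.derived!r}")
            alive.discard(e.derived)
        elif e.kind == ADMIXTURE:
            for actor in (e.target, e.source1, e.source2):
                if actor not in pops:
                    violations.append(f"admixture names unknown population {actor!r}")
            if isinstance(e.rate, (int, float)) and not 0 <= e.rate <= 1:
                violations.append("admixture rate outside [0, 1]")
        elif e.kind == SIZE_CHANGE:
            if e.population not in pops:
                violations.append(f"size change names unknown population {e.population!r}")
        else:
            violations.append(f"unknown event kind {e.kind!r}")
    if len(alive) > 1:
        violations.append(f"disconnected: {len(alive)} roots remain ({sorted(alive)})")
    return violations


# ---------------------------------------------------------------------------
# prior sampling
# ---------------------------------------------------------------------------

def sample_parameters(
    s: Scenario, n: int, seed: int, max_tries: int = 10_000
) -> list[ParameterDraw]:
    """i.i.d. draws from the scenario's priors, constraints by rejection.

    Raises if the constraint acceptance rate falls below 1e-4 (a
    degenerate constraint system).
    """
    bad = validate_scenario(s)
    if bad:
        raise ScenarioError(f"invalid scenario {s.id}: {bad}")
    rng = np.random.default_rng(seed)
    draws: list[ParameterDraw] = []
    tries = 0
    while len(draws) < n:
        tries += 1
        if tries > max(max_tries, 10_000 * (len(draws) + 1)) and len(draws) / tries < 1e-4:
            raise ScenarioError(
                f"constraint acceptance rate below 1e-4 in scenario {s.id}"
            )
        values: dict[str, float] = {}
        for p in s.priors:
            if p.distribution == "uniform":
                values[p.name] = float(rng.uniform(p.low, p.high))
            else:
                values[p.name] = float(
                    np.exp(rng.uniform(np.log(p.low), np.log(p.high)))
                )
        ok = all(
            values[p.name] > values[p.greater_than]
            for p in s.priors
            if p.greater_than is not None
        )
        if ok:
            draws.append(ParameterDraw(values, s.id, seed))
    return draws


def generations_to_years(g: float, generation_time: float = 2.0) -> float:
    """Convert generations to years at the given generation time (default 2 y)."""
    if g < 0:
        raise ValueError("generations must be >= 0")
    return g * generation_time


# ---------------------------------------------------------------------------
# serialization (YAML)
# ---------------------------------------------------------------------------

def scenario_to_dict(s: Scenario) -> dict:
    return {
        "id": s.id,
        "note": s.note,
        "populations": dict(s.populations),
        "events": [
            {k: v for k, v in vars(e).items() if v is not None} for e in s.events
        ],
        "priors": [
            {k: v for k, v in vars(p).items() if v is not None} for p in s.priors
        ],
    }


def scenario_from_dict(d: Mapping) -> Scenario:
    return Scenario(
        id=d["id"],
        note=d.get("note", ""),
        populations=dict(d["populations"]),
        events=[DemographicEvent(**e) for e in d["events"]],
        priors=[PriorSpec(**p) for p in d["priors"]],
    )


def dump_scenarios(scenarios: Iterable[Scenario], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([scenario_to_dict(s) for s in scenarios], fh, sort_keys=False)


def load_scenarios(path) -> list[Scenario]:
    with open(path) as fh:
        return [scenario_from_dict(d) for d in yaml.safe_load(fh)]


# ---------------------------------------------------------------------------
# scenario library
# ---------------------------------------------------------------------------

_INFERRED = "topology partially inferred"


def _ne_priors(names: Iterable[str], low: float, high: float) -> list[PriorSpec]:
    return [PriorSpec(f"N_{n}", low, high) for n in names]


def _nested_pair(
    set_id: str,
    idx: int,
    first: str,
    second: str,
    out: str,
    ne_range: tuple[float, float],
    t_range: tuple[float, float],
    note: str = "",
) -> Scenario:
    """((first, second) at t2, out) at t1, t1 > t2."""
    pops = {p: f"N_{p}" for p in (first, second, out)}
    return Scenario(
        id=f"{set_id}-{idx}",
        populations=pops,
        events=[
            DemographicEvent(MERGE, "t2", derived=second, ancestor=first),
            DemographicEvent(MERGE, "t1", derived=first, ancestor=out),
        ],
        priors=_ne_priors(pops, *ne_range)
        + [
            PriorSpec("t2", *t_range),
            PriorSpec("t1", *t_range, greater_than="t2"),
        ],
        note=note,
    )


def _fig4() -> list[Scenario]:
    ne = (100.0, 1_000_000.0)
    t = (100.0, 100_000.0)
    pops = ("Europe", "Canaries", "NorthAfrica")
    return [
        _nested_pair("fig4", 1, "Europe", "Canaries", "NorthAfrica", ne, t, _INFERRED),
        _nested_pair("fig4", 2, "Europe", "NorthAfrica", "Canaries", ne, t, _INFERRED),
        # supported topology: Europe is the outgroup to Canaries+NorthAfrica
        _nested_pair("fig4", 3, "Canaries", "NorthAfrica", "Europe", ne, t),
    ]


def _three_taxon_set(set_id: str, a: str, b: str, c: str) -> list[Scenario]:
    """Six 3-taxon scenarios: three nested orders, two admixture variants,
    and a simultaneous split (member 5, the one the published text fixes)."""
    ne = (100.0, 10_000.0)
    t = (100.0, 1_000_000.0)
    out: list[Scenario] = [
        _nested_pair(set_id, 1, a, b, c, ne, t, _INFERRED),
        _nested_pair(set_id, 2, a, c, b, ne, t, _INFERRED),
        _nested_pair(set_id, 3, b, c, a, ne, t, _INFERRED),
        # 4: b and c split at t2; a is an admixture pulse of b and c at ta < t2
        Scenario(
            id=f"{set_id}-4",
            populations={p: f"N_{p}" for p in (a, b, c)},
            events=[
                DemographicEvent(ADMIXTURE, "ta", target=a, source1=b, source2=c, rate="r"),
                DemographicEvent(MERGE, "t2", derived=c, ancestor=b),
                DemographicEvent(MERGE, "t2", derived=a, ancestor=b),
            ],
            priors=_ne_priors((a, b, c), *ne)
            + [
                PriorSpec("ta", *t),
                PriorSpec("t2", *t, greater_than="ta"),
                PriorSpec("r", 0.001, 0.999),
            ],
            note=_INFERRED,
        ),
        # 5: simultaneous split of all three from one ancestor (no admixture)
        Scenario(
            id=f"{set_id}-5",
            populations={p: f"N_{p}" for p in (a, b, c)},
            events=[
                DemographicEvent(MERGE, "t1", derived=b, ancestor=a),
                DemographicEvent(MERGE, "t1", derived=c, ancestor=a),
            ],
            priors=_ne_priors((a, b, c), *ne) + [PriorSpec("t1", *t)],
        ),
        # 6: a and c split at t2; b admixed from a and c at tb < t2
        Scenario(
            id=f"{set_id}-6",
            populations={p: f"N_{p}" for p in (a, b, c)},
            events=[
                DemographicEvent(ADMIXTURE, "tb", target=b, source1=a, source2=c, rate="r"),
                DemographicEvent(MERGE, "t2", derived=c, ancestor=a),
                DemographicEvent(MERGE, "t2", derived=b, ancestor=a),
            ],
            priors=_ne_priors((a, b, c), *ne)
            + [
                PriorSpec("tb", *t),
                PriorSpec("t2", *t, greater_than="tb"),
                PriorSpec("r", 0.001, 0.999),
            ],
            note=_INFERRED,
        ),
    ]
    return out


def _figS1_western() -> list[Scenario]:
    """Western-group test: Europe, La Palma, El Hierro and the combined
    central group.  Member 4 (simultaneous island splits, Europe outgroup)
    is the one the published description fixes."""
    ne = (100.0, 10_000.0)
    t = (100.0, 1_000_000.0)
    pops = ("Europe", "LaPalma", "ElHierro", "Central")

    s1 = Scenario(  # ((LaPalma, ElHierro), Central)
        id="figS1-1",
        populations={p: f"N_{p}" for p in pops},
        events=[
            DemographicEvent(MERGE, "t2", derived="ElHierro", ancestor="LaPalma"),
            DemographicEvent(MERGE, "t1", derived="Central", ancestor="LaPalma"),
            DemographicEvent(MERGE, "t_root", derived="LaPalma", ancestor="Europe"),
        ],
        priors=_ne_priors(pops, *ne)
        + [
            PriorSpec("t2", *t),
            PriorSpec("t1", *t, greater_than="t2"),
            PriorSpec("t_root", *t, greater_than="t1"),
        ],
        note=_INFERRED,
    )
    s2 = Scenario(  # ((LaPalma, Central), ElHierro)
        id="figS1-2",
        populations={p: f"N_{p}" for p in pops},
        events=[
            DemographicEvent(MERGE, "t2", derived="Central", ancestor="LaPalma"),
            DemographicEvent(MERGE, "t1", derived="ElHierro", ancestor="LaPalma"),
            DemographicEvent(MERGE, "t_root", derived="LaPalma", ancestor="Europe"),
        ],
        priors=s1.priors,
        note=_INFERRED,
    )
    s3 = Scenario(  # ((ElHierro, Central), LaPalma)
        id="figS1-3",
        populations={p: f"N_{p}" for p in pops},
        events=[
            DemographicEvent(MERGE, "t2", derived="Central", ancestor="ElHierro"),
            DemographicEvent(MERGE, "t1", derived="ElHierro", ancestor="LaPalma"),
            DemographicEvent(MERGE, "t_root", derived="LaPalma", ancestor="Europe"),
        ],
        priors=s1.priors,
        note=_INFERRED,
    )
    s4 = Scenario(  # simultaneous split of the three island groups
        id="figS1-4",
        populations={p: f"N_{p}" for p in pops},
        events=[
            DemographicEvent(MERGE, "t1", derived="ElHierro", ancestor="LaPalma"),
            DemographicEvent(MERGE, "t1", derived="Central", ancestor="LaPalma"),
            DemographicEvent(MERGE, "t_root", derived="LaPalma", ancestor="Europe"),
        ],
        priors=_ne_priors(pops, *ne)
        + [
            PriorSpec("t1", *t),
            PriorSpec("t_root", *t, greater_than="t1"),
        ],
    )
    s5 = Scenario(  # serial colonisation Central -> ElHierro -> LaPalma
        id="figS1-5",
        populations={p: f"N_{p}" for p in pops},
        events=[
            DemographicEvent(MERGE, "t3", derived="LaPalma", ancestor="ElHierro"),
            DemographicEvent(MERGE, "t2", derived="ElHierro", ancestor="Central"),
            DemographicEvent(MERGE, "t_root", derived="Central", ancestor="Europe"),
        ],
        priors=_ne_priors(pops, *ne)
        + [
            PriorSpec("t3", *t),
            PriorSpec("t2", *t, greater_than="t3"),
            PriorSpec("t_root", *t, greater_than="t2"),
        ],
        note=_INFERRED,
    )
    return [s1, s2, s3, s4, s5]


def _fig5_final() -> list[Scenario]:
    """Final 9-population set.  Members 2 (eastern+Morocco most recent,
    central trio sister to the western pair's branch) and 6 (all splits
    simultaneous) follow the published description; the rest vary branch
    order / the origin of the eastern branch and are flagged."""
    ne = (100.0, 10_000.0)
    t = (100.0, 1_000_000.0)
    pops = (
        "Europe",
        "ElHierro",
        "LaPalma",
        "LaGomera",
        "Tenerife",
        "GranCanaria",
        "Lanzarote",
        "Fuerteventura",
        "NorthAfrica",
    )
    west = ("ElHierro", "LaPalma")
    central = ("LaGomera", "Tenerife", "GranCanaria")
    east = ("Lanzarote", "Fuerteventura", "NorthAfrica")

    def group_merges(members, anchor, tsym):
        return [
            DemographicEvent(MERGE, tsym, derived=m, ancestor=anchor)
            for m in members
            if m != anchor
        ]

    def scen(idx, events, priors, note=""):
        return Scenario(
            id=f"fig5-{idx}",
            populations={p: f"N_{p}" for p in pops},
            events=events,
            priors=_ne_priors(pops, *ne) + priors,
            note=note,
        )

    # shared building blocks: simultaneous within-group splits
    ev_w = group_merges(west, "LaPalma", "t_w")
    ev_c = group_merges(central, "Tenerife", "t_c")
    ev_e = group_merges(east, "NorthAfrica", "t_e")

    t_priors = [PriorSpec("t_w", *t), PriorSpec("t_c", *t), PriorSpec("t_e", *t)]

    # 2: eastern split most recent; central ancestor joins eastern ancestor,
    #    then that branch joins the western ancestor, then Europe (outgroup).
    s2 = scen(
        2,
        ev_e
        + ev_c
        + ev_w
        + [
            DemographicEvent(MERGE, "t_ce", derived="NorthAfrica", ancestor="Tenerife"),
            DemographicEvent(MERGE, "t_wc", derived="Tenerife", ancestor="LaPalma"),
            DemographicEvent(MERGE, "t_root", derived="LaPalma", ancestor="Europe"),
        ],
        [
            PriorSpec("t_e", *t),
            PriorSpec("t_c", *t, greater_than="t_e"),
            PriorSpec("t_w", *t, greater_than="t_c"),
            PriorSpec("t_ce", *t, greater_than="t_c"),
            PriorSpec("t_wc", *t, greater_than="t_ce"),
            PriorSpec("t_root", *t, greater_than="t_wc"),
        ],
    )
    # 6: all nine-region splits simultaneous, Europe outgroup
    s6 = scen(
        6,
        [
            DemographicEvent(MERGE, "t1", derived=p, ancestor="NorthAfrica")
            for p in pops
            if p not in ("Europe", "NorthAfrica")
        ]
        + [DemographicEvent(MERGE, "t_root", derived="NorthAfrica", ancestor="Europe")],
        [PriorSpec("t1", *t), PriorSpec("t_root", *t, greater_than="t1")],
    )
    # 1: eastern branch originates from the central ancestor (stepping stone)
    s1 = scen(
        1,
        ev_e
        + ev_c
        + ev_w
        + [
            DemographicEvent(MERGE, "t_ec", derived="NorthAfrica", ancestor="Tenerife"),
            DemographicEvent(MERGE, "t_cw", derived="LaPalma", ancestor="Tenerife"),
            DemographicEvent(MERGE, "t_root", derived="Tenerife", ancestor="Europe"),
        ],
        [
            PriorSpec("t_e", *t),
            PriorSpec("t_c", *t, greater_than="t_e"),
            PriorSpec("t_w", *t),
            PriorSpec("t_ec", *t, greater_than="t_c"),
            PriorSpec("t_cw", *t, greater_than="t_ec"),
            PriorSpec("t_root", *t, greater_than="t_cw"),
        ],
        note=_INFERRED,
    )
    # 3: western pair splits first from the archipelago ancestor
    s3 = scen(
        3,
        ev_w
        + ev_c
        + ev_e
        + [
            DemographicEvent(MERGE, "t_ce", derived="Tenerife", ancestor="NorthAfrica"),
            DemographicEvent(MERGE, "t_wce", derived="LaPalma", ancestor="NorthAfrica"),
            DemographicEvent(MERGE, "t_root", derived="NorthAfrica", ancestor="Europe"),
        ],
        t_priors
        + [
            PriorSpec("t_ce", *t, greater_than="t_c"),
            PriorSpec("t_wce", *t, greater_than="t_ce"),
            PriorSpec("t_root", *t, greater_than="t_wce"),
        ],
        note=_INFERRED,
    )
    # 4: all three group ancestors split simultaneously from one ancestor
    s4 = scen(
        4,
        ev_w
        + ev_c
        + ev_e
        + [
            DemographicEvent(MERGE, "t_groups", derived="LaPalma", ancestor="NorthAfrica"),
            DemographicEvent(MERGE, "t_groups", derived="Tenerife", ancestor="NorthAfrica"),
            DemographicEvent(MERGE, "t_root", derived="NorthAfrica", ancestor="Europe"),
        ],
        t_priors
        + [
            PriorSpec("t_groups", *t, greater_than="t_w"),
            PriorSpec("t_root", *t, greater_than="t_groups"),
        ],
        note=_INFERRED,
    )
    # 5: eastern branch originates from the western ancestor
    s5 = scen(
        5,
        ev_e
        + ev_w
        + ev_c
        + [
            DemographicEvent(MERGE, "t_ew", derived="NorthAfrica", ancestor="LaPalma"),
            DemographicEvent(MERGE, "t_wc", derived="Tenerife", ancestor="LaPalma"),
            DemographicEvent(MERGE, "t_root", derived="LaPalma", ancestor="Europe"),
        ],
        [
            PriorSpec("t_e", *t),
            PriorSpec("t_w", *t, greater_than="t_e"),
            PriorSpec("t_c", *t),
            PriorSpec("t_ew", *t, greater_than="t_w"),
            PriorSpec("t_wc", *t, greater_than="t_ew"),
            PriorSpec("t_root", *t, greater_than="t_wc"),
        ],
        note=_INFERRED,
    )
    return [s1, s2, s3, s4, s5, s6]


_SET_BUILDERS = {
    "fig4": _fig4,
    "figS1_western": _figS1_western,
    "figS2_central": lambda: _three_taxon_set("figS2c", "Tenerife", "GranCanaria", "LaGomera"),
    "figS2_eastern": lambda: _three_taxon_set("figS2e", "Fuerteventura", "Lanzarote", "NorthAfrica"),
    "fig5_final": _fig5_final,
}


def paper_scenarios(set_id: str) -> list[Scenario]:
    """Return one of the bundled Canary Islands scenario sets.

    ``set_id`` is one of ``fig4``, ``figS1_western``, ``figS2_central``,
    ``figS2_eastern``, ``fig5_final``.
    """
    try:
        builder = _SET_BUILDERS[set_id]
    except KeyError:
        raise ScenarioError(
            f"unknown scenario set {set_id!r}; choose from {sorted(_SET_BUILDERS)}"
        ) from None
    scenarios = builder()
    for s in scenarios:
        bad = validate_scenario(s)
        if bad:
            raise ScenarioError(f"internal error: scenario {s.id} invalid: {bad}")
    return scenarios


def scenario_sets() -> list[str]:
    return sorted(_SET_BUILDERS)
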