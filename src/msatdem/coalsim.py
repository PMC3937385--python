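"""Backward-time coalescent simulator with stepwise microsatellite mutation.

Simulates gene genealogies under a multi-population scenario (splits,
pulse admixture, size changes) in the continuous-time approximation:
within a population of ``N`` diploids, ``k`` lineages coalesce at rate
``k(k-1)/2`` per ``2N`` generations.  Z-linked loci carry 1.5 gene
copies per diploid (ZZ males, ZW females), so their pair-coalescence
rate uses ``0.75 * 2N``; sampled females contribute a single Z copy.

Mutations are a Poisson process on branches.  Under the stepwise
mutation model (SMM) each mutation moves the allele +-1 repeat unit;
the generalised model (GSM) draws step magnitudes from a geometric
distribution, P(k) = (1-p) p^(k-1).  An optional contiguous allele
range applies reflecting boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .demography import (
    ADMIXTURE,
    MERGE,
    SIZE_CHANGE,
    ParameterDraw,
    Scenario,
    ScenarioError,
    validate_scenario,
)
from .genepop import (
    AUTOSOMAL,
    Dataset,
    FEMALE,
    Individual,
    LocusDef,
    MALE,
    Z_LINKED,
)


@dataclass(frozen=True)
class SampleConfig:
    """Numbers of sampled males and females per population."""

    sizes: Mapping[str, tuple[int, int]]  # pop -> (n_males, n_females)

    def total_individuals(self) -> int:
        return sum(m + f for m, f in self.sizes.values())

    def copies(self, population: str, inheritance: str) -> int:
        m, f = self.sizes[population]
        return 2 * m + (2 * f if inheritance == AUTOSOMAL else f)


@dataclass(frozen=True)
class MutationModel:
    """Microsatellite mutation model shared by all loci.

    ``mean_rate`` is mutations per locus per generation; ``gsm_p = 0``
    reduces the GSM to the pure SMM.  ``range_bound`` (a width in repeat
    units, centred on ``ancestral_state``) applies reflecting boundaries.
    """

    mean_rate: float
    model: str = "smm"
    gsm_p: float = 0.0
    ancestral_state: int = 20
    range_bound: int | None = None

    def __post_init__(self) -> None:
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be > 0")
        if self.model not in ("smm", "gsm"):
            raise ValueError("model must be 'smm' or 'gsm'")
        if not 0 <= self.gsm_p < 1:
            raise ValueError("gsm_p must be in [0, 1)")


@dataclass
class GenealogySample:
    """A coalescent tree over sampled gene copies at one locus.

    Node 0..n_leaves-1 are leaves at time 0; internal nodes follow in
    coalescence order.  ``parents[i]`` is -1 for the root.
    """

    times: np.ndarray
    parents: np.ndarray
    n_leaves: int
    leaf_population: list[str]
    leaf_sex: list[str]
    leaf_individual: np.ndarray  # index into the dataset's individual list
    leaf_slot: np.ndarray  # 0 or 1: which allele slot the copy fills

    @property
    def tmrca(self) -> float:
        return float(self.times.max())

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (root entry 0)."""
        out = np.zeros(len(self.times))
        has_parent = self.parents >= 0
        out[has_parent] = self.times[self.parents[has_parent]] - self.times[has_parent]
        return out


class _BufferedRng:
    """Amortises numpy Generator call overhead in the event loop."""

    __slots__ = ("rng", "_exp", "_ei", "_uni", "_ui", "_n")

    def __init__(self, rng: np.random.Generator, n: int = 512) -> None:
        self.rng = rng
        self._n = n
        self._exp = rng.exponential(size=n)
        self._ei = 0
        self._uni = rng.random(size=n)
        self._ui = 0

    def exponential(self) -> float:
        if self._ei == self._n:
            self._exp = self.rng.exponential(size=self._n)
            self._ei = 0
        v = self._exp[self._ei]
        self._ei += 1
        return v

    def uniform(self) -> float:
        if self._ui == self._n:
            self._uni = self.rng.random(size=self._n)
            self._ui = 0
        v = self._uni[self._ui]
        self._ui += 1
        return v


def _leaf_layout(
    scenario: Scenario,
    config: SampleConfig,
    individuals: Sequence[Individual],
    inheritance: str,
) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Per-copy population/sex labels and (individual, slot) bookkeeping."""
    pops, sexes, ind_idx, slots = [], [], [], []
    for i, ind in enumerate(individuals):
        n_copies = 1 if (inheritance == Z_LINKED and ind.sex == FEMALE) else 2
        for s in range(n_copies):
            pops.append(ind.population)
            sexes.append(ind.sex)
            ind_idx.append(i)
            slots.append(s)
    return pops, sexes, np.array(ind_idx), np.array(slots)


def _pair_rate_factor(n_diploids: float, inheritance: str) -> float:
    """Coalescence rate per lineage pair: 1/(2N) autosomal, 1/(1.5N) Z."""
    if inheritance == Z_LINKED:
        return 1.0 / (2.0 * 0.75 * n_diploids)
    return 1.0 / (2.0 * n_diploids)


def simulate_locus(
    scenario: Scenario,
    draw: ParameterDraw,
    config: SampleConfig,
    locus: LocusDef,
    seed: int | np.random.Generator,
    individuals: Sequence[Individual] | None = None,
) -> GenealogySample:
    """Simulate one locus genealogy under the scenario at the given draw.

    ``individuals`` fixes the sampled individual list (shared across loci
    by :func:`simulate_dataset`); by default it is built from ``config``.
    """
    bad = validate_scenario(scenario)
    if bad:
        raise ScenarioError(f"invalid scenario {scenario.id}: {bad}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if individuals is None:
        individuals = default_individuals(scenario, config)

    leaf_pop, leaf_sex, leaf_ind, leaf_slot = _leaf_layout(
        scenario, config, individuals, locus.inheritance
    )
    n_leaves = len(leaf_pop)
    if n_leaves < 2:
        raise ValueError("need at least 2 sampled gene copies")

    # resolved demography
    factor = {
        pop: _pair_rate_factor(draw.resolve(size), locus.inheritance)
        for pop, size in scenario.populations.items()
    }
    events = sorted(scenario.events, key=lambda e: draw.resolve(e.time))

    active: dict[str, list[int]] = {pop: [] for pop in scenario.populations}
    for node, pop in enumerate(leaf_pop):
        active[pop].append(node)

    times = list(np.zeros(n_leaves))
    parents = [-1] * (2 * n_leaves - 1)
    merged_into: dict[str, str] = {}

    def resolve_pop(pop: str) -> str:
        while pop in merged_into:
            pop = merged_into[pop]
        return pop

    buf = _BufferedRng(rng)
    t = 0.0
    ev_i = 0
    total = n_leaves
    next_node = n_leaves
    pop_names = list(scenario.populations)

    # Populations evolve independently between events, so each epoch can
    # draw the successive Kingman coalescence times per population in one
    # vectorised pass instead of re-evaluating global rates per event.
    while total > 1:
        t_end = draw.resolve(events[ev_i].time) if ev_i < len(events) else np.inf
        for pop in pop_names:
            lineages = active[pop]
            k = len(lineages)
            if k < 2:
                continue
            js = np.arange(k, 1, -1, dtype=np.float64)
            gaps = rng.exponential(size=k - 1) * (2.0 / (js * (js - 1) * factor[pop]))
            ts = t + np.cumsum(gaps)
            m = int(np.searchsorted(ts, t_end))
            for i in range(m):
                kk = len(lineages)
                i1 = int(buf.uniform() * kk)
                i2 = int(buf.uniform() * (kk - 1))
                if i2 >= i1:
                    i2 += 1
                c1, c2 = lineages[i1], lineages[i2]
                for idx in (i1, i2) if i1 > i2 else (i2, i1):
                    lineages[idx] = lineages[-1]
                    lineages.pop()
                parents[c1] = parents[c2] = next_node
                times.append(ts[i])
                lineages.append(next_node)
                next_node += 1
            total -= m
        if total == 1:
            break
        if ev_i >= len(events):
            stranded = [p for p in pop_names if len(active[p]) > 0]
            raise ScenarioError(
                f"scenario {scenario.id}: lineages stranded in populations "
                f"{stranded} with no further events"
            )
        t = t_end
        # apply every event scheduled at this instant, in list order
        while ev_i < len(events) and draw.resolve(events[ev_i].time) <= t:
            e = events[ev_i]
            ev_i += 1
            if e.kind == MERGE:
                anc = resolve_pop(e.ancestor)
                if anc == e.derived:
                    continue
                active[anc].extend(active[e.derived])
                active[e.derived] = []
                merged_into[e.derived] = anc
            elif e.kind == ADMIXTURE:
                r = draw.resolve(e.rate)
                s1, s2 = resolve_pop(e.source1), resolve_pop(e.source2)
                moving = active[e.target]
                active[e.target] = []
                for node in moving:
                    dest = s1 if buf.uniform() < r else s2
                    active[dest].append(node)
            elif e.kind == SIZE_CHANGE:
                factor[e.population] = _pair_rate_factor(
                    draw.resolve(e.new_size), locus.inheritance
                )

    return GenealogySample(
        times=np.asarray(times),
        parents=np.asarray(parents[: len(times)]),
        n_leaves=n_leaves,
        leaf_population=leaf_pop,
        leaf_sex=leaf_sex,
        leaf_individual=leaf_ind,
        leaf_slot=leaf_slot,
    )


def _fold(states: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Reflecting-boundary image of a free +-1 walk endpoint on [lo, hi].

    Exact for unit steps (the reflected walk is the folded free walk)."""
    width = hi - lo
    if width <= 0:
        return np.full_like(states, lo)
    y = np.abs(states - lo) % (2 * width)
    y = np.where(y > width, 2 * width - y, y)
    return lo + y


def _mutate(
    tree: GenealogySample, mut: MutationModel, rng: np.random.Generator
) -> np.ndarray:
    """Leaf allele states from Poisson mutations on branches."""
    lengths = tree.branch_lengths()
    n_mut = rng.poisson(mut.mean_rate * lengths)
    net = np.zeros(len(lengths), dtype=np.int64)
    nz = np.flatnonzero(n_mut)
    if mut.model == "smm" or mut.gsm_p == 0.0:
        # sum of n fair +-1 steps = 2*Binomial(n, 1/2) - n
        net[nz] = 2 * rng.binomial(n_mut[nz], 0.5) - n_mut[nz]
    else:
        for i in nz:
            k = rng.geometric(1.0 - mut.gsm_p, size=n_mut[i])
            signs = rng.integers(0, 2, size=n_mut[i]) * 2 - 1
            net[i] = int(np.sum(k * signs))

    order = np.argsort(-tree.times, kind="stable")
    state = np.zeros(len(tree.times), dtype=np.int64)
    bounded = mut.range_bound is not None
    if bounded:
        half = mut.range_bound // 2
        lo, hi = mut.ancestral_state - half, mut.ancestral_state + half
    for node in order:
        p = tree.parents[node]
        if p < 0:
            state[node] = mut.ancestral_state
        else:
            state[node] = state[p] + net[node]
    if bounded:
        if mut.model == "gsm" and mut.gsm_p > 0:
            # geometric steps can overshoot a boundary; clamp after folding
            state = np.clip(_fold(state, lo, hi), lo, hi)
        else:
            state = _fold(state, lo, hi)
    return state[: tree.n_leaves]


def default_individuals(
    scenario: Scenario, config: SampleConfig
) -> list[Individual]:
    """Individuals implied by a sample configuration: males then females."""
    out: list[Individual] = []
    for pop in scenario.populations:
        if pop not in config.sizes:
            continue
        m, f = config.sizes[pop]
        for i in range(m):
            out.append(Individual(f"{pop}-m{i:03d}", pop, MALE))
        for i in range(f):
            out.append(Individual(f"{pop}-f{i:03d}", pop, FEMALE))
    return out


def simulate_dataset(
    scenario: Scenario,
    draw: ParameterDraw,
    config: SampleConfig,
    loci: Sequence[LocusDef],
    mut: MutationModel,
    seed: int,
) -> Dataset:
    """Simulate independent loci and assemble a genotype :class:`Dataset`.

    Fully reproducible: per-locus RNG streams are spawned from ``seed``,
    so the result is byte-identical for a given seed.
    """
    individuals = default_individuals(scenario, config)
    n = len(individuals)
    alleles = np.zeros((n, len(loci), 2), np.int32)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(loci))
    for j, locus in enumerate(loci):
        rng = np.random.default_rng(children[j])
        tree = simulate_locus(scenario, draw, config, locus, rng, individuals)
        states = _mutate(tree, mut, rng)
        if (states < 1).any():
            # keep allele states positive (integer repeat counts); an
            # explicit range_bound avoids ever hitting this shift
            states = states + (1 - states.min())
        alleles[tree.leaf_individual, j, tree.leaf_slot] = states
    return Dataset(list(loci), individuals, alleles)


def default_loci(
    n_autosomal: int, n_z: int = 0, prefix: str = "L"
) -> list[LocusDef]:
    """Convenience: unlinked loci, autosomal first then Z-linked."""
    out = [LocusDef(f"{prefix}{i + 1:02d}", AUTOSOMAL) for i in range(n_autosomal)]
    out += [
        LocusDef(f"{prefix}Z{i + 1:02d}", Z_LINKED) for i in range(n_z)
    ]
    return out
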