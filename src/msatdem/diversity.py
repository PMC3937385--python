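"""Per-population diversity statistics for microsatellite datasets.

Implements the classical per-population descriptors for subdivided
populations: observed heterozygosity, Nei's unbiased expected
heterozygosity, Weir & Cockerham's within-population inbreeding
coefficient F_IS, rarefaction-standardised allelic richness, private
allele counts and a permutation test for Hardy–Weinberg equilibrium.

Z-linked loci (birds: males ZZ diploid, females ZW hemizygous) are
handled by a fixed policy: allele frequencies, expected heterozygosity
and allelic richness use *all* typed gene copies (a hemizygous female
contributes one); observed heterozygosity, F_IS and the HWE test use
male diploid genotypes only, so hemizygotes never masquerade as
homozygotes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genepop import Dataset, MALE, Z_LINKED


def _diploid_rows(dataset: Dataset, pop_mask: np.ndarray, j: int) -> np.ndarray:
    """(k, 2) array of typed diploid genotypes for one population x locus.

    At Z-linked loci only males enter (see module policy).
    """
    mask = pop_mask.copy()
    if dataset.loci[j].inheritance == Z_LINKED:
        mask &= dataset.sex_array() == MALE
    block = dataset.alleles[mask, j, :]
    typed = (block > 0).all(axis=1)
    return block[typed]


def _allele_freqs(copies: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique allele states and their relative frequencies."""
    states, counts = np.unique(copies, return_counts=True)
    return states, counts / counts.sum()


def nei_unbiased_he(copies: np.ndarray) -> float:
    """Nei's unbiased gene diversity (2n/(2n-1))(1 - sum p_i^2).

    ``copies`` are the typed gene copies at one locus in one population;
    the 2n factor generalises to the copy count, which may be odd when
    hemizygous females contribute single Z copies.
    """
    c = len(copies)
    if c < 2:
        return float("nan")
    _, p = _allele_freqs(copies)
    return c / (c - 1) * (1.0 - float(np.sum(p**2)))


def observed_het(genos: np.ndarray) -> float:
    """Fraction of heterozygotes among typed diploid genotypes."""
    if len(genos) == 0:
        return float("nan")
    return float(np.mean(genos[:, 0] != genos[:, 1]))


def _wc_within_components(genos: np.ndarray) -> tuple[float, float]:
    """Weir–Cockerham within-population variance components (b, c).

    Single-population case of the 1984 estimator, summed over alleles:
    ``b`` is the among-individuals-within-population component and ``c``
    the within-individuals component; ``f = sum(b) / sum(b + c)``.
    """
    n = len(genos)
    if n < 2:
        return 0.0, 0.0
    states = np.unique(genos)
    b_sum = c_sum = 0.0
    for s in states:
        is_s = genos == s
        p = is_s.mean()
        h = float(np.mean(is_s.sum(axis=1) == 1))  # het carrying allele s
        b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        c = h / 2
        b_sum += b
        c_sum += c
    return b_sum, c_sum


def fis_weir_cockerham(dataset: Dataset, population: str) -> float:
    """Multi-locus F_IS: sum of b over sum of (b+c) across loci."""
    pop_mask = dataset.population_mask(population)
    b_tot = bc_tot = 0.0
    for j in range(dataset.n_loci):
        genos = _diploid_rows(dataset, pop_mask, j)
        b, c = _wc_within_components(genos)
        b_tot += b
        bc_tot += b + c
    if bc_tot == 0:
        return float("nan")
    return b_tot / bc_tot


def rarefied_richness(copies: np.ndarray, g: int) -> float:
    """Expected allele count in a rarefied sample of ``g`` gene copies.

    sum_i [1 - C(2N - N_i, g) / C(2N, g)] with 2N the typed copy count
    and N_i the count of allele i (hurlbert/Fstat rarefaction).
    """
    c = len(copies)
    if g > c:
        raise ValueError(f"rarefaction size g={g} exceeds available copies {c}")
    states, counts = np.unique(copies, return_counts=True)
    denom = math.comb(c, g)
    total = 0.0
    for ni in counts:
        rem = c - int(ni)
        total += 1.0 - (math.comb(rem, g) / denom if rem >= g else 0.0)
    return total


def auto_rarefaction_g(dataset: Dataset) -> int:
    """Minimum typed gene-copy count over all nonempty population x locus cells."""
    best = None
    for pop in dataset.populations:
        for j in range(dataset.n_loci):
            c = len(dataset.gene_copies(pop, j))
            if c > 0:
                best = c if best is None else min(best, c)
    if best is None:
        raise ValueError("dataset has no typed calls")
    return best


def allelic_richness(
    dataset: Dataset, g: int | str = "auto"
) -> tuple[pd.DataFrame, pd.Series]:
    """Rarefied allelic richness per population x locus, plus per-population means.

    ``g='auto'`` uses the minimum typed copy count across nonempty cells
    (the Fstat convention), so every cell can be rarefied.
    """
    if g == "auto":
        g = auto_rarefaction_g(dataset)
    g = int(g)
    pops = dataset.populations
    names = [loc.name for loc in dataset.loci]
    table = pd.DataFrame(np.nan, index=pops, columns=names)
    for pop in pops:
        for j, name in enumerate(names):
            copies = dataset.gene_copies(pop, j)
            if len(copies) == 0:
                continue
            if g > len(copies):
                raise ValueError(
                    f"g={g} exceeds {len(copies)} typed copies in population "
                    f"{pop!r}, locus {name!r}"
                )
            table.loc[pop, name] = rarefied_richness(copies, g)
    return table, table.mean(axis=1)


def private_allele_counts(dataset: Dataset) -> pd.Series:
    """Number of alleles observed in exactly one population, per population."""
    pops = dataset.populations
    counts = pd.Series(0, index=pops, dtype=int)
    for j in range(dataset.n_loci):
        seen: dict[int, set[str]] = {}
        for pop in pops:
            for a in np.unique(dataset.gene_copies(pop, j)):
                seen.setdefault(int(a), set()).add(pop)
        for a, holders in seen.items():
            if len(holders) == 1:
                counts[next(iter(holders))] += 1
    return counts


@dataclass
class HweResult:
    """Permutation HWE p-values per population x locus."""

    p: pd.DataFrame
    monomorphic: pd.DataFrame  # True where the cell had a single allele


def hwe_test(dataset: Dataset, permutations: int, seed: int) -> HweResult:
    """Permutation test for Hardy–Weinberg equilibrium, per population x locus.

    Null distribution: alleles shuffled among individuals within the
    population at that locus; statistic |F_IS| (single-locus Weir–Cockerham);
    p = (1 + #{perm >= observed}) / (permutations + 1).  Monomorphic cells
    report p = 1 with a flag.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    rng = np.random.default_rng(seed)
    pops = dataset.populations
    names = [loc.name for loc in dataset.loci]
    p_tab = pd.DataFrame(np.nan, index=pops, columns=names)
    mono = pd.DataFrame(False, index=pops, columns=names)
    for pop in pops:
        pop_mask = dataset.population_mask(pop)
        for j, name in enumerate(names):
            genos = _diploid_rows(dataset, pop_mask, j)
            if len(genos) == 0:
                continue
            if len(np.unique(genos)) < 2:
                p_tab.loc[pop, name] = 1.0
                mono.loc[pop, name] = True
                continue
            obs = abs(_fis_single(genos))
            pool = genos.ravel().copy()
            k = 0
            for _ in range(permutations):
                rng.shuffle(pool)
                perm = pool.reshape(-1, 2)
                if abs(_fis_single(perm)) >= obs - 1e-12:
                    k += 1
            p_tab.loc[pop, name] = (1 + k) / (permutations + 1)
    return HweResult(p_tab, mono)


def _fis_single(genos: np.ndarray) -> float:
    b, c = _wc_within_components(genos)
    if b + c == 0:
        return 0.0
    return b / (b + c)


def population_diversity(
    dataset: Dataset,
    rarefaction_g: int | str = "auto",
    hwe_permutations: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-population diversity table.

    Columns: sample_size, mean_alleles, monomorphic_loci, private_alleles,
    allelic_richness, Ho, He, Fis and (when ``hwe_permutations > 0``)
    hwe_p_min plus a Bonferroni-adjusted companion column (adjustment
    reported, not applied).  Loci with no typed copies in a population are
    skipped for that population.
    """
    pops = dataset.populations
    _, richness_mean = allelic_richness(dataset, rarefaction_g)
    private = private_allele_counts(dataset)

    rows = []
    for pop in pops:
        pop_mask = dataset.population_mask(pop)
        n_alleles, he_vals, ho_vals = [], [], []
        mono = 0
        for j in range(dataset.n_loci):
            copies = dataset.gene_copies(pop, j)
            if len(copies) == 0:
                continue
            k = len(np.unique(copies))
            n_alleles.append(k)
            if k == 1:
                mono += 1
            he = nei_unbiased_he(copies)
            if not math.isnan(he):
                he_vals.append(he)
            genos = _diploid_rows(dataset, pop_mask, j)
            ho = observed_het(genos)
            if not math.isnan(ho):
                ho_vals.append(ho)
        rows.append(
            {
                "population": pop,
                "sample_size": int(pop_mask.sum()),
                "mean_alleles": float(np.mean(n_alleles)) if n_alleles else float("nan"),
                "monomorphic_loci": mono,
                "private_alleles": int(private[pop]),
                "allelic_richness": float(richness_mean[pop]),
                "Ho": float(np.mean(ho_vals)) if ho_vals else float("nan"),
                "He": float(np.mean(he_vals)) if he_vals else float("nan"),
                "Fis": fis_weir_cockerham(dataset, pop),
            }
        )
    table = pd.DataFrame(rows).set_index("population")

    if hwe_permutations > 0:
        hwe = hwe_test(dataset, hwe_permutations, seed)
        n_cells = hwe.p.notna().sum(axis=1)
        pmin = hwe.p.min(axis=1)
        table["hwe_p_min"] = pmin
        table["hwe_p_min_bonferroni"] = np.minimum(1.0, pmin * n_cells)
    return table
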