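"""Pairwise population differentiation: Weir–Cockerham theta and Jost's D.

Weir & Cockerham's (1984) theta is the variance-component estimator of
F_ST: per locus and allele the components are

* ``a`` — among populations,
* ``b`` — among individuals within populations,
* ``c`` — within individuals,

and the multi-locus estimate is ``sum(a) / sum(a + b + c)`` over loci and
alleles.  Significance is assessed by permuting whole multilocus
genotypes between the two populations (no HWE assumption).

Jost's D_est is computed per locus from the Nei–Chesser bias-corrected
within- and total heterozygosities for the pair (s = 2 subpopulations),
D = (H_T - H_S)/(1 - H_S) * s/(s-1), combined across loci by the
harmonic mean, with a bootstrap (individuals resampled within
populations) percentile confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .genepop import Dataset, MALE, Z_LINKED

#: value substituted for non-positive per-locus D_est in the harmonic mean
HARMONIC_EPS = 1e-4


@dataclass
class PairwiseMatrix:
    """Symmetric pairwise matrix with optional p-values and CIs."""

    populations: list[str]
    values: np.ndarray
    p_values: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    significant: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)

    def to_frame(self, which: str = "values") -> pd.DataFrame:
        return pd.DataFrame(
            getattr(self, which), index=self.populations, columns=self.populations
        )

    def lower_triangle(self) -> np.ndarray:
        """Off-diagonal lower-triangle entries, row-major order."""
        n = len(self.populations)
        return np.array([self.values[i, j] for i in range(n) for j in range(i)])


# ---------------------------------------------------------------------------
# Weir–Cockerham components
# ---------------------------------------------------------------------------

def _locus_genotypes(dataset: Dataset, j: int, include_z: bool = True) -> np.ndarray:
    """(n_ind, 2) genotype slice at locus j; untyped rows become (0, 0).

    At Z-linked loci only male diploid genotypes are retained (females'
    hemizygous copies would fake homozygosity in the component sums).
    """
    block = dataset.alleles[:, j, :].copy()
    typed = (block > 0).all(axis=1)
    if dataset.loci[j].inheritance == Z_LINKED:
        typed &= dataset.sex_array() == MALE
        if not include_z:
            typed[:] = False
    block[~typed] = 0
    return block


def wc_components_locus(genos_by_pop: list[np.ndarray]) -> tuple[float, float, float]:
    """Weir–Cockerham (a, b, c) summed over alleles for one locus.

    ``genos_by_pop`` holds the typed diploid (k_i, 2) genotype arrays, one
    per population.  Returns (0, 0, 0) for loci that are unusable
    (any empty population, n_bar <= 1, or monomorphic across the set).
    """
    r = len(genos_by_pop)
    n = np.array([len(g) for g in genos_by_pop], float)
    if (n == 0).any():
        return 0.0, 0.0, 0.0
    nbar = n.mean()
    if nbar <= 1 or r < 2:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    states = np.unique(np.concatenate([g.ravel() for g in genos_by_pop]))
    n_states = len(states)
    if n_states < 2:
        return 0.0, 0.0, 0.0
    # per population: allele frequencies p and per-allele heterozygote
    # carrier frequencies h, vectorised over alleles
    p = np.empty((r, n_states))
    h = np.empty((r, n_states))
    for i, g in enumerate(genos_by_pop):
        idx = np.searchsorted(states, g)
        p[i] = np.bincount(idx.ravel(), minlength=n_states) / (2 * len(g))
        het = idx[:, 0] != idx[:, 1]
        h[i] = np.bincount(idx[het].ravel(), minlength=n_states) / len(g)
    pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def theta_pair(
    dataset: Dataset, pop1: str, pop2: str, include_z: bool = True
) -> float:
    """Multi-locus Weir–Cockerham theta between two populations."""
    m1 = dataset.population_mask(pop1)
    m2 = dataset.population_mask(pop2)
    return _theta_from_masks(dataset, m1, m2, include_z)


def _theta_from_masks(
    dataset: Dataset, m1: np.ndarray, m2: np.ndarray, include_z: bool = True
) -> float:
    a_tot = abc_tot = 0.0
    for j in range(dataset.n_loci):
        block = _locus_genotypes(dataset, j, include_z)
        g1 = block[m1]
        g1 = g1[(g1 > 0).all(axis=1)]
        g2 = block[m2]
        g2 = g2[(g2 > 0).all(axis=1)]
        a, b, c = wc_components_locus([g1, g2])
        a_tot += a
        abc_tot += a + b + c
    if abc_tot == 0:
        return float("nan")
    return a_tot / abc_tot


def pairwise_fst(dataset: Dataset, include_z: bool = True) -> PairwiseMatrix:
    """Pairwise multi-locus theta for every population pair."""
    pops = dataset.populations
    n = len(pops)
    values = np.full((n, n), np.nan)
    notes = []
    for i, k in combinations(range(n), 2):
        th = theta_pair(dataset, pops[i], pops[k], include_z)
        if np.isnan(th):
            notes.append(f"undefined theta for pair ({pops[i]}, {pops[k]})")
        values[i, k] = values[k, i] = th
    return PairwiseMatrix(pops, values, notes=notes)


def fst_significance(
    dataset: Dataset,
    permutations: int = 10_000,
    alpha: float = 0.001,
    seed: int = 0,
    include_z: bool = True,
) -> PairwiseMatrix:
    """Permutation test of theta > 0 for every population pair.

    Whole multilocus genotypes (rows) are permuted between the two
    populations; p = (1 + #{theta_perm >= theta_obs}) / (permutations + 1).
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    rng = np.random.default_rng(seed)
    pops = dataset.populations
    n = len(pops)
    values = np.full((n, n), np.nan)
    pvals = np.full((n, n), np.nan)
    sig = np.zeros((n, n), bool)
    for i, k in combinations(range(n), 2):
        m1 = dataset.population_mask(pops[i])
        m2 = dataset.population_mask(pops[k])
        obs = _theta_from_masks(dataset, m1, m2, include_z)
        values[i, k] = values[k, i] = obs
        if np.isnan(obs):
            continue
        idx = np.flatnonzero(m1 | m2)
        n1 = int(m1.sum())
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(idx)
            pm1 = np.zeros_like(m1)
            pm1[perm[:n1]] = True
            pm2 = np.zeros_like(m2)
            pm2[perm[n1:]] = True
            if _theta_from_masks(dataset, pm1, pm2, include_z) >= obs - 1e-12:
                count += 1
        p = (1 + count) / (permutations + 1)
        pvals[i, k] = pvals[k, i] = p
        sig[i, k] = sig[k, i] = p <= alpha
    return PairwiseMatrix(pops, values, p_values=pvals, significant=sig)


# ---------------------------------------------------------------------------
# Jost's D_est
# ---------------------------------------------------------------------------

def _freqs_and_sizes(
    dataset: Dataset, masks: list[np.ndarray], j: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Per-population allele frequency matrix and diploid-equivalent sizes.

    Frequencies use all typed gene copies (hemizygous females count one at
    Z loci); the sample size entering the Nei–Chesser correction is the
    copy count divided by two.
    """
    all_states: list[np.ndarray] = []
    copies_by_pop = []
    for m in masks:
        block = dataset.alleles[m, j, :]
        copies = block[block > 0]
        if len(copies) == 0:
            return None
        copies_by_pop.append(copies)
        all_states.append(np.unique(copies))
    states = np.unique(np.concatenate(all_states))
    freqs = np.zeros((len(masks), len(states)))
    sizes = np.zeros(len(masks))
    for i, copies in enumerate(copies_by_pop):
        idx = np.searchsorted(states, copies)
        counts = np.bincount(idx, minlength=len(states))
        freqs[i] = counts / counts.sum()
        sizes[i] = len(copies) / 2.0
    return freqs, sizes


def dest_locus(freqs: np.ndarray, sizes: np.ndarray) -> float:
    """Jost's D_est for one locus from per-population frequencies.

    Nei–Chesser bias correction with the harmonic mean sample size:
    H_S = (2n~/(2n~-1)) * (1 - mean_j sum_i p_ij^2);
    H_T = (1 - sum_i pbar_i^2) + H_S/(2 n~ s);
    D = (H_T - H_S)/(1 - H_S) * s/(s-1).
    """
    s = freqs.shape[0]
    ntilde = s / np.sum(1.0 / sizes)
    hs_obs = 1.0 - np.mean(np.sum(freqs**2, axis=1))
    hs = (2 * ntilde / (2 * ntilde - 1)) * hs_obs
    pbar = freqs.mean(axis=0)
    ht = (1.0 - np.sum(pbar**2)) + hs / (2 * ntilde * s)
    if hs >= 1.0:
        return float("nan")
    return float((ht - hs) / (1.0 - hs) * s / (s - 1))


def _harmonic_mean_dest(per_locus: np.ndarray, eps: float = HARMONIC_EPS) -> float:
    vals = per_locus[~np.isnan(per_locus)]
    if len(vals) == 0:
        return float("nan")
    clipped = np.where(vals > eps, vals, eps)
    return float(len(clipped) / np.sum(1.0 / clipped))


def dest_pair(
    dataset: Dataset, pop1: str, pop2: str, eps: float = HARMONIC_EPS
) -> float:
    """Harmonic-mean D_est across loci for one population pair.

    Per-locus values <= 0 enter the harmonic mean as ``eps`` (the harmonic
    mean is undefined at 0 and sign-breaking below it); loci with
    H_S = 1 are skipped.
    """
    m1 = dataset.population_mask(pop1)
    m2 = dataset.population_mask(pop2)
    per_locus = np.full(dataset.n_loci, np.nan)
    for j in range(dataset.n_loci):
        fs = _freqs_and_sizes(dataset, [m1, m2], j)
        if fs is None:
            continue
        per_locus[j] = dest_locus(*fs)
    return _harmonic_mean_dest(per_locus, eps)


def pairwise_dest(
    dataset: Dataset,
    bootstrap: int = 1000,
    seed: int = 0,
    eps: float = HARMONIC_EPS,
) -> PairwiseMatrix:
    """Pairwise harmonic-mean D_est with bootstrap percentile 95% CI.

    Bootstrap resamples individuals with replacement within each
    population.  ``bootstrap=0`` skips the CI.
    """
    rng = np.random.default_rng(seed)
    pops = dataset.populations
    n = len(pops)
    values = np.full((n, n), np.nan)
    lo = np.full((n, n), np.nan)
    hi = np.full((n, n), np.nan)
    pop_indices = {p: np.flatnonzero(dataset.population_mask(p)) for p in pops}
    for i, k in combinations(range(n), 2):
        values[i, k] = values[k, i] = dest_pair(dataset, pops[i], pops[k], eps)
        if bootstrap <= 0:
            continue
        idx1, idx2 = pop_indices[pops[i]], pop_indices[pops[k]]
        reps = np.empty(bootstrap)
        for b in range(bootstrap):
            r1 = rng.choice(idx1, size=len(idx1), replace=True)
            r2 = rng.choice(idx2, size=len(idx2), replace=True)
            per_locus = np.full(dataset.n_loci, np.nan)
            for j in range(dataset.n_loci):
                fs = _freqs_boot(dataset, [r1, r2], j)
                if fs is None:
                    continue
                per_locus[j] = dest_locus(*fs)
            reps[b] = _harmonic_mean_dest(per_locus, eps)
        reps = reps[~np.isnan(reps)]
        if len(reps):
            lo[i, k] = lo[k, i] = float(np.percentile(reps, 2.5))
            hi[i, k] = hi[k, i] = float(np.percentile(reps, 97.5))
    return PairwiseMatrix(pops, values, ci_low=lo, ci_high=hi)


def _freqs_boot(dataset: Dataset, rows_by_pop: list[np.ndarray], j: int):
    all_states, copies_by_pop = [], []
    for rows in rows_by_pop:
        block = dataset.alleles[rows, j, :]
        copies = block[block > 0]
        if len(copies) == 0:
            return None
        copies_by_pop.append(copies)
        all_states.append(np.unique(copies))
    states = np.unique(np.concatenate(all_states))
    freqs = np.zeros((len(rows_by_pop), len(states)))
    sizes = np.zeros(len(rows_by_pop))
    for i, copies in enumerate(copies_by_pop):
        idx = np.searchsorted(states, copies)
        counts = np.bincount(idx, minlength=len(states))
        freqs[i] = counts / counts.sum()
        sizes[i] = len(copies) / 2.0
    return freqs, sizes


# ---------------------------------------------------------------------------
# matrix utilities
# ---------------------------------------------------------------------------

def matrix_correlation(m1: PairwiseMatrix, m2: PairwiseMatrix) -> float:
    """Pearson correlation over the lower-triangle off-diagonal entries."""
    if m1.populations != m2.populations:
        raise ValueError("matrices must share population labels and order")
    x, y = m1.lower_triangle(), m2.lower_triangle()
    bad = np.isnan(x) | np.isnan(y)
    if bad.any():
        pairs = [
            (m1.populations[i], m1.populations[j])
            for idx, (i, j) in enumerate(
                (i, j) for i in range(len(m1.populations)) for j in range(i)
            )
            if bad[idx]
        ]
        raise ValueError(f"undefined cells for pairs: {pairs}")
    return float(np.corrcoef(x, y)[0, 1])


def combined_table(fst: PairwiseMatrix, dest: PairwiseMatrix) -> pd.DataFrame:
    """One matrix with theta below the diagonal and D_est above it."""
    if fst.populations != dest.populations:
        raise ValueError("matrices must share population labels and order")
    n = len(fst.populations)
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i > j:
                out[i, j] = fst.values[i, j]
            elif i < j:
                out[i, j] = dest.values[i, j]
    return pd.DataFrame(out, index=fst.populations, columns=fst.populations)
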